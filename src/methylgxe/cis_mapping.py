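"""Map each VML to its cis SNP set.

A SNP is in cis of a locus if it lies on the same chromosome within
``window`` bp (default 1 Mb) of the locus span, boundary inclusive:
start - window <= pos <= end + window. Loci with zero cis SNPs are valid
(they can only ever be explained by exposures or the baseline).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vml_identification import VML

CIS_WINDOW = 1_000_000


def find_cis_snps(vml: VML, snp_manifest: pd.DataFrame, window: int = CIS_WINDOW) -> list[str]:
    """Position-ordered SNP ids within the cis window of one locus."""
    sub = snp_manifest[snp_manifest["chrom"] == vml.chrom]
    pos = sub["pos"].to_numpy()
    lo = np.searchsorted(pos, vml.start - window, side="left")
    hi = np.searchsorted(pos, vml.end + window, side="right")
    return list(sub["snp_id"].iloc[lo:hi])


def build_cis_map(
    vmls: list[VML], snp_manifest: pd.DataFrame, window: int = CIS_WINDOW
) -> dict[str, list[str]]:
    """vml_id -> ordered cis SNP id list, for a sorted manifest."""
    return {v.vml_id: find_cis_snps(v, snp_manifest, window) for v in vmls}


def cis_map_table(cis_map: dict[str, list[str]]) -> pd.DataFrame:
    """Long-format (vml_id, snp_id) table for export."""
    records = [(vid, sid) for vid, snps in cis_map.items() for sid in snps]
    return pd.DataFrame(records, columns=["vml_id", "snp_id"])
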