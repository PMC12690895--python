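"""Meta-analyses: cross-dataset agreement and SNP under-sampling.

``overlap_vml`` + ``compute_agreement`` quantify how well two independent
result sets (e.g. two cohorts) agree on overlapping loci, both as whole
model classes and factor by factor (a factor "agrees" when it is present in
both winning models or absent from both). ``subsample_snp_experiment``
probes the sensitivity of the class composition to the amount of genetic
information by randomly under-sampling each locus's cis SNP set and
re-running the modelling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AlignedDataset, DataError
from .null_filter import apply_filter, build_null, evaluate_ge

FACTOR_PRESENCE = {
    "G": {"g"},
    "E": {"e"},
    "GE_ADD": {"g", "e"},
    "GXE": {"g", "e", "gxe"},
    "B": set(),
}


def overlap_vml(
    a: pd.DataFrame, b: pd.DataFrame, match: str = "all"
) -> pd.DataFrame:
    """Pairs of loci from two tables with >= 1 shared genomic position.

    Inputs need columns ``vml_id, chrom, start, end`` (1-based inclusive).
    ``match="all"`` emits every overlapping pair; ``match="greedy-longest"``
    reduces to a 1-1 matching preferring the longest overlaps.
    """
    merged = a.merge(b, on="chrom", suffixes=("_a", "_b"))
    hit = merged[
        (merged["start_a"] <= merged["end_b"]) & (merged["start_b"] <= merged["end_a"])
    ].copy()
    hit["overlap_bp"] = (
        np.minimum(hit["end_a"], hit["end_b"])
        - np.maximum(hit["start_a"], hit["start_b"])
        + 1
    )
    cols = [c for c in hit.columns if c.endswith(("_a", "_b"))] + ["chrom", "overlap_bp"]
    hit = hit[cols].reset_index(drop=True)
    if match == "all":
        return hit
    if match != "greedy-longest":
        raise DataError(f"unknown match mode {match!r}")
    hit = hit.sort_values(
        ["overlap_bp", "vml_id_a", "vml_id_b"], ascending=[False, True, True]
    )
    used_a, used_b, keep = set(), set(), []
    for idx, row in hit.iterrows():
        if row["vml_id_a"] in used_a or row["vml_id_b"] in used_b:
            continue
        used_a.add(row["vml_id_a"])
        used_b.add(row["vml_id_b"])
        keep.append(idx)
    return hit.loc[keep].reset_index(drop=True)


@dataclass
class AgreementReport:
    n_pairs: int
    factor_agreement: dict[str, float]
    overall_agreement: float
    pairs: pd.DataFrame = field(repr=False)


def factor_agreement(class_a: str, class_b: str) -> dict[str, bool]:
    """Per-factor agreement of two model classes: a factor agrees when it is
    present in both or absent from both."""
    for c in (class_a, class_b):
        if c not in FACTOR_PRESENCE:
            raise DataError(f"unknown model class {c!r}")
    pa, pb = FACTOR_PRESENCE[class_a], FACTOR_PRESENCE[class_b]
    return {f: (f in pa) == (f in pb) for f in ("g", "e", "gxe")}


def compute_agreement(
    pairs: pd.DataFrame, exclude_b: bool = True
) -> AgreementReport:
    """Agreement over paired loci carrying ``class_a`` and ``class_b`` columns.

    Baseline-involving pairs are excluded by default: the baseline call
    conflates "no signal" with cohort-specific information differences, which
    inflates apparent disagreement.
    """
    df = pairs.copy()
    if exclude_b:
        df = df[(df["class_a"] != "B") & (df["class_b"] != "B")]
    records = []
    for _, row in df.iterrows():
        agree = factor_agreement(row["class_a"], row["class_b"])
        records.append(
            {
                **{k: row[k] for k in df.columns},
                "agree_g": agree["g"],
                "agree_e": agree["e"],
                "agree_gxe": agree["gxe"],
                "agree_overall": row["class_a"] == row["class_b"],
            }
        )
    out = pd.DataFrame(records)
    n = len(out)
    return AgreementReport(
        n_pairs=n,
        factor_agreement={
            "G": out["agree_g"].mean() if n else np.nan,
            "E": out["agree_e"].mean() if n else np.nan,
            "GxE": out["agree_gxe"].mean() if n else np.nan,
        },
        overall_agreement=out["agree_overall"].mean() if n else np.nan,
        pairs=out,
    )


def subsample_snp_experiment(
    dataset: AlignedDataset,
    summarized: pd.DataFrame,
    cis_map: dict[str, list[str]],
    seed: int,
    k_values: tuple[int, ...] = (10, 100, 500, 1000),
    reps: int = 5,
    n_permutations: int = 10,
    vml_kinds: dict[str, str] | None = None,
    **lasso_kw,
) -> pd.DataFrame:
    """Re-run the modelling stage with each locus's cis set under-sampled to
    at most k SNPs (loci with fewer keep their full set; no sampling).

    Returns a long table of final class counts per (k, rep).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_values:
        for rep in range(reps):
            sub_map = {}
            for vid, snps in cis_map.items():
                if len(snps) <= k:
                    sub_map[vid] = list(snps)
                else:
                    pick = rng.choice(len(snps), size=k, replace=False)
                    sub_map[vid] = [snps[i] for i in sorted(pick)]
            run_seed = int(rng.integers(2**31))
            res = evaluate_ge(
                dataset, summarized, sub_map, run_seed, vml_kinds=vml_kinds, **lasso_kw
            )
            null = build_null(
                dataset, summarized, sub_map, run_seed,
                n_permutations=n_permutations, vml_kinds=vml_kinds, **lasso_kw,
            )
            final = apply_filter(res, null)
            counts = final["winner_class"].value_counts()
            for cls in ("B", "G", "E", "GE_ADD", "GXE"):
                rows.append(
                    {"k": k, "rep": rep, "model_class": cls,
                     "count": int(counts.get(cls, 0))}
                )
    return pd.DataFrame(rows)
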