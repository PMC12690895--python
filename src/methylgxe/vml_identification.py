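"""Grouping HVPs into variably methylated loci (VML).

Two locus kinds are produced:

* **VMR** (variably methylated region): a maximal run of >= 2 HVPs on one
  chromosome where successive probes are < ``max_gap`` bp apart and each
  adjacent pair is co-methylated (Pearson r > ``min_r`` on unadjusted
  M values). Its per-sample methylation is the median across member probes.
* **sVMP** (sparse variably methylated probe): an HVP left outside every VMR
  that has *no other array probe at all* (variable or not) within ``max_gap``.
  Sparse array coverage, not lack of signal, is what isolates these probes,
  so they are kept as single-probe loci.

HVPs that are neither — i.e. they have a close neighbour on the array but
failed the proximity/correlation chaining — are discarded (counted in the
log): a nearby probe existed and did not co-vary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DataError

logger = logging.getLogger("methylgxe")


@dataclass
class VML:
    vml_id: str
    kind: str  # "VMR" | "sVMP"
    chrom: str
    start: int
    end: int
    probe_ids: list[str]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def summarize_vmr(methylation: pd.DataFrame, probe_ids: list[str]) -> pd.Series:
    """Per-sample median of member-probe M values (unadjusted scale)."""
    missing = [p for p in probe_ids if p not in methylation.columns]
    if missing:
        raise DataError(f"probes missing from methylation matrix: {missing}")
    if len(probe_ids) < 2:
        raise DataError("a VMR summary needs at least 2 probes")
    return methylation[probe_ids].median(axis=1)


def _split_on_correlation(run: pd.DataFrame, m: np.ndarray, min_r: float,
                          all_pairs: bool) -> list[list[int]]:
    """Split a distance-chained run at adjacent pairs with r <= min_r.

    ``run`` rows are position-sorted probes of one candidate chain; ``m`` is
    the (n_samples, n_probes_in_run) value block. With ``all_pairs`` the run
    is kept whole iff the mean over all pairwise correlations exceeds
    ``min_r`` (alternative construction, off by default).
    """
    k = len(run)
    if all_pairs:
        c = np.corrcoef(m.T)
        mean_r = c[np.triu_indices(k, 1)].mean()
        return [list(range(k))] if mean_r > min_r else [[i] for i in range(k)]
    groups, current = [], [0]
    for i in range(1, k):
        r = np.corrcoef(m[:, i - 1], m[:, i])[0, 1]
        if r > min_r:
            current.append(i)
        else:
            groups.append(current)
            current = [i]
    groups.append(current)
    return groups


def find_vml(
    hvp_ids: list[str],
    probe_manifest: pd.DataFrame,
    methylation: pd.DataFrame,
    max_gap: int = 1000,
    min_r: float = 0.15,
    svmp_mode: str = "array",
    all_pairs: bool = False,
) -> list[VML]:
    """Group HVPs into VMRs and sVMPs.

    ``svmp_mode`` controls which probes count as "neighbours" when deciding
    sVMP eligibility: ``"array"`` (default) consults the full manifest,
    ``"hvp"`` only other HVPs.
    """
    hvp_set = set(hvp_ids)
    man = probe_manifest.set_index("probe_id")
    missing = hvp_set - set(man.index)
    if missing:
        raise DataError(f"HVPs missing manifest coordinates: {sorted(missing)[:5]}")
    if svmp_mode not in ("array", "hvp"):
        raise DataError(f"unknown svmp_mode {svmp_mode!r}")

    hvp_man = (
        probe_manifest[probe_manifest["probe_id"].isin(hvp_set)]
        .sort_values(["chrom", "pos", "probe_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    vmls: list[VML] = []
    in_vmr: set[str] = set()

    for chrom, grp in hvp_man.groupby("chrom", sort=True):
        grp = grp.reset_index(drop=True)
        pos = grp["pos"].to_numpy()
        # maximal runs of consecutive HVPs with inter-probe gap < max_gap
        breaks = np.where(np.diff(pos) >= max_gap)[0] + 1
        for run_idx in np.split(np.arange(len(grp)), breaks):
            if len(run_idx) < 2:
                continue
            run = grp.iloc[run_idx]
            m = methylation[list(run["probe_id"])].to_numpy(dtype=float)
            for sub in _split_on_correlation(run, m, min_r, all_pairs):
                if len(sub) < 2:
                    continue
                probes = list(run["probe_id"].iloc[sub])
                start = int(run["pos"].iloc[sub].min())
                end = int(run["pos"].iloc[sub].max())
                vmls.append(VML(f"{chrom}:{start}-{end}(VMR)", "VMR", chrom, start, end, probes))
                in_vmr.update(probes)

    # sVMP rule: leftover HVPs with no neighbouring probe within max_gap
    neighbour_man = probe_manifest if svmp_mode == "array" else hvp_man
    n_discarded = 0
    for chrom, grp in hvp_man.groupby("chrom", sort=True):
        npos = np.sort(
            neighbour_man.loc[neighbour_man["chrom"] == chrom, "pos"].to_numpy()
        )
        for _, row in grp.iterrows():
            pid, p = row["probe_id"], int(row["pos"])
            if pid in in_vmr:
                continue
            lo = np.searchsorted(npos, p - max_gap + 1, side="left")
            hi = np.searchsorted(npos, p + max_gap - 1, side="right")
            n_neighbours = hi - lo - int(np.any(npos[lo:hi] == p))
            if n_neighbours == 0:
                vmls.append(VML(f"{chrom}:{p}-{p}(sVMP)", "sVMP", chrom, p, p, [pid]))
            else:
                n_discarded += 1
    if n_discarded:
        logger.info("find_vml: discarded %d HVPs (close but uncorrelated/non-sparse)", n_discarded)

    vmls.sort(key=lambda v: (v.chrom, v.start, v.end, v.kind))
    return vmls


def summarize_all(methylation: pd.DataFrame, vmls: list[VML]) -> pd.DataFrame:
    """Samples x VML matrix of summarized methylation (median for VMRs,
    the probe's own M values for sVMPs)."""
    cols = {}
    for v in vmls:
        if v.kind == "VMR":
            cols[v.vml_id] = summarize_vmr(methylation, v.probe_ids)
        else:
            cols[v.vml_id] = methylation[v.probe_ids[0]]
    return pd.DataFrame(cols, index=methylation.index)


def vml_table(vmls: list[VML]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "vml_id": [v.vml_id for v in vmls],
            "kind": [v.kind for v in vmls],
            "chrom": [v.chrom for v in vmls],
            "start": [v.start for v in vmls],
            "end": [v.end for v in vmls],
            "n_probes": [v.n_probes for v in vmls],
            "probe_ids": [",".join(v.probe_ids) for v in vmls],
        }
    )


def vml_to_bed(vmls: list[VML]) -> pd.DataFrame:
    """0-based half-open BED export of VML spans."""
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in vmls],
            "start": [v.start - 1 for v in vmls],
            "end": [v.end for v in vmls],
            "name": [v.vml_id for v in vmls],
        }
    )
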