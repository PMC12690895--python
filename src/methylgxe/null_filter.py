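"""Permutation null filter for the model competition.

Even on pure noise, screening hundreds of candidates and picking the
AIC-best of many models yields winners with a deceptively positive
R^2 improvement over the covariates-only baseline. To calibrate this, the
genotype and exposome tables are shuffled *jointly* (one permutation of
sample order applied to both, preserving every G-E correlation) while
methylation and covariates keep their original order, and the whole
selection + competition stage is re-run. Pooled over permutations and loci,
the resulting delta R^2 values form the null distribution; it is distinctly
bimodal, so it is stratified into marginal (G or E winners) and joint
(G+E or GxE winners) components. Observed winners whose delta R^2 falls
below the 95th percentile of their stratum's null are demoted to baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AlignedDataset
from .model_selection import select_best_model
from .variable_selection import select_variables

logger = logging.getLogger("methylgxe")

MARGINAL = ("G", "E")
JOINT = ("GE_ADD", "GXE")


@dataclass
class NullDistribution:
    delta_r2_marginal: np.ndarray
    delta_r2_joint: np.ndarray
    percentile: float = 95.0
    n_permutations: int = 0
    cutoff_marginal: float = field(init=False)
    cutoff_joint: float = field(init=False)

    def __post_init__(self):
        self.cutoff_marginal = _cutoff(self.delta_r2_marginal, self.percentile)
        self.cutoff_joint = _cutoff(self.delta_r2_joint, self.percentile)


def _cutoff(values: np.ndarray, percentile: float) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        # the permutations produced no informative winner in this stratum:
        # the null provides no delta R^2 to beat, so nothing is demoted
        return 0.0
    return float(np.percentile(values, percentile))  # linear interpolation


def permute_ge(dataset: AlignedDataset, seed: int) -> AlignedDataset:
    """Shuffle genotype and exposome rows with one shared permutation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n_samples)
    geno = pd.DataFrame(
        dataset.genotypes.to_numpy()[perm],
        index=dataset.genotypes.index,
        columns=dataset.genotypes.columns,
    )
    expo = pd.DataFrame(
        dataset.exposome.to_numpy()[perm],
        index=dataset.exposome.index,
        columns=dataset.exposome.columns,
    )
    return dataset.with_ge(geno, expo)


def _evaluate_one(
    vml_id: str,
    y: np.ndarray,
    cis_snps: list[str],
    dataset: AlignedDataset,
    seed: int,
    kind: str,
    salt: str,
    lasso_kw: dict,
) -> dict:
    sel = select_variables(
        vml_id, y, cis_snps,
        dataset.genotypes, dataset.exposome, dataset.covariates,
        seed, salt=salt, **lasso_kw,
    )
    row = {
        "vml_id": vml_id,
        "kind": kind,
        "n_selected_g": len(sel.selected_g),
        "n_selected_e": len(sel.selected_e),
    }
    if sel.is_empty:
        row.update(
            winner_class="B", snp_id=None, exposure_id=None,
            aic=np.nan, r2=np.nan, baseline_r2=np.nan, delta_r2=0.0,
            partial_r2_g=np.nan, partial_r2_e=np.nan, partial_r2_gxe=np.nan,
        )
    else:
        best = select_best_model(
            vml_id, y, sorted(sel.selected_g), sorted(sel.selected_e),
            dataset.genotypes, dataset.exposome, dataset.covariates,
        )
        row.update(
            winner_class=best.winner.model_class,
            snp_id=best.winner.snp_id,
            exposure_id=best.winner.exposure_id,
            aic=best.winner.aic,
            r2=best.winner.r2,
            baseline_r2=best.baseline_r2,
            delta_r2=best.delta_r2,
            partial_r2_g=best.partial_r2.get("g", np.nan),
            partial_r2_e=best.partial_r2.get("e", np.nan),
            partial_r2_gxe=best.partial_r2.get("gxe", np.nan),
        )
    return row


def evaluate_ge(
    dataset: AlignedDataset,
    summarized: pd.DataFrame,
    cis_map: dict[str, list[str]],
    seed: int,
    vml_kinds: dict[str, str] | None = None,
    salt: str = "",
    n_jobs: int = 1,
    **lasso_kw,
) -> pd.DataFrame:
    """Run variable selection + model competition for every locus.

    Returns one row per locus with the winning class, its variables, fit
    statistics and LMG partial R^2 values. Loci where nothing is selected
    are assigned class ``B`` without fitting. Each locus draws its own seed
    stream, so results are identical for any ``n_jobs``.
    """
    kinds = vml_kinds or {}
    args = [
        (
            vid, summarized[vid].to_numpy(dtype=float), cis_map.get(vid, []),
            dataset, seed, kinds.get(vid, ""), salt, lasso_kw,
        )
        for vid in summarized.columns
    ]
    if n_jobs == 1:
        rows = [_evaluate_one(*a) for a in args]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(_evaluate_one)(*a) for a in args)
    return pd.DataFrame(rows)


def build_null(
    dataset: AlignedDataset,
    summarized: pd.DataFrame,
    cis_map: dict[str, list[str]],
    seed: int,
    n_permutations: int = 10,
    percentile: float = 95.0,
    vml_kinds: dict[str, str] | None = None,
    n_jobs: int = 1,
    **lasso_kw,
) -> NullDistribution:
    """Build the stratified null delta R^2 distribution.

    Each permutation re-runs selection and model competition on every locus
    with the same per-locus CV seed streams as the observed run, so the only
    difference is the shuffling itself.
    """
    marginal, joint = [], []
    for i in range(n_permutations):
        perm_seed = (seed + 100_003 * (i + 1)) % (2**31)
        permuted = permute_ge(dataset, perm_seed)
        res = evaluate_ge(
            permuted, summarized, cis_map, seed,
            vml_kinds=vml_kinds, salt=f"perm{i}", n_jobs=n_jobs, **lasso_kw,
        )
        informative = res[res["winner_class"] != "B"]
        if informative.empty:
            logger.info("build_null: permutation %d yielded no informative winners", i)
            continue
        m = informative["winner_class"].isin(MARGINAL)
        marginal.extend(informative.loc[m, "delta_r2"])
        joint.extend(informative.loc[~m, "delta_r2"])
    return NullDistribution(
        np.asarray(marginal), np.asarray(joint),
        percentile=percentile, n_permutations=n_permutations,
    )


def apply_filter(results: pd.DataFrame, null: NullDistribution) -> pd.DataFrame:
    """Demote winners whose delta R^2 is below their stratum's cutoff.

    The pre-filter class is retained in ``prefilter_class`` for audit; a
    winner exactly at the cutoff is kept (strict "below" is demoted).
    """
    out = results.copy()
    out["prefilter_class"] = out["winner_class"]
    cls = out["winner_class"]
    demote = (
        (cls.isin(MARGINAL) & (out["delta_r2"] < null.cutoff_marginal))
        | (cls.isin(JOINT) & (out["delta_r2"] < null.cutoff_joint))
    )
    out.loc[demote, "winner_class"] = "B"
    return out
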