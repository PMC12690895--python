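"""Model competition (G / E / G+E / GxE) and LMG variance decomposition.

For each locus, every selected SNP and exposure is used one at a time to fit
the four linear model families

    G:      DNAme ~ SNP_i + covars
    E:      DNAme ~ EE_j + covars
    G+E:    DNAme ~ SNP_i + EE_j + covars
    GxE:    DNAme ~ SNP_i + EE_j + SNP_i*EE_j + covars

(the interaction model is hierarchical: main effects always included). The
best explanatory model is the one with the lowest AIC; ties go to the model
with fewer parameters, then by fixed class order G < E < G+E < GxE, then by
lexicographic variable ids — fully deterministic. The winner's variance is
decomposed with the LMG (Lindeman-Merenda-Gold) method: the average, over
all orderings of the winner's non-covariate terms, of each term's sequential
R^2 increase, with the covariate block always entered first. Shares are
non-negative and sum exactly to R^2_winner - R^2_baseline.

AIC uses the Gaussian log-likelihood convention
``n*ln(2*pi*RSS/n) + n + 2*(k+1)`` where k counts estimated coefficients
including the intercept and the +1 accounts for the error variance; only AIC
differences matter for the competition, but the constant is pinned so values
are comparable across implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .data_model import DataError

logger = logging.getLogger("methylgxe")

CLASS_ORDER = {"G": 0, "E": 1, "GE_ADD": 2, "GXE": 3, "B": 4}
RSS_FLOOR = 1e-12  # guard: perfect fits would send AIC to -inf


@dataclass
class FittedModel:
    model_class: str
    snp_id: str | None
    exposure_id: str | None
    rss: float
    k: int  # estimated coefficients, incl. intercept
    aic: float
    r2: float
    n: int


@dataclass
class BestModel:
    vml_id: str
    winner: FittedModel
    baseline_r2: float
    delta_r2: float
    partial_r2: dict[str, float] = field(default_factory=dict)


def gaussian_aic(n: int, rss: float, k: int) -> float:
    rss = max(rss, RSS_FLOOR)
    return n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 1)


def fit_ols(y: np.ndarray, design: np.ndarray) -> tuple[float, int, float, float] | None:
    """Least squares fit; returns (rss, k, r2, aic) or None if singular."""
    n, k = design.shape
    if n <= k:
        raise DataError(f"need n > k to fit ({n} samples, {k} coefficients)")
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k:
        return None
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return rss, k, r2, gaussian_aic(n, rss, k)


def _term_columns(model_class, snp, expo):
    if model_class == "G":
        return {"g": snp}
    if model_class == "E":
        return {"e": expo}
    if model_class == "GE_ADD":
        return {"g": snp, "e": expo}
    if model_class == "GXE":
        return {"g": snp, "e": expo, "gxe": snp * expo}
    return {}


def lmg_decompose(
    y: np.ndarray,
    covariates: np.ndarray,
    terms: dict[str, np.ndarray],
) -> dict[str, float]:
    """LMG relative importance of ``terms`` with covariates always first.

    Exact enumeration over all orderings of the (<= 3) terms; each share is
    the mean sequential R^2 increment of that term.
    """
    n = len(y)
    base = np.column_stack([np.ones(n), covariates])
    names = sorted(terms)

    def r2_of(subset: frozenset) -> float:
        cols = [terms[t] for t in names if t in subset]
        design = np.column_stack([base] + cols) if cols else base
        fit = fit_ols(y, design)
        if fit is None:
            raise DataError("singular design in LMG decomposition")
        return fit[2]

    cache = {frozenset(): r2_of(frozenset())}
    shares = {t: 0.0 for t in names}
    orders = list(permutations(names))
    for order in orders:
        seen: frozenset = frozenset()
        for t in order:
            nxt = seen | {t}
            if nxt not in cache:
                cache[nxt] = r2_of(nxt)
            shares[t] += cache[nxt] - cache[seen]
            seen = nxt
    return {t: s / len(orders) for t, s in shares.items()}


def select_best_model(
    vml_id: str,
    y: np.ndarray,
    selected_g: list[str],
    selected_e: list[str],
    genotypes: pd.DataFrame,
    exposome: pd.DataFrame,
    covariates: pd.DataFrame,
) -> BestModel:
    """Fit the full model space for one locus and return the AIC winner
    with its LMG decomposition."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    cov = covariates.to_numpy(dtype=float)
    base = np.column_stack([np.ones(n), cov])

    base_fit = fit_ols(y, base)
    if base_fit is None:
        raise DataError("baseline (covariates-only) design is singular")
    baseline_r2 = base_fit[2]

    snps = {s: genotypes[s].to_numpy(dtype=float) for s in sorted(selected_g)}
    expos = {e: exposome[e].to_numpy(dtype=float) for e in sorted(selected_e)}

    candidates: list[FittedModel] = []

    def try_model(model_class, snp_id, expo_id, cols):
        fit = fit_ols(y, np.column_stack([base] + cols))
        if fit is None:
            logger.warning(
                "select_best_model[%s]: singular %s model (snp=%s, e=%s) dropped",
                vml_id, model_class, snp_id, expo_id,
            )
            return
        rss, k, r2, aic = fit
        candidates.append(
            FittedModel(model_class, snp_id, expo_id, rss, k, aic, r2, n)
        )

    for sid, g in snps.items():
        try_model("G", sid, None, [g])
    for eid, e in expos.items():
        try_model("E", None, eid, [e])
    for sid, g in snps.items():
        for eid, e in expos.items():
            try_model("GE_ADD", sid, eid, [g, e])
            try_model("GXE", sid, eid, [g, e, g * e])

    if not candidates:
        logger.warning("select_best_model[%s]: all models singular; assigning B", vml_id)
        rss, k, r2, aic = base_fit
        winner = FittedModel("B", None, None, rss, k, aic, r2, n)
        return BestModel(vml_id, winner, baseline_r2, 0.0, {})

    winner = min(
        candidates,
        key=lambda m: (
            m.aic, m.k, CLASS_ORDER[m.model_class], m.snp_id or "", m.exposure_id or "",
        ),
    )
    terms = _term_columns(
        winner.model_class,
        snps.get(winner.snp_id) if winner.snp_id else None,
        expos.get(winner.exposure_id) if winner.exposure_id else None,
    )
    partial = lmg_decompose(y, cov, terms)
    return BestModel(vml_id, winner, baseline_r2, winner.r2 - baseline_r2, partial)


def count_total_models(cis_counts: list[int], n_exposures: int) -> int:
    """Size of the model space without variable selection:
    sum over loci of G_i + E + 2*G_i*E."""
    if any(g < 0 for g in cis_counts) or n_exposures < 0:
        raise DataError("counts must be non-negative")
    return int(sum(g + n_exposures + 2 * g * n_exposures for g in cis_counts))
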