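"""LASSO screening of cis SNPs and exposures per VML.

For each locus the candidate pool is screened in three scenarios: (1) cis
SNPs only, (2) exposures only, (3) both together. Concomitant variables are
present and unpenalized in every scenario. The regularization strength is
chosen by 10-fold cross-validation (one-standard-error rule by default,
CV-MSE minimizer available), and every
variable with a nonzero coefficient in any scenario is pooled into the
locus's selected set. A locus with no cis SNPs runs scenario (2) only; a
locus where nothing survives is assigned the baseline class downstream
without fitting any model.

Selection is deterministic given the global seed: each locus draws its CV
fold stream from a stable hash of (seed, vml_id), so results do not depend
on evaluation order or parallel scheduling.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lasso import cv_lasso

logger = logging.getLogger("methylgxe")


@dataclass
class SelectedVariables:
    vml_id: str
    selected_g: set[str] = field(default_factory=set)
    selected_e: set[str] = field(default_factory=set)
    coefficients: dict[str, float] = field(default_factory=dict)
    #: per selected variable, max |r| with any unselected candidate — flags
    #: correlated blocks where the lasso's pick among near-duplicates is
    #: essentially arbitrary
    max_corr_unselected: dict[str, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not (self.selected_g or self.selected_e)


def derive_seed(global_seed: int, vml_id: str, salt: str = "") -> int:
    """Stable per-locus RNG seed (order-independent, < 2**31)."""
    return zlib.crc32(f"{global_seed}:{vml_id}:{salt}".encode()) & 0x7FFFFFFF


def lasso_select(
    y: np.ndarray,
    candidates: pd.DataFrame,
    covariates: np.ndarray | None,
    seed: int,
    n_folds: int = 10,
    n_alphas: int = 50,
    eps: float = 1e-3,
    lambda_rule: str = "1se",
) -> dict[str, float]:
    """One lasso scenario; returns {candidate id: coefficient} for the
    nonzero-coefficient candidates at the CV-chosen penalty."""
    if candidates.shape[1] == 0:
        return {}
    x = candidates.to_numpy(dtype=float)
    const = x.std(axis=0) <= 1e-12
    if const.any():
        logger.warning(
            "lasso_select: dropping %d constant candidate column(s)", int(const.sum())
        )
        candidates = candidates.loc[:, ~const]
        x = x[:, ~const]
        if x.shape[1] == 0:
            return {}
    try:
        coefs, _ = cv_lasso(
            x, np.asarray(y, dtype=float), covariates, seed,
            n_folds=n_folds, n_alphas=n_alphas, eps=eps, lambda_rule=lambda_rule,
        )
    except np.linalg.LinAlgError as exc:  # CV failure is not fatal
        logger.warning("lasso_select: CV failed (%s); returning empty set", exc)
        return {}
    nz = np.flatnonzero(coefs != 0.0)
    return {candidates.columns[i]: float(coefs[i]) for i in nz}


def select_variables(
    vml_id: str,
    y: np.ndarray,
    cis_snp_ids: list[str],
    genotypes: pd.DataFrame,
    exposome: pd.DataFrame,
    covariates: pd.DataFrame,
    seed: int,
    salt: str = "",
    **lasso_kw,
) -> SelectedVariables:
    """Run the three screening scenarios for one locus and pool survivors."""
    cov = covariates.to_numpy(dtype=float)
    base_seed = derive_seed(seed, vml_id, salt)
    g_cands = genotypes[cis_snp_ids] if cis_snp_ids else genotypes.iloc[:, :0]

    pooled: dict[str, float] = {}
    if len(cis_snp_ids) > 0:
        pooled.update(lasso_select(y, g_cands, cov, base_seed, **lasso_kw))
        pooled.update(
            lasso_select(
                y, pd.concat([g_cands, exposome], axis=1), cov, base_seed + 2, **lasso_kw
            )
        )
    pooled.update(lasso_select(y, exposome, cov, base_seed + 1, **lasso_kw))

    sel = SelectedVariables(vml_id=vml_id, coefficients=pooled)
    e_cols = set(exposome.columns)
    for name in pooled:
        (sel.selected_e if name in e_cols else sel.selected_g).add(name)

    # correlated-block audit: max |r| of each pick with unselected candidates
    all_cands = pd.concat([g_cands, exposome], axis=1)
    unsel = [c for c in all_cands.columns if c not in pooled]
    if pooled and unsel:
        cmat = np.corrcoef(all_cands.to_numpy(dtype=float).T)
        idx = {c: i for i, c in enumerate(all_cands.columns)}
        uidx = [idx[c] for c in unsel]
        for name in pooled:
            sel.max_corr_unselected[name] = float(
                np.nanmax(np.abs(cmat[idx[name], uidx]))
            )
    return sel


def selection_table(selections: list[SelectedVariables]) -> pd.DataFrame:
    """Long-format (vml_id, variable_id, type, coefficient) export."""
    rows = []
    for s in selections:
        for name, coef in sorted(s.coefficients.items()):
            rows.append(
                (s.vml_id, name, "E" if name in s.selected_e else "G", coef)
            )
    return pd.DataFrame(rows, columns=["vml_id", "variable_id", "type", "coefficient"])
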