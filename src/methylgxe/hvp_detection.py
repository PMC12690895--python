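"""Highly variable probe (HVP) detection.

M values are first residualized on the concomitant variables so that known
drivers of methylation variation (sex, gestational age, cell composition,
ancestry components) do not inflate per-probe variance. Probes whose residual
variance exceeds the 90th percentile of the residual-variance distribution are
flagged as HVPs. The residuals are used *only* here; every later stage models
unadjusted M values (the covariates re-enter each model explicitly).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import DataError


def residualize(methylation: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-probe OLS residuals of M ~ intercept + covariates.

    All probes share one design matrix, so the projection is computed once and
    applied to the whole matrix.
    """
    if not methylation.index.equals(covariates.index):
        raise DataError("methylation and covariates must share an identical sample order")
    n = len(methylation.index)
    x = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DataError("covariate design is rank-deficient")
    y = methylation.to_numpy(dtype=float)
    q, _ = np.linalg.qr(x)
    resid = y - q @ (q.T @ y)
    return pd.DataFrame(resid, index=methylation.index, columns=methylation.columns)


def select_hvps(
    residuals: pd.DataFrame,
    quantile: float = 0.90,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Flag probes whose residual variance exceeds the given quantile.

    The threshold is the linear-interpolation (R type-7) quantile of the
    per-probe sample variances (denominator n-1). Membership is strict
    (variance > threshold) by default; ``inclusive=True`` switches to >=,
    which only matters for probes tied exactly at the cutoff.

    Returns a frame with columns ``probe_id``, ``residual_variance``,
    ``is_hvp`` and ``variance_threshold``.
    """
    if residuals.shape[1] < 10:
        raise DataError("need at least 10 probes to take a variance quantile")
    if residuals.shape[0] < 2:
        raise DataError("need at least 2 samples to compute a variance")
    var = residuals.to_numpy(dtype=float).var(axis=0, ddof=1)
    threshold = float(np.quantile(var, quantile))
    is_hvp = var >= threshold if inclusive else var > threshold
    return pd.DataFrame(
        {
            "probe_id": residuals.columns,
            "residual_variance": var,
            "is_hvp": is_hvp,
            "variance_threshold": threshold,
        }
    )


def find_hvps(
    methylation: pd.DataFrame,
    covariates: pd.DataFrame,
    quantile: float = 0.90,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Residualize, then select HVPs; convenience wrapper over both steps."""
    return select_hvps(residualize(methylation, covariates), quantile, inclusive)
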