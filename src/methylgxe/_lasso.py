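"""Cross-validated lasso with unpenalized covariates.

This is the screening engine behind variable selection. It solves

    min_{a, b}  (1/2n) ||y - C a - X b||^2 + alpha ||b||_1

where C holds the concomitant variables (never penalized, never
standardized) and X the candidate SNP/exposure columns (standardized to unit
variance internally). The covariate block is profiled out exactly: for fixed
b the optimal a is the OLS fit of (y - X b) on C, so the problem reduces to
a plain lasso on C-residualized y and X. Cross-validation respects this by
fitting the covariate projection on each training fold and applying it to the
held-out fold.

The path over a geometric alpha grid is computed by cyclic coordinate descent
on the precomputed Gram matrix (covariance updates), JIT-compiled with numba:
the pipeline calls this routine hundreds of thousands of times during the
permutation-null stage, where a generic solver's per-call overhead dominates.
sklearn's `lasso_path` serves as the correctness reference in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

# above this many candidates the X-based scikit-learn solver wins over the
# Gram-based one (per-coordinate cost O(n) instead of O(p))
_LARGE_P = 400


@njit(cache=True)
def _cd_path_gram(gram, xy, alphas, tol, max_iter):  # pragma: no cover - numba
    """Lasso coefficient path by coordinate descent on gram = X'X/n, xy = X'y/n.

    ``alphas`` must be decreasing; solutions are warm-started down the path.
    Returns a (p, n_alphas) array.
    """
    p = gram.shape[0]
    n_alphas = alphas.shape[0]
    coefs = np.zeros((p, n_alphas))
    b = np.zeros(p)
    for k in range(n_alphas):
        a = alphas[k]
        for _ in range(max_iter):
            max_delta = 0.0
            for j in range(p):
                gjj = gram[j, j]
                if gjj <= 0.0:
                    continue
                rho = xy[j] - np.dot(gram[j], b) + gjj * b[j]
                if rho > a:
                    nb = (rho - a) / gjj
                elif rho < -a:
                    nb = (rho + a) / gjj
                else:
                    nb = 0.0
                delta = abs(nb - b[j])
                if delta > max_delta:
                    max_delta = delta
                b[j] = nb
            if max_delta < tol:
                break
        coefs[:, k] = b
    return coefs


def _path(x: np.ndarray, y: np.ndarray, grid: np.ndarray, tol: float,
          max_iter: int) -> np.ndarray:
    """(p, n_alphas) lasso coefficient path on centered/standardized data."""
    n, p = x.shape
    if p >= _LARGE_P or p >= n:
        _, coefs, _ = lasso_path(x, y, alphas=grid, max_iter=max_iter)
        return coefs
    gram = (x.T @ x) / n
    xty = (x.T @ y) / n
    return _cd_path_gram(gram, xty, grid, tol, max_iter)


def _covariate_basis(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        c = np.ones((n, 1))
    else:
        c = np.column_stack([np.ones(n), covariates])
    return c


def _project_out(c_train, c_apply, *arrays_train_apply):
    """Residualize arrays on the span of c fitted on the training rows."""
    coef, _, _, _ = np.linalg.lstsq(c_train, np.column_stack(
        [a for a, _ in arrays_train_apply]), rcond=None)
    # split back
    out = []
    col = 0
    for a_train, a_apply in arrays_train_apply:
        w = 1 if a_train.ndim == 1 else a_train.shape[1]
        beta = coef[:, col:col + w]
        rt = a_train - (c_train @ beta).reshape(a_train.shape)
        ra = a_apply - (c_apply @ beta).reshape(a_apply.shape)
        out.append((rt, ra))
        col += w
    return out


def cv_lasso(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    seed: int,
    n_folds: int = 10,
    n_alphas: int = 50,
    eps: float = 1e-3,
    lambda_rule: str = "1se",
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> tuple[np.ndarray, float]:
    """K-fold CV lasso; returns (coefficients on the original x scale, alpha).

    Candidate columns with (residual) variance ~0 get coefficient 0. The
    alpha grid is shared across folds; ``lambda_rule`` is ``"min"``
    (CV-MSE minimizer) or ``"1se"`` (sparsest alpha within one standard
    error of the minimum).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if lambda_rule not in ("min", "1se"):
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    c = _covariate_basis(covariates, n)
    (yr, _), (xr, _) = _project_out(c, c, (y, y), (x, x))
    sd = xr.std(axis=0)
    live = sd > 1e-12
    if not live.any():
        return np.zeros(p), np.inf
    scale = np.where(live, sd, 1.0)
    xs = xr / scale

    alpha_max = np.max(np.abs(xs[:, live].T @ yr)) / n
    if not np.isfinite(alpha_max) or alpha_max <= 0:
        return np.zeros(p), np.inf
    if int(live.sum()) >= n:
        # over-parameterized case: do not chase the saturated end of the
        # path (glmnet's lambda.min.ratio convention)
        eps = max(eps, 1e-2)
    # nudge the top of the grid so the alpha_max solution is exactly empty
    # (at alpha == alpha_max the KKT condition sits on a float boundary)
    grid = np.geomspace(alpha_max * (1.0 + 1e-10), alpha_max * eps, n_alphas)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    fold_mse = np.empty((n_folds, n_alphas))
    for f, (tr, te) in enumerate(kf.split(x)):
        (ytr, yte), (xtr, xte) = _project_out(
            c[tr], c[te], (y[tr], y[te]), (x[tr], x[te]))
        xtr = xtr / scale
        xte = xte / scale
        coefs = _path(xtr, ytr, grid, tol, max_iter)
        resid = yte[:, None] - xte @ coefs
        fold_mse[f] = (resid**2).mean(axis=0)

    mean_mse = fold_mse.mean(axis=0)
    i_min = int(np.argmin(mean_mse))
    if lambda_rule == "1se":
        se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
        ok = np.where(mean_mse <= mean_mse[i_min] + se[i_min])[0]
        i_best = int(ok.min())  # grid is decreasing: smallest index = largest alpha
    else:
        i_best = i_min

    coefs = _path(xs, yr, grid[: i_best + 1], tol, max_iter)
    b_std = coefs[:, -1]
    b_std[np.abs(b_std) < 10.0 * tol] = 0.0  # convergence-level dust is not a selection
    b = np.where(live, b_std / scale, 0.0)
    return b, float(grid[i_best])
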