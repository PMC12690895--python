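import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from methylgxe import (
    count_total_models,
    fit_ols,
    gaussian_aic,
    lmg_decompose,
    select_best_model,
)
from methylgxe.model_selection import CLASS_ORDER


def test_aic_formula_properties():
    # equal RSS, one extra coefficient: AIC differs by exactly 2
    assert gaussian_aic(100, 5.0, 6) - gaussian_aic(100, 5.0, 5) == pytest.approx(2.0)
    # perfect fit: RSS floored, AIC finite
    assert np.isfinite(gaussian_aic(100, 0.0, 5))


def test_aic_matches_statsmodels(rng):
    """Cross-implementation check: our convention counts the error variance
    as a parameter, so it equals statsmodels' OLS AIC + 2."""
    for _ in range(20):
        n = int(rng.integers(30, 120))
        k = int(rng.integers(2, 6))
        x = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
        y = rng.standard_normal(n)
        rss, kk, r2, aic = fit_ols(y, x)
        res = sm.OLS(y, x).fit()
        assert aic == pytest.approx(res.aic + 2.0, abs=1e-8)
        assert r2 == pytest.approx(res.rsquared, abs=1e-10)


def test_fit_ols_singular_returns_none(rng):
    n = 30
    x = np.column_stack([np.ones(n), np.ones(n)])
    assert fit_ols(rng.standard_normal(n), x) is None


def test_count_total_models_examples():
    assert count_total_models([2], 3) == 17
    assert count_total_models([0], 94) == 94
    assert count_total_models([10, 5], 94) == 3023


def _random_vml_case(rng, n=80, n_g=2, n_e=3):
    samples = [f"s{i}" for i in range(n)]
    geno = pd.DataFrame(
        rng.binomial(2, 0.3, (n, n_g)).astype(float), index=samples,
        columns=[f"rs{j}" for j in range(n_g)],
    )
    expo = pd.DataFrame(
        rng.standard_normal((n, n_e)), index=samples,
        columns=[f"E{j}" for j in range(n_e)],
    )
    covs = pd.DataFrame(rng.standard_normal((n, 2)), index=samples, columns=["c1", "c2"])
    y = (
        0.4 * geno.iloc[:, 0] + 0.3 * expo.iloc[:, 0]
        + covs @ [0.2, -0.1] + rng.standard_normal(n)
    ).to_numpy()
    return y, geno, expo, covs


def _brute_force_winner(y, geno, expo, covs):
    """Independent enumeration: every model fitted from scratch, AIC computed
    directly from the residual sum of squares."""
    n = len(y)
    base = np.column_stack([np.ones(n), covs.to_numpy()])
    entries = []

    def aic_of(cols, k):
        x = np.column_stack([base] + cols)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = max(float(((y - x @ beta) ** 2).sum()), 1e-12)
        return n * np.log(2 * np.pi * rss / n) + n + 2 * (k + 1)

    kb = base.shape[1]
    for s in geno.columns:
        entries.append((aic_of([geno[s].to_numpy()], kb + 1), kb + 1,
                        CLASS_ORDER["G"], s, ""))
    for e in expo.columns:
        entries.append((aic_of([expo[e].to_numpy()], kb + 1), kb + 1,
                        CLASS_ORDER["E"], "", e))
    for s in geno.columns:
        for e in expo.columns:
            g, x = geno[s].to_numpy(), expo[e].to_numpy()
            entries.append((aic_of([g, x], kb + 2), kb + 2,
                            CLASS_ORDER["GE_ADD"], s, e))
            entries.append((aic_of([g, x, g * x], kb + 3), kb + 3,
                            CLASS_ORDER["GXE"], s, e))
    return min(entries)


def test_winner_matches_brute_force_enumeration(rng):
    for case in range(30):
        y, geno, expo, covs = _random_vml_case(rng)
        best = select_best_model(
            "v", y, list(geno.columns), list(expo.columns), geno, expo, covs
        )
        aic, k, order, sid, eid = _brute_force_winner(y, geno, expo, covs)
        assert best.winner.aic == pytest.approx(aic, abs=1e-8)
        assert CLASS_ORDER[best.winner.model_class] == order
        assert (best.winner.snp_id or "") == sid
        assert (best.winner.exposure_id or "") == eid


def test_model_space_size(rng):
    """2 SNPs and 3 exposures give 2 + 3 + 2*(2*3) = 17 candidate models."""
    y, geno, expo, covs = _random_vml_case(rng, n_g=2, n_e=3)
    assert count_total_models([2], 3) == 17


def test_winner_invariant_under_shift(rng):
    y, geno, expo, covs = _random_vml_case(rng)
    a = select_best_model("v", y, list(geno.columns), list(expo.columns), geno, expo, covs)
    b = select_best_model("v", y + 7.5, list(geno.columns), list(expo.columns),
                          geno, expo, covs)
    assert a.winner.model_class == b.winner.model_class
    assert a.winner.snp_id == b.winner.snp_id
    assert a.delta_r2 == pytest.approx(b.delta_r2, abs=1e-9)


def test_gxe_recovered_when_interaction_strong(rng):
    """Planted interaction (partial R^2 ~ 0.15, n=500): GxE wins in >= 90%
    of seeds."""
    wins = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        n = 500
        g = r.binomial(2, 0.3, n).astype(float)
        e = r.standard_normal(n)
        covs = pd.DataFrame(r.standard_normal((n, 2)), columns=["c1", "c2"])
        inter = (g - g.mean()) * (e - e.mean())
        y = (
            0.3 * g + 0.3 * e
            + np.sqrt(0.15 / (1 - 0.15)) / inter.std() * inter
            + covs.to_numpy() @ [0.2, 0.1] + r.standard_normal(n)
        )
        geno = pd.DataFrame({"rs0": g})
        expo = pd.DataFrame({"E0": e})
        best = select_best_model("v", y, ["rs0"], ["E0"], geno, expo, covs)
        wins += best.winner.model_class == "GXE"
    assert wins >= 18


def test_aic_nesting_vs_likelihood_gain(rng):
    """GxE beats G+E on the same pair iff the interaction improves twice the
    log-likelihood by more than 2."""
    for _ in range(20):
        y, geno, expo, covs = _random_vml_case(rng)
        n = len(y)
        base = np.column_stack([np.ones(n), covs.to_numpy()])
        g, e = geno.iloc[:, 0].to_numpy(), expo.iloc[:, 0].to_numpy()
        add = fit_ols(y, np.column_stack([base, g, e]))
        full = fit_ols(y, np.column_stack([base, g, e, g * e]))
        gain = n * np.log(add[0] / full[0])  # 2 * delta log-likelihood
        assert (full[3] < add[3]) == (gain > 2.0)


# ---------------------------------------------------------------------------
# LMG decomposition
# ---------------------------------------------------------------------------

def _lmg_oracle(y, covs, terms):
    """Independent all-orderings average of sequential R^2 increments."""
    n = len(y)
    base = np.column_stack([np.ones(n), covs])

    def r2(cols):
        x = np.column_stack([base] + cols) if cols else base
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(((y - x @ beta) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        return 1 - rss / tss

    names = list(terms)
    shares = {t: 0.0 for t in names}
    perms = list(itertools.permutations(names))
    for order in perms:
        cols = []
        prev = r2(cols)
        for t in order:
            cols = cols + [terms[t]]
            cur = r2(cols)
            shares[t] += cur - prev
            prev = cur
    return {t: v / len(perms) for t, v in shares.items()}


def test_lmg_orthogonal_terms_get_their_marginal_r2(rng):
    n = 64
    q, _ = np.linalg.qr(rng.standard_normal((n, 3)))
    t1, t2 = q[:, 0], q[:, 1]
    y = np.sqrt(0.30) * t1 * np.sqrt(n) + np.sqrt(0.20) * t2 * np.sqrt(n)
    noise = rng.standard_normal(n)
    # make noise orthogonal to both terms, then rescale to fix R^2 exactly
    noise -= q[:, :2] @ (q[:, :2].T @ noise)
    noise -= noise.mean()
    y = y + noise / noise.std() * np.sqrt(0.50)
    shares = lmg_decompose(y, np.zeros((n, 0)), {"a": t1, "b": t2})
    assert shares["a"] == pytest.approx(0.30, abs=1e-2)
    assert shares["b"] == pytest.approx(0.20, abs=1e-2)


def test_lmg_matches_factorial_oracle_and_sums(rng):
    for _ in range(25):
        n = 70
        covs = rng.standard_normal((n, 2))
        g = rng.binomial(2, 0.4, n).astype(float)
        e = rng.standard_normal(n)
        terms = {"g": g, "e": e, "gxe": g * e}
        y = covs @ [0.5, -0.2] + 0.4 * g + 0.3 * e + 0.2 * g * e + rng.standard_normal(n)
        shares = lmg_decompose(y, covs, terms)
        oracle = _lmg_oracle(y, covs, terms)
        for t in terms:
            assert shares[t] == pytest.approx(oracle[t], abs=1e-10)
            assert shares[t] >= -1e-12
        full = fit_ols(y, np.column_stack([np.ones(n), covs, g, e, g * e]))
        base = fit_ols(y, np.column_stack([np.ones(n), covs]))
        assert sum(shares.values()) == pytest.approx(full[2] - base[2], abs=1e-10)


def test_lmg_single_term_is_delta_r2(rng):
    n = 60
    covs = rng.standard_normal((n, 2))
    g = rng.binomial(2, 0.3, n).astype(float)
    y = covs @ [0.3, 0.1] + 0.5 * g + rng.standard_normal(n)
    shares = lmg_decompose(y, covs, {"g": g})
    full = fit_ols(y, np.column_stack([np.ones(n), covs, g]))
    base = fit_ols(y, np.column_stack([np.ones(n), covs]))
    assert shares["g"] == pytest.approx(full[2] - base[2], abs=1e-12)
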