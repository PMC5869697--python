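"""NB GLM fitting, dispersion profiling, LRT calibration and BH FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import brute_force_bh
from revcon.nbglm import (
    bh_fdr,
    estimate_dispersion,
    fit_nb_glm,
    irls,
    lrt,
    nb_loglik,
)
from revcon.tumour_sig import one_vs_rest_block


def _nb_draw(rng, mu, phi, size):
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


# ---------------------------------------------------------------------------
# bh_fdr


def test_bh_hand_examples():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_fdr([0.37]), [0.37])
    with pytest.raises(ValueError):
        bh_fdr([0.1, np.nan])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_matches_stepup_definition(p):
    np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)
    assert (bh_fdr(p) >= np.asarray(p) - 1e-12).all()


# ---------------------------------------------------------------------------
# fit_nb_glm / irls


def test_intercept_only_fit_recovers_sample_mean():
    rng = np.random.default_rng(0)
    y = _nb_draw(rng, 20.0, 0.1, size=(200, 30)).astype(float)
    fit = fit_nb_glm(y, np.ones((30, 1)), np.zeros(30), phi=0.1)
    # with equal offsets the NB mean MLE is the arithmetic mean
    np.testing.assert_allclose(fit.mu[:, 0], y.mean(axis=1), rtol=1e-6)


def test_poisson_limit_agrees_with_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    n = 60
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    offsets = np.log(rng.uniform(0.5, 2.0, n))
    beta_true = np.array([2.0, 0.7])
    mu = np.exp(X @ beta_true + offsets)
    y = rng.poisson(mu, size=(5, n)).astype(float)
    fit = fit_nb_glm(y, X, offsets, phi=0.0)
    for g in range(5):
        ref = sm.GLM(y[g], X, family=sm.families.Poisson(),
                     offset=offsets).fit()
        np.testing.assert_allclose(fit.beta[g], ref.params, atol=1e-6)


def test_two_group_log2fc_recovery():
    rng = np.random.default_rng(2)
    n = 100
    group = np.repeat([0.0, 1.0], n // 2)
    X = np.column_stack([np.ones(n), group])
    mu0 = 50.0
    y = _nb_draw(rng, np.where(group == 1, mu0 * 2.0, mu0), 0.1,
                 size=(300, n)).astype(float)
    fit = fit_nb_glm(y, X, np.zeros(n), phi=0.1)
    lfc = fit.beta[:, 1] / np.log(2)
    assert lfc.mean() == pytest.approx(1.0, abs=0.05)
    assert (lfc > 0).mean() > 0.99


def test_rank_deficient_design_names_columns():
    y = np.ones((3, 8))
    X = np.column_stack([np.ones(8), np.ones(8)])
    with pytest.raises(ValueError, match="dup"):
        fit_nb_glm(y, X, np.zeros(8), 0.1, colnames=("intercept", "dup"))


def test_likelihood_monotone_in_design_columns():
    rng = np.random.default_rng(3)
    n = 40
    y = _nb_draw(rng, 30.0, 0.2, size=(50, n)).astype(float)
    X1 = np.ones((n, 1))
    X2 = np.column_stack([np.ones(n), rng.normal(size=n)])
    f1 = fit_nb_glm(y, X1, np.zeros(n), 0.2)
    f2 = fit_nb_glm(y, X2, np.zeros(n), 0.2)
    assert (f2.loglik >= f1.loglik - 1e-6).all()


# ---------------------------------------------------------------------------
# dispersion


def test_dispersion_matches_finegrid_oracle():
    rng = np.random.default_rng(4)
    y = _nb_draw(rng, rng.lognormal(3, 1, 20)[:, None], 0.15,
                 size=(20, 40)).astype(float)
    X = np.ones((40, 1))
    est = estimate_dispersion(y, X, np.zeros(40))
    grid = np.linspace(0.01, 1.0, 400)
    lls = []
    for g in grid:
        _, mu, _ = irls(y, X, np.zeros(40), g)
        lls.append(nb_loglik(y, mu, g).sum())
    oracle = grid[int(np.argmax(lls))]
    assert est == pytest.approx(oracle, abs=0.01)


def test_dispersion_poisson_boundary():
    rng = np.random.default_rng(5)
    y = rng.poisson(rng.lognormal(3, 1, 400)[:, None], size=(400, 50)).astype(float)
    est = estimate_dispersion(y, np.ones((50, 1)), np.zeros(50))
    assert est <= 0.01


def test_dispersion_all_zero_errors():
    with pytest.raises(ValueError):
        estimate_dispersion(np.zeros((5, 10)), np.ones((10, 1)), np.zeros(10))


# ---------------------------------------------------------------------------
# lrt


def test_lrt_identical_models_and_chisq_oracle():
    rng = np.random.default_rng(6)
    y = _nb_draw(rng, 20.0, 0.1, size=(10, 20)).astype(float)
    X = np.ones((20, 1))
    fit = fit_nb_glm(y, X, np.zeros(20), 0.1)
    p = lrt(fit, fit, df=1)
    np.testing.assert_allclose(p, 1.0)
    assert stats.chi2.sf(3.841, 1) == pytest.approx(0.050, abs=5e-4)


def test_lrt_rejects_non_nested():
    rng = np.random.default_rng(7)
    y = _nb_draw(rng, 20.0, 0.1, size=(5, 20)).astype(float)
    x = rng.normal(size=20)
    f1 = fit_nb_glm(y, np.column_stack([np.ones(20), x]), np.zeros(20), 0.1)
    f2 = fit_nb_glm(y, x[:, None], np.zeros(20), 0.1)
    with pytest.raises(ValueError):
        lrt(f2, f1, df=1)


def test_lrt_null_pvalues_uniform():
    """Two-group LRT on null NB data is calibrated (KS vs U(0,1))."""
    rng = np.random.default_rng(8)
    n = 50
    phi = 0.1
    mu = rng.lognormal(3.5, 1.0, 2000)[:, None]
    y = _nb_draw(rng, mu, phi, size=(2000, n)).astype(float)
    group = np.repeat([0.0, 1.0], n // 2)
    Xf = np.column_stack([np.ones(n), group])
    full = fit_nb_glm(y, Xf, np.zeros(n), phi)
    red = fit_nb_glm(y, Xf[:, :1], np.zeros(n), phi)
    p = lrt(full, red, df=1)
    assert stats.kstest(p, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# one_vs_rest_block fast path vs general fitter


def test_one_vs_rest_matches_general_glm():
    rng = np.random.default_rng(9)
    nb = 12
    counts = _nb_draw(rng, rng.lognormal(3, 1, 40)[:, None], 0.1,
                      size=(40, nb + 2)).astype(float)
    offsets = np.log(counts.sum(axis=0))
    bg = np.arange(nb)
    cols = np.array([nb, nb + 1])
    lfc_fast, p_fast = one_vs_rest_block(
        counts, offsets, np.broadcast_to(bg, (2, nb)), cols, 0.1)
    X = np.column_stack([np.ones(nb + 1), np.zeros(nb + 1)])
    X[-1, 1] = 1.0
    for j, c in enumerate(cols):
        used = np.concatenate([bg, [c]])
        full = fit_nb_glm(counts[:, used], X, offsets[used], 0.1)
        red = fit_nb_glm(counts[:, used], X[:, :1], offsets[used], 0.1)
        p_gen = lrt(full, red, 1)
        ok = counts[:, c] > 0
        np.testing.assert_allclose(lfc_fast[ok, j],
                                   (full.beta[:, 1] / np.log(2))[ok], atol=1e-6)
        np.testing.assert_allclose(p_fast[:, j], p_gen, atol=1e-6)
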