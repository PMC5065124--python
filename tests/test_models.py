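"""Interaction estimators against closed forms and an independent ML oracle."""

import numpy as np
import pandas as pd
import pytest

from gxescan.glm import batched_logistic, logistic_fit
from gxescan.models import build_design, eb_combine, fit_case_only, fit_interaction_cc
from conftest import make_cohort


def _expand_2x2x2(counts):
    """counts[g][e][y] -> per-subject arrays (y, g, e)."""
    ys, gs, es = [], [], []
    for g in (0, 1):
        for e in (0, 1):
            for y in (0, 1):
                k = counts[g][e][y]
                ys += [y] * k
                gs += [g] * k
                es += [e] * k
    return np.array(ys, float), np.array(gs, float), np.array(es, float)


def saturated_interaction_oracle(counts):
    """log[(OR of E in G=1) / (OR of E in G=0)] from raw cross-products."""
    def or_within(g):
        c = counts[g]
        return (c[1][1] * c[0][0]) / (c[1][0] * c[0][1])

    return np.log(or_within(1) / or_within(0))


def test_saturated_2x2x2_equals_cross_product_ratio():
    rng = np.random.default_rng(0)
    for _ in range(20):
        counts = [[[int(rng.integers(5, 60)) for _ in range(2)] for _ in range(2)] for _ in range(2)]
        y, g, e = _expand_2x2x2(counts)
        X = np.column_stack([np.ones_like(y), g, e, g * e])
        beta, _, _, conv = logistic_fit(y, X)
        assert conv
        assert beta[3] == pytest.approx(saturated_interaction_oracle(counts), abs=1e-6)


def test_matches_independent_ml_oracle():
    """Full interaction model coefficients agree with statsmodels Newton ML."""
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    n_compared = 0
    for trial in range(5):
        n = 800
        cohort = make_cohort(n, n_cases=400, seed=trial)
        d = rng.binomial(2, 0.3, n).astype(float)
        fit = fit_interaction_cc(cohort, d, stratum="t", min_mac=0)
        y, X, names, _ = build_design(cohort, d)
        res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12)
        # quasi-separated draws (a sparse genotype x heavy-drinking cell) are
        # flagged by both fitters; the ML solutions are only comparable when
        # both converge
        assert fit.converged == bool(res.mle_retvals["converged"])
        if not fit.converged:
            continue
        n_compared += 1
        assert np.abs(fit.params.to_numpy() - res.params).max() < 1e-6
        assert fit.loglik == pytest.approx(res.llf, abs=1e-8)
        assert fit.aic == pytest.approx(res.aic, abs=1e-6)
        assert np.abs(fit.se.to_numpy() - res.bse).max() < 1e-5
    assert n_compared >= 3


def test_dosage_rescaling_halves_g_terms():
    rng = np.random.default_rng(2)
    n = 800
    cohort = make_cohort(n, n_cases=400, seed=9)
    d = rng.binomial(2, 0.4, n).astype(float)
    f1 = fit_interaction_cc(cohort, d, min_mac=0)
    f2 = fit_interaction_cc(cohort, 2.0 * d, min_mac=0)
    assert f1.converged and f2.converged
    # doubling the dosage is allowed because [0,2] scaling is not enforced in the model
    for term in ("G", "G:E1", "G:E2"):
        assert f2.params[term] == pytest.approx(f1.params[term] / 2.0, rel=1e-6)
    assert f2.params["E1"] == pytest.approx(f1.params["E1"], rel=1e-6)


def test_degenerate_inputs_raise():
    cohort = make_cohort(100, n_cases=0, seed=3)
    d = np.random.default_rng(0).binomial(2, 0.3, 100).astype(float)
    with pytest.raises(ValueError, match="cases and controls"):
        fit_interaction_cc(cohort, d)
    cohort2 = make_cohort(100, n_cases=50, seed=4)
    with pytest.raises(ValueError, match="constant"):
        fit_interaction_cc(cohort2, np.ones(100))


def test_separation_flagged_not_raised():
    cohort = make_cohort(60, n_cases=30, seed=5)
    d = cohort["status"].to_numpy().astype(float) * 2.0  # perfect separation
    d[0] = 1.0
    fit = fit_interaction_cc(cohort, d, min_mac=0)
    assert not fit.converged


def test_batched_matches_single_fit():
    rng = np.random.default_rng(6)
    n, m = 250, 8
    X0 = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    singles, Xs = [], []
    y = rng.integers(0, 2, n).astype(float)
    for j in range(m):
        X = np.column_stack([X0, rng.binomial(2, 0.3, n)])
        Xs.append(X)
        singles.append(logistic_fit(y, X)[0])
    fit = batched_logistic(y, np.stack(Xs))
    assert np.abs(fit.beta - np.stack(singles)).max() < 1e-8
    assert fit.converged.all()


def test_case_only_2x2_oracle():
    """Binary hard genotype: CO beta equals the log cross-product ratio of
    exposure by genotype among cases."""
    counts = {(0, 0): 80, (0, 1): 40, (1, 0): 30, (1, 1): 45}  # (g, e) -> n cases
    g = np.concatenate([np.full(v, k[0], float) for k, v in counts.items()])
    e = np.concatenate([np.full(v, k[1], float) for k, v in counts.items()])
    n = g.size
    cohort = make_cohort(n, n_cases=n, seed=7)
    cohort["alcohol_cat"] = e
    res = fit_case_only(cohort, g, covariates=())
    oracle = np.log(counts[(1, 1)] * counts[(0, 0)] / (counts[(1, 0)] * counts[(0, 1)]))
    assert res.beta == pytest.approx(oracle, abs=1e-6)
    assert res.method == "case_only"


def test_case_only_needs_two_levels():
    cohort = make_cohort(50, n_cases=50, seed=8)
    cohort["alcohol_cat"] = 1.0
    with pytest.raises(ValueError, match="exposure levels"):
        fit_case_only(cohort, np.random.default_rng(1).binomial(2, 0.3, 50).astype(float), covariates=())


def test_eb_limits_and_fixed_point():
    cc, co = 0.30, 0.10
    # no G-E dependence evidence -> case-only
    assert eb_combine(cc, 0.04, co, 0.01, 0.0, 0.001).beta == pytest.approx(co)
    # overwhelming dependence -> case-control
    assert eb_combine(cc, 0.04, co, 0.01, 50.0, 0.001).beta == pytest.approx(cc, abs=1e-4)
    # agreement is a fixed point regardless of theta
    for theta in (0.0, 0.3, 5.0):
        assert eb_combine(0.2, 0.04, 0.2, 0.01, theta, 0.01).beta == pytest.approx(0.2)
    with pytest.raises(ValueError):
        eb_combine(0.1, 0.0, 0.1, 0.01, 0.1, 0.01)


def test_eb_between_estimates_with_positive_variance():
    res = eb_combine(0.4, 0.05, 0.1, 0.02, 0.25, 0.01)
    assert min(0.1, 0.4) <= res.beta <= max(0.1, 0.4)
    assert res.se > 0
    assert 0 <= res.p <= 1
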