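"""Fixed-effects pooling, Woolf heterogeneity, lambda and Q-Q quantiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gxescan.meta import fixed_effects_meta, genomic_lambda, qq_points, woolf_heterogeneity


def test_single_stratum_identity():
    res = fixed_effects_meta([(0.3, 0.1)])
    assert (res.beta, res.se, res.k) == (0.3, 0.1, 1)
    assert res.Q == 0.0 and res.het_p == 1.0


def test_hand_inverse_variance_arithmetic():
    res = fixed_effects_meta([(0.2, 0.1), (0.4, 0.2)])
    assert res.beta == pytest.approx(0.24, abs=1e-12)          # weights 100, 25
    assert res.se == pytest.approx(1.0 / np.sqrt(125.0), abs=1e-12)
    assert res.Q == pytest.approx(0.8, abs=1e-12)              # 100*0.04^2 + 25*0.16^2
    assert res.df == 1


def test_order_invariance_and_range():
    est = [(0.1, 0.3), (0.5, 0.2), (-0.2, 0.4)]
    a = fixed_effects_meta(est)
    b = fixed_effects_meta(est[::-1])
    assert a.beta == pytest.approx(b.beta)
    assert min(e[0] for e in est) <= a.beta <= max(e[0] for e in est)


@given(
    st.lists(
        st.tuples(st.floats(-3, 3), st.floats(0.01, 5)),
        min_size=1, max_size=12,
    )
)
@settings(max_examples=100, deadline=None)
def test_pooled_within_stratum_range(est):
    res = fixed_effects_meta(est, drop_unstable=False)
    betas = [e[0] for e in est]
    assert min(betas) - 1e-9 <= res.beta <= max(betas) + 1e-9
    assert res.se <= min(e[1] for e in est) + 1e-9


def test_unstable_strata_dropped():
    res = fixed_effects_meta([(0.2, 0.1), (25.0, 0.1), (0.3, 50.0)])
    assert res.k == 1
    assert res.beta == pytest.approx(0.2)


def test_woolf_identical_betas():
    Q, df, p = woolf_heterogeneity([(0.25, 0.1), (0.25, 0.2), (0.25, 0.15)])
    assert Q == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        woolf_heterogeneity([(0.2, 0.1)])


def test_q_null_distribution():
    """Homogeneous strata: Q ~ chi2(k-1) over replicates."""
    rng = np.random.default_rng(0)
    k, reps = 5, 400
    ses = np.array([0.1, 0.15, 0.2, 0.12, 0.3])
    qs = []
    for _ in range(reps):
        betas = rng.normal(0.3, ses)
        Q, df, _ = woolf_heterogeneity(list(zip(betas, ses)))
        qs.append(Q)
    ks = stats.kstest(qs, stats.chi2(k - 1).cdf)
    assert ks.pvalue > 0.01


def test_lambda_examples():
    assert genomic_lambda(np.full(1001, 0.5)) == pytest.approx(1.0, abs=1e-12)
    rng = np.random.default_rng(1)
    u = rng.uniform(size=100_000)
    assert genomic_lambda(u) == pytest.approx(1.0, abs=0.02)
    inflated = stats.chi2.sf(1.2 * stats.chi2.isf(u, 1), 1)
    assert genomic_lambda(inflated) == pytest.approx(1.2, abs=0.025)
    with pytest.raises(ValueError):
        genomic_lambda([])
    with pytest.raises(ValueError):
        genomic_lambda([0.0, 0.5])


def test_qq_points_definition():
    exp_q, obs_q = qq_points([0.1, 0.5, 0.9])
    assert np.allclose(exp_q, np.sort(-np.log10(np.array([1, 3, 5]) / 6.0)))
    assert np.allclose(obs_q, np.sort(-np.log10([0.9, 0.5, 0.1])))
    assert np.all(np.diff(exp_q) >= 0) and np.all(np.diff(obs_q) >= 0)


def test_qq_uniform_on_diagonal():
    rng = np.random.default_rng(2)
    exp_q, obs_q = qq_points(rng.uniform(size=20_000))
    body = slice(0, 19_000)  # the extreme tail is noisy by construction
    assert np.abs(exp_q[body] - obs_q[body]).max() < 0.05


def test_split_halves_meta_approximates_full_fit():
    """Meta over disjoint halves of one homogeneous cohort ~ full-cohort fit."""
    from gxescan.models import fit_interaction_cc
    from gxescan.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_studies=1, n_cases=10_000, n_controls=10_000,
        beta_GxE1=np.log(0.7), seed=13,
    )
    cohort, gm = simulate_cohort(cfg)
    d = gm.dosage[0]
    full = fit_interaction_cc(cohort, d, include_sex=True)
    rng = np.random.default_rng(0)
    half = rng.permutation(len(cohort)) < len(cohort) // 2
    ests = []
    for sel in (half, ~half):
        f = fit_interaction_cc(cohort.iloc[np.flatnonzero(sel)], d[sel], include_sex=True)
        ests.append((f.params["G:E1"], f.se["G:E1"]))
    pooled = fixed_effects_meta(ests)
    assert abs(pooled.beta - full.params["G:E1"]) / abs(full.params["G:E1"]) < 0.05
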