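"""Weighted-alpha allocation and the two-step screen/test bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gxescan.cocktail import allocate_weighted_alpha, cocktail_scan, screen_variants
from gxescan.simulate import SimulationConfig, simulate_cohort, spike_signal


def test_doubling_scheme_thresholds():
    th, grp = allocate_weighted_alpha(35, base_group_size=5, alpha=0.05)
    assert np.allclose(th[:5], 0.005)                  # group 1: 5 variants
    assert np.allclose(th[5:15], 0.00125)              # group 2: 10 variants
    assert np.allclose(th[15:35], 3.125e-4)            # group 3: 20 variants
    assert grp[:5].tolist() == [1] * 5
    assert grp[34] == 3


def test_budget_below_alpha():
    th, _ = allocate_weighted_alpha(10_000, base_group_size=5, alpha=0.05)
    assert th.sum() < 0.05
    assert np.all(np.diff(th) <= 1e-18)  # non-increasing in rank


@given(st.integers(1, 2000), st.integers(1, 20), st.floats(0.001, 0.2))
@settings(max_examples=80, deadline=None)
def test_partition_property(m, B, alpha):
    th, grp = allocate_weighted_alpha(m, B, alpha)
    assert th.shape == (m,) and grp.shape == (m,)
    assert np.all(th > 0)
    assert th.sum() < alpha
    # group sizes follow B * 2^(j-1) except the truncated last group
    for j in range(1, grp.max()):
        assert (grp == j).sum() == B * 2 ** (j - 1)


def test_invalid_allocation_inputs():
    with pytest.raises(ValueError):
        allocate_weighted_alpha(10, 0, 0.05)
    with pytest.raises(ValueError):
        allocate_weighted_alpha(10, 5, 1.5)


def test_winner_rule_and_co_routing():
    """Strong marginal effect: variant must rank first, screen via the
    marginal statistic and route to the case-only test."""
    cfg = SimulationConfig(
        n_studies=2, n_cases=1000, n_controls=1000, n_variants=60,
        beta_G=0.5, seed=21,
    )
    cohort, gm = simulate_cohort(cfg)
    rec = cocktail_scan(cohort, gm).set_index("id")
    row = rec.loc["var00000"]
    assert row["winner"] == "marginal"
    assert row["test_method"] == "case_only"
    assert row["screen_stat"] == pytest.approx(abs(row["z_marginal"]))
    assert row["rank"] <= 5
    assert row["group_index"] == 1


def test_screen_stat_is_max_of_z():
    cfg = SimulationConfig(n_studies=2, n_cases=300, n_controls=300, n_variants=20, seed=22)
    cohort, gm = simulate_cohort(cfg)
    rec = screen_variants(cohort, gm)
    assert np.allclose(
        rec["screen_stat"],
        np.maximum(np.abs(rec["z_marginal"]), np.abs(rec["z_corr"])),
    )
    routed = np.where(rec["winner"] == "marginal", "case_only", "case_control")
    assert (rec["test_method"] == routed).all()


def test_tied_screens_rank_by_position():
    """Duplicate dosage columns give identical screen statistics; ranking
    must fall back to genomic position deterministically."""
    cfg = SimulationConfig(n_studies=1, n_cases=200, n_controls=200, n_variants=6, seed=23)
    cohort, gm = simulate_cohort(cfg)
    gm.dosage[3] = gm.dosage[1]
    rec = cocktail_scan(cohort, gm).set_index("id")
    assert rec.loc["var00001", "rank"] + 1 == rec.loc["var00003", "rank"]


def test_weak_screens_get_stringent_threshold():
    """A pure interaction with its marginal association cancelled by an
    opposing main effect screens poorly, lands in a late group with a
    threshold far more stringent than group 1, and is missed by the
    two-step procedure even though the single-step scan sees it clearly."""
    from gxescan.scan import interaction_scan

    b_int = np.log(0.6)
    cfg = SimulationConfig(
        n_studies=2, n_cases=1500, n_controls=1500, n_variants=200,
        beta_G=-b_int * 0.45,   # cancels the exposure-averaged marginal effect
        ge_corr_beta=0.3,       # offsets the case-driven G-E correlation in the combined sample
        beta_GxE1=b_int, seed=24,
    )
    cohort, gm = simulate_cohort(cfg)
    rec = cocktail_scan(cohort, gm).set_index("id")
    row = rec.loc["var00000"]
    assert row["p_marginal"] > 0.05 and row["p_corr"] > 0.05
    assert row["group_index"] > 1
    assert row["alpha_threshold"] < 0.005
    assert not row["significant"]
    scan = interaction_scan(cohort, gm).set_index("id")
    assert scan.loc["var00000", "p_GxE1"] < 1e-4
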