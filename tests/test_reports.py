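"""Genotype-stratified OR tables and the joint-reference layout."""

import numpy as np
import pandas as pd
import pytest

from gxescan.reports import genotype_stratified_or, joint_reference_or
from gxescan.simulate import SimulationConfig, simulate_cohort
from conftest import make_cohort, make_matrix


def _cohort_from_counts(counts):
    """counts[(genotype, exposure, status)] -> cohort + matching matrix."""
    rows = []
    for (g, e, y), k in counts.items():
        rows += [(g, e, y)] * k
    arr = np.array(rows, dtype=float)
    n = arr.shape[0]
    cohort = make_cohort(n, seed=0)
    cohort["status"] = arr[:, 2].astype(int)
    cohort["alcohol_cat"] = arr[:, 1]
    cohort["alcohol_gday"] = np.where(arr[:, 1] == 1, 10.0, 0.0)
    gm = make_matrix(arr[:, 0][None, :])
    return cohort, gm


def test_crude_or_matches_cross_product():
    """Unadjusted within-genotype OR equals the count cross-product; the
    genotype-2 row uses case/control counts (425,387)/(434,590)."""
    counts = {}
    table = {
        0: ((1365, 1593), (1638, 1717)),
        1: ((1495, 1574), (1646, 2002)),
        2: ((425, 387), (434, 590)),
    }
    # desk-scale: divide the printed-scale counts by 10 to keep the fit fast
    for g, ((ca0, co0), (ca1, co1)) in table.items():
        counts[(g, 0, 1)] = ca0 // 10
        counts[(g, 0, 0)] = co0 // 10
        counts[(g, 1, 1)] = ca1 // 10
        counts[(g, 1, 0)] = co1 // 10
    cohort, gm = _cohort_from_counts(counts)
    tab = genotype_stratified_or(cohort, gm, "v0", covariates=(), scheme="none").set_index("genotype")
    for g in (0, 1, 2):
        a, b = counts[(g, 1, 1)], counts[(g, 1, 0)]
        c, d = counts[(g, 0, 1)], counts[(g, 0, 0)]
        oracle = (a * d) / (b * c)
        assert tab.loc[g, "or"] == pytest.approx(oracle, rel=1e-5)
    assert (tab["or_ref"] == 1.0).all()
    # count bookkeeping: report covers the full analysis sample
    total = tab[["n_cases_ref", "n_controls_ref", "n_cases_exp", "n_controls_exp"]].to_numpy().sum()
    assert total == len(cohort)


def test_null_simulation_ors_near_one():
    cfg = SimulationConfig(n_studies=2, n_cases=2000, n_controls=2000,
                           beta_E1=0.0, beta_E2=0.0, seed=41)
    cohort, gm = simulate_cohort(cfg)
    tab = genotype_stratified_or(cohort, gm, "var00000")
    assert np.all(np.abs(np.log(tab["or"])) < 0.5)
    assert (tab["p"] > 0.001).all()  # no spurious strong association


def test_constant_exposure_errors():
    counts = {(g, 0, y): 30 for g in (0, 1, 2) for y in (0, 1)}
    cohort, gm = _cohort_from_counts(counts)
    with pytest.raises(ValueError, match="contrast"):
        genotype_stratified_or(cohort, gm, "v0", covariates=(), scheme="none")


def test_joint_reference_cell_is_unity():
    cfg = SimulationConfig(n_studies=2, n_cases=500, n_controls=500, seed=42)
    cohort, gm = simulate_cohort(cfg)
    tab = joint_reference_or(cohort, gm, "var00000")
    ref = tab[(tab.genotype == 0) & (tab.exposure == 0)].iloc[0]
    assert ref["or"] == 1.0 and ref["ci_lower"] == 1.0 and ref["ci_upper"] == 1.0
    assert tab["control_prevalence"].sum() == pytest.approx(1.0, abs=1e-9)
    assert len(tab) == 6


def test_multiplicative_structure_without_interaction():
    """No-interaction generator: OR(g,e) ~ OR(g,0) x OR(0,e)."""
    cfg = SimulationConfig(n_studies=1, n_cases=6000, n_controls=6000,
                           beta_G=0.25, beta_E1=np.log(0.8), maf=0.5, seed=43)
    cohort, gm = simulate_cohort(cfg)
    tab = joint_reference_or(cohort, gm, "var00000", scheme="none").set_index(["genotype", "exposure"])
    for g in (1, 2):
        lhs = np.log(tab.loc[(g, 1), "or"])
        rhs = np.log(tab.loc[(g, 0), "or"]) + np.log(tab.loc[(0, 1), "or"])
        assert lhs == pytest.approx(rhs, abs=0.25)


def test_spiked_interaction_breaks_multiplicativity_quadratically():
    """Log-additive dosage: the (g=2, e=1) cell departs from the product of
    its margins by the squared per-allele interaction OR (0.8^2 = 0.64)."""
    cfg = SimulationConfig(n_studies=1, n_cases=8000, n_controls=8000,
                           beta_GxE1=np.log(0.8), maf=0.5, seed=44)
    cohort, gm = simulate_cohort(cfg)
    tab = joint_reference_or(cohort, gm, "var00000", scheme="none").set_index(["genotype", "exposure"])
    ratio = tab.loc[(2, 1), "or"] / (tab.loc[(2, 0), "or"] * tab.loc[(0, 1), "or"])
    assert np.log(ratio) == pytest.approx(2 * np.log(0.8), abs=0.25)
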