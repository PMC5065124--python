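"""Exact HWE test against integer enumeration, and the variant filters."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gxescan.qc import QCThresholds, hwe_exact_test, qc_filter
from conftest import make_cohort, make_matrix


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    n_major = 2 * n - n_minor
    if n_minor == 0:
        return 1.0
    weights = {}
    for h in range(n_minor % 2, min(n_minor, n_major) + 1, 2):
        a = (n_minor - h) // 2
        b = n - h - a
        # multinomial count of genotype configurations x 2^h phasings
        weights[h] = Fraction(comb(n, h) * comb(n - h, a) * 2**h)
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def test_monomorphic_p_is_one():
    assert hwe_exact_test(100, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 100) == 1.0


def test_balanced_table_matches_enumeration():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(hwe_enumeration_oracle(25, 50, 25), rel=1e-9)


def test_het_deficit_more_extreme():
    assert hwe_exact_test(60, 20, 20) < hwe_exact_test(50, 40, 10)


def test_exhaustive_agreement_small_tables():
    """Every table with total n <= 30 agrees with integer enumeration."""
    for n in range(1, 31):
        for n_alt_hom in range(n + 1):
            for n_het in range(n - n_alt_hom + 1):
                n_ref_hom = n - n_alt_hom - n_het
                got = hwe_exact_test(n_ref_hom, n_het, n_alt_hom)
                want = hwe_enumeration_oracle(n_ref_hom, n_het, n_alt_hom)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (n_ref_hom, n_het, n_alt_hom)


def test_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 2)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
@settings(max_examples=50, deadline=None)
def test_allele_label_symmetry(a, h, b):
    if a + h + b == 0:
        return
    assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a), rel=1e-9)


# ---------------------------------------------------------------- filters


def _cohort_for(n, seed=0):
    return make_cohort(n, n_cases=n // 2, seed=seed)


def test_fail_reasons():
    rng = np.random.default_rng(0)
    n = 400
    rows = []
    # v0: rare variant, expected MAF ~0.02
    rows.append(rng.binomial(2, 0.02, n).astype(float))
    # v1: imputed with low r2
    rows.append(rng.binomial(2, 0.3, n).astype(float))
    # v2: call rate 0.95
    v = rng.binomial(2, 0.3, n).astype(float)
    v[: int(0.05 * n)] = np.nan
    rows.append(v)
    # v3: gross HWE violation in controls (all het)
    rows.append(np.ones(n))
    # v4: clean common variant
    rows.append(rng.binomial(2, 0.31, n).astype(float))
    gm = make_matrix(np.vstack(rows), typed=[True, False, True, True, True], r2=[1, 0.2, 1, 1, 1])
    cohort = _cohort_for(n)
    kept, report = qc_filter(gm, cohort)
    reasons = dict(zip(report["id"], report["fail_reasons"]))
    assert "low_maf" in reasons["v0"]
    assert "low_imputation_r2" in reasons["v1"]
    assert "low_call_rate" in reasons["v2"]
    assert "hwe_fail" in reasons["v3"]
    assert reasons["v4"] == ""
    assert kept.variants["id"].tolist() == ["v4"]
    assert (report["pass_flag"] == (report["fail_reasons"] == "")).all()


def test_filter_idempotent():
    rng = np.random.default_rng(3)
    gm = make_matrix(rng.binomial(2, rng.uniform(0.02, 0.5, size=(20, 1)), size=(20, 300)).astype(float))
    cohort = _cohort_for(300)
    kept, _ = qc_filter(gm, cohort)
    kept2, rep2 = qc_filter(kept, cohort)
    assert kept2.n_variants == kept.n_variants
    assert rep2["pass_flag"].all()


def test_maf_allele_swap_invariant():
    rng = np.random.default_rng(4)
    d = rng.binomial(2, 0.2, size=(5, 200)).astype(float)
    cohort = _cohort_for(200)
    _, rep_a = qc_filter(make_matrix(d), cohort)
    _, rep_b = qc_filter(make_matrix(2.0 - d), cohort)
    assert np.allclose(rep_a["maf"], rep_b["maf"])
    assert np.allclose(rep_a["hwe_p"], rep_b["hwe_p"])


def test_per_study_mac_gate():
    rng = np.random.default_rng(5)
    n = 400
    d = rng.binomial(2, 0.25, size=(1, n)).astype(float)
    d[0, 200:] = 0.0  # second study monomorphic -> per-study MAC 0
    cohort = _cohort_for(n)
    cohort.loc[200:, "study"] = "study01"
    _, report = qc_filter(make_matrix(d), cohort)
    assert "low_mac" in report["fail_reasons"].iloc[0]


def test_no_controls_error():
    gm = make_matrix(np.ones((1, 10)))
    cohort = make_cohort(10, n_cases=10)
    with pytest.raises(ValueError, match="no controls"):
        qc_filter(gm, cohort)
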