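import numpy as np
import pandas as pd
import pytest

from gxescan.genio import GenotypeMatrix
from gxescan.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """3 studies x 150/150 with a modest spiked interaction at var00000."""
    cfg = SimulationConfig(
        n_studies=3, n_cases=150, n_controls=150, n_variants=12,
        beta_GxE1=np.log(0.6), seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """2 studies x 200/200, fully null disease model."""
    cfg = SimulationConfig(
        n_studies=2, n_cases=200, n_controls=200, n_variants=8,
        beta_E1=0.0, beta_E2=0.0, seed=7,
    )
    return simulate_cohort(cfg)


def make_matrix(dosage, typed=True, r2=1.0, chrom="1", start_pos=100):
    """Genotype matrix straight from a dosage array, for targeted QC tests."""
    dosage = np.asarray(dosage, dtype=float)
    m = dosage.shape[0]
    typed = np.broadcast_to(np.asarray(typed, dtype=bool), m)
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), m)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + np.arange(m),
            "id": [f"v{i}" for i in range(m)],
            "ref": "A",
            "alt": "G",
            "typed": typed,
            "imputation_r2": r2,
        }
    )
    return GenotypeMatrix(variants=variants, dosage=dosage,
                          samples=[f"s{j}" for j in range(dosage.shape[1])])


def make_cohort(n, n_cases=None, study="study00", seed=0):
    """Minimal cohort frame with noise covariates (no disease structure)."""
    rng = np.random.default_rng(seed)
    status = np.zeros(n, dtype=int)
    if n_cases:
        status[:n_cases] = 1
    gday = rng.uniform(0, 40, n)
    from gxescan.exposures import harmonize_alcohol

    return pd.DataFrame(
        {
            "subject_id": [f"s{j}" for j in range(n)],
            "study": study,
            "sex": rng.choice(["male", "female"], n),
            "age": rng.normal(60, 8, n),
            "status": status,
            "alcohol_gday": gday,
            "alcohol_cat": harmonize_alcohol(gday),
            "smoke_ever": rng.integers(0, 2, n),
            "pack_years": 0.0,
            "pc1": rng.normal(size=n),
            "pc2": rng.normal(size=n),
            "pc3": rng.normal(size=n),
        }
    )
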