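"""Shared study conditions for the analysis scripts.

One synthetic consortium stands in for the multi-study case-control data:
14 study strata totalling ~8,000 cases and ~8,750 controls (the scale of the
harmonised alcohol analysis), a common causal variant at MAF 0.33 carrying a
protective light-to-moderate-drinking interaction, and 399 null variants.
All scripts derive their inputs from this one configuration and master seed.
"""

from pathlib import Path

import numpy as np

from gxescan.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch" / "analysis"

MASTER_SEED = 20160101
SPIKED_VARIANT = "var00000"
INTERACTION_OR = 0.78          # per allele, light-to-moderate vs non/occasional

CONSORTIUM = SimulationConfig(
    n_studies=14,
    n_cases=575,
    n_controls=625,
    n_variants=400,
    maf=0.33,
    beta_GxE1=float(np.log(INTERACTION_OR)),
    seed=MASTER_SEED,
)

NULL_CONSORTIUM = SimulationConfig(
    n_studies=14,
    n_cases=575,
    n_controls=625,
    n_variants=400,
    maf=0.33,
    seed=MASTER_SEED,
)


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS


def scratchdir() -> Path:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    return SCRATCH
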