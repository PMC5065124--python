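"""Synthetic multi-study case-control consortium generator.

Emulates the design of a genotype-imputed colorectal-cancer consortium: a
configurable number of study strata, Hardy-Weinberg genotypes at a chosen
minor-allele frequency, a three-level alcohol exposure (non/occasional,
light-to-moderate, heavy drinking), binary/continuous smoking variables, and
disease status drawn from a logistic model with configurable genotype main
effect, exposure main effects and genotype-by-exposure (GxE) interaction
log-odds-ratios.  Cases and controls are filled retrospectively per study by
rejection sampling, so the per-study case/control counts are exact.

The generator is the ground-truth test bed for every downstream stage: the
true interaction coefficients are known, genotype-exposure dependence can be
switched on (`ge_corr_beta`), and everything is reproducible from one master
seed with per-study derived streams.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .genio import GenotypeMatrix

__all__ = ["SimulationConfig", "SimulationError", "simulate_cohort", "spike_signal"]

_REJECTION_CAP = 10_000_000  # candidate draws per study before giving up


class SimulationError(RuntimeError):
    """Requested case/control counts unreachable under the disease model."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated consortium.

    Defaults mirror a 14-study alcohol-analysis consortium: roughly 8,000
    cases and 8,800 controls overall, a common causal variant with MAF 0.33,
    exposure category probabilities (non/occasional, light-to-moderate,
    heavy) of about (0.47, 0.45, 0.08), and exposure main-effect odds ratios
    0.91 (light-to-moderate) and 1.22 (heavy) against non/occasional
    drinking.  All effect parameters are on the log-odds-ratio scale.

    `ge_corr_beta` is the log-OR of drinking (either non-reference category)
    per copy of the variant allele in the exposure model; 0 means
    genotype-exposure independence in the source population.
    """

    n_studies: int = 14
    n_cases: int = 575        # per study
    n_controls: int = 625     # per study
    maf: float = 0.33
    exposure_probs: tuple[float, float, float] = (0.47, 0.45, 0.08)
    beta_G: float = 0.0
    beta_E1: float = math.log(0.91)
    beta_E2: float = math.log(1.22)
    beta_GxE1: float = 0.0
    beta_GxE2: float = 0.0
    ge_corr_beta: float = 0.0
    baseline_logit: float = -2.2
    sex_ratio: float = 0.5    # fraction male
    seed: int = 0
    # genome layout: `n_variants` dosage columns, one of which (causal_index)
    # is the variant wired into the disease model; the rest are null.
    n_variants: int = 1
    causal_index: int = 0
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    imputed_fraction: float = 0.3
    imputation_r2_range: tuple[float, float] = (0.6, 1.0)
    # smoking nuisance variables (not wired into the disease model by default)
    smoke_ever_prob: float = 0.5
    smoke_beta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        probs = np.asarray(self.exposure_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any():
            raise ValueError("exposure_probs must be 3 nonnegative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"exposure_probs must sum to 1, got {probs.sum()!r}")
        for name in ("n_studies", "n_cases", "n_controls", "n_variants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.causal_index < self.n_variants):
            raise ValueError("causal_index out of range")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")


def _study_rng(seed: int, study_index: int) -> np.random.Generator:
    """Stream for one study, derived from the master seed by a fixed offset
    so any stratum is independently reproducible."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, study_index)))


def _genome_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))


def _draw_exposure(rng: np.random.Generator, g: np.ndarray, probs: np.ndarray, ge_corr_beta: float) -> np.ndarray:
    """Exposure category via a multinomial logit with a linear dosage term.

    P(E=k | G) ∝ p_k * exp(ge_corr_beta * G * 1[k > 0]); with ge_corr_beta=0
    this reduces to the configured category probabilities.
    """
    score = np.log(np.clip(probs, 1e-300, None))[None, :] + ge_corr_beta * g[:, None] * np.array([0.0, 1.0, 1.0])
    w = np.exp(score - score.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(g.shape[0])
    return (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1)


def _sample_study(cfg: SimulationConfig, study_index: int) -> dict[str, np.ndarray]:
    rng = _study_rng(cfg.seed, study_index)
    probs = np.asarray(cfg.exposure_probs, dtype=float)
    need = {1: cfg.n_cases, 0: cfg.n_controls}
    kept: dict[str, list[np.ndarray]] = {k: [] for k in ("g", "e", "sex", "age", "smoke", "pky", "pc", "status")}
    drawn = 0
    batch = max(2048, 4 * (cfg.n_cases + cfg.n_controls))
    while need[1] > 0 or need[0] > 0:
        if drawn >= _REJECTION_CAP:
            raise SimulationError(
                f"study {study_index}: drew {drawn} candidates but still need "
                f"{need[1]} cases / {need[0]} controls; baseline_logit="
                f"{cfg.baseline_logit} makes the requested counts unreachable"
            )
        g = rng.binomial(2, cfg.maf, size=batch).astype(float)
        e = _draw_exposure(rng, g, probs, cfg.ge_corr_beta)
        sex = (rng.random(batch) < cfg.sex_ratio).astype(int)  # 1 = male
        age = rng.normal(62.0, 8.0, size=batch)
        smoke = (rng.random(batch) < cfg.smoke_ever_prob).astype(int)
        pky = np.where(smoke == 1, rng.gamma(2.0, 10.0, size=batch), 0.0)
        pc = rng.normal(0.0, 1.0, size=(batch, 3))
        e1 = (e == 1).astype(float)
        e2 = (e == 2).astype(float)
        lp = (
            cfg.baseline_logit
            + cfg.beta_G * g
            + cfg.beta_E1 * e1
            + cfg.beta_E2 * e2
            + cfg.beta_GxE1 * g * e1
            + cfg.beta_GxE2 * g * e2
            + cfg.smoke_beta * smoke
        )
        status = (rng.random(batch) < expit(lp)).astype(int)
        drawn += batch
        for lab in (1, 0):
            if need[lab] <= 0:
                continue
            pick = np.flatnonzero(status == lab)[: need[lab]]
            need[lab] -= pick.size
            kept["g"].append(g[pick])
            kept["e"].append(e[pick])
            kept["sex"].append(sex[pick])
            kept["age"].append(age[pick])
            kept["smoke"].append(smoke[pick])
            kept["pky"].append(pky[pick])
            kept["pc"].append(pc[pick])
            kept["status"].append(status[pick])
    out = {k: np.concatenate(v) for k, v in kept.items() if k != "pc"}
    out["pc"] = np.concatenate(kept["pc"], axis=0)
    # shuffle so cases/controls are interleaved within the study
    order = rng.permutation(out["status"].shape[0])
    return {k: v[order] for k, v in out.items()}


def _category_to_gday(rng: np.random.Generator, cat: np.ndarray) -> np.ndarray:
    """Raw grams/day consistent with the harmonisation rule for each category."""
    g = np.empty(cat.shape[0])
    m0, m1, m2 = cat == 0, cat == 1, cat == 2
    g[m0] = rng.uniform(0.0, 0.999, size=int(m0.sum()))
    g[m1] = rng.uniform(1.0, 28.0, size=int(m1.sum()))
    g[m2] = 28.0 + rng.gamma(2.0, 8.0, size=int(m2.sum()))
    return g


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Simulate one consortium; returns (cohort table, genotype matrix).

    The cohort is a pandas DataFrame with one row per subject (subject_id,
    study, sex, age, status, alcohol_gday, alcohol_cat, smoke_ever,
    pack_years, pc1..pc3); `df.attrs["config"]` stores the configuration for
    downstream re-simulation (`spike_signal`).  The genotype matrix holds
    `n_variants` dosage rows; the causal variant's dosages come from the
    joint retrospective draw, the null variants are independent HWE draws.
    """
    cfg = config
    parts = [_sample_study(cfg, s) for s in range(cfg.n_studies)]
    n_per = cfg.n_cases + cfg.n_controls
    n_total = n_per * cfg.n_studies

    grng = _genome_rng(cfg.seed)
    lo, hi = cfg.null_maf_range
    mafs = grng.uniform(lo, hi, size=cfg.n_variants)
    mafs[cfg.causal_index] = cfg.maf
    typed = grng.random(cfg.n_variants) >= cfg.imputed_fraction
    r2 = np.where(typed, 1.0, grng.uniform(*cfg.imputation_r2_range, size=cfg.n_variants))
    dosage = grng.binomial(2, mafs[:, None], size=(cfg.n_variants, n_total)).astype(float)
    dosage[cfg.causal_index] = np.concatenate([p["g"] for p in parts])

    variants = pd.DataFrame(
        {
            "chrom": "9",
            "pos": 100_000 + 1_000 * np.arange(cfg.n_variants),
            "id": [f"var{i:05d}" for i in range(cfg.n_variants)],
            "ref": "C",
            "alt": "T",
            "typed": typed,
            "imputation_r2": np.round(r2, 4),
            "sim_maf": mafs,
        }
    )

    study = np.repeat([f"study{s:02d}" for s in range(cfg.n_studies)], n_per)
    cat = np.concatenate([p["e"] for p in parts]).astype(int)
    gday_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2,)))
    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n_total)],
            "study": study,
            "sex": np.where(np.concatenate([p["sex"] for p in parts]) == 1, "male", "female"),
            "age": np.round(np.concatenate([p["age"] for p in parts]), 2),
            "status": np.concatenate([p["status"] for p in parts]).astype(int),
            "alcohol_gday": np.round(_category_to_gday(gday_rng, cat), 3),
            "alcohol_cat": cat,
            "smoke_ever": np.concatenate([p["smoke"] for p in parts]).astype(int),
            "pack_years": np.round(np.concatenate([p["pky"] for p in parts]), 2),
        }
    )
    pcs = np.concatenate([p["pc"] for p in parts], axis=0)
    for j in range(3):
        cohort[f"pc{j + 1}"] = np.round(pcs[:, j], 4)
    cohort.attrs["config"] = cfg

    gm = GenotypeMatrix(variants=variants, dosage=dosage, samples=list(cohort["subject_id"]))
    return cohort, gm


def spike_signal(
    gm: GenotypeMatrix,
    cohort: pd.DataFrame,
    variant_id: str,
    beta_GxE1: float,
    beta_GxE2: float = 0.0,
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Re-simulate the cohort with a GxE signal at one variant, all others null.

    The named variant becomes the causal variant (keeping its simulated MAF);
    case status is regenerated under the requested interaction
    coefficient(s) with the same master seed, so `beta_GxE1=0` at the
    original causal variant reproduces the null generator exactly.
    """
    cfg: SimulationConfig = cohort.attrs["config"]
    ids = list(gm.variants["id"])
    if variant_id not in ids:
        raise KeyError(f"unknown variant id {variant_id!r}")
    idx = ids.index(variant_id)
    maf = float(gm.variants["sim_maf"].iloc[idx]) if "sim_maf" in gm.variants else cfg.maf
    new_cfg = dataclasses.replace(
        cfg, causal_index=idx, maf=maf, beta_GxE1=beta_GxE1, beta_GxE2=beta_GxE2
    )
    return simulate_cohort(new_cfg)


def write_config(cfg: SimulationConfig, path) -> None:
    """Plain key-value dump of a simulation config."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(cfg):
            v = getattr(cfg, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            fh.write(f"{f.name} = {v}\n")
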