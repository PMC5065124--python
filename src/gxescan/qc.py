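"""Variant-level quality control.

Filters follow standard GWAS consortium practice: genotyped variants are
excluded on call rate < 0.98, Hardy-Weinberg disequilibrium in controls at
p < 1e-4, and MAF < 0.05; variants are further restricted to per-study minor
allele count > 5 and, for imputed variants, imputation accuracy R^2 > 0.3.
HWE uses the exact conditional (Levene-Haldane) test on hard-called
genotypes of typed variants in controls only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genio import GenotypeMatrix

__all__ = ["QCThresholds", "hwe_exact_test", "qc_filter"]


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.98
    min_hwe_p: float = 1e-4
    min_maf: float = 0.05
    min_mac: int = 5          # per-study MAC must exceed this
    min_imputation_r2: float = 0.3


def _het_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Levene-Haldane distribution of the heterozygote count conditional on
    n diploid genotypes and n_minor minor alleles.  Returns (het values,
    log probabilities); het shares the parity of n_minor."""
    n_major = 2 * n - n_minor
    h = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    n_hom_min = (n_minor - h) // 2
    n_hom_maj = n - h - n_hom_min
    logp = (
        gammaln(n + 1)
        - gammaln(n_hom_maj + 1)
        - gammaln(h + 1)
        - gammaln(n_hom_min + 1)
        + h * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return h, logp


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one (the
    conventional, non-mid-p convention).  Monomorphic tables return 1.0.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError(f"genotype counts must be nonnegative integers, got {counts}")
    n = int(n_hom_ref + n_het + n_hom_alt)
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    h_vals, logp = _het_log_probs(n, n_minor)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.searchsorted(h_vals, n_het)]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-12)].sum()))


def _hard_calls(dosage: np.ndarray) -> np.ndarray:
    """Nearest-integer genotype; dosages in (0.5, 1.5] call het."""
    g = np.full(dosage.shape, np.nan)
    ok = np.isfinite(dosage)
    g[ok & (dosage <= 0.5)] = 0
    g[ok & (dosage > 0.5) & (dosage <= 1.5)] = 1
    g[ok & (dosage > 1.5)] = 2
    return g


def qc_filter(
    gm: GenotypeMatrix,
    cohort: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply variant QC; returns (filtered matrix, per-variant report).

    The report has one row per input variant: call_rate, hwe_p (typed
    variants, controls only), maf (all samples), min per-study mac,
    imputation_r2, pass_flag and semicolon-joined fail_reasons.  Subjects
    with a missing dosage at a variant contribute to that variant's call
    rate but are excluded from its statistics, mirroring the rule that
    missing data drop a subject from the relevant analyses only.
    """
    th = thresholds or QCThresholds()
    dos = gm.dosage
    n_var, n_samp = dos.shape
    if len(cohort) != n_samp:
        raise ValueError("cohort rows do not match genotype samples")
    controls = (cohort["status"].to_numpy() == 0)
    typed = gm.variants["typed"].to_numpy(dtype=bool)
    if typed.any() and not controls.any():
        raise ValueError("HWE filtering requested but the cohort has no controls")

    finite = np.isfinite(dos)
    call_rate = finite.mean(axis=1)

    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(dos, axis=1) / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    studies = cohort["study"].to_numpy()
    macs = np.full(n_var, np.inf)
    for s in pd.unique(studies):
        cols = studies == s
        with np.errstate(invalid="ignore"):
            alt = np.nansum(np.where(finite[:, cols], dos[:, cols], 0.0), axis=1)
        tot = 2.0 * finite[:, cols].sum(axis=1)
        macs = np.minimum(macs, np.minimum(alt, tot - alt))

    hwe_p = np.ones(n_var)
    hard = _hard_calls(dos[:, controls])
    for i in np.flatnonzero(typed):
        row = hard[i]
        row = row[np.isfinite(row)]
        if row.size:
            hwe_p[i] = hwe_exact_test(int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum()))

    r2 = gm.variants["imputation_r2"].to_numpy(dtype=float)

    reasons = []
    for i in range(n_var):
        why = []
        if call_rate[i] < th.min_call_rate:
            why.append("low_call_rate")
        if typed[i] and hwe_p[i] < th.min_hwe_p:
            why.append("hwe_fail")
        if not np.isfinite(maf[i]) or maf[i] < th.min_maf:
            why.append("low_maf")
        if macs[i] <= th.min_mac:
            why.append("low_mac")
        if not typed[i] and not (r2[i] > th.min_imputation_r2):
            why.append("low_imputation_r2")
        reasons.append(why)

    report = gm.variants[["chrom", "pos", "id"]].copy()
    report["call_rate"] = call_rate
    report["hwe_p"] = np.where(typed, hwe_p, np.nan)
    report["maf"] = maf
    report["mac"] = np.where(np.isfinite(macs), macs, 0.0)
    report["imputation_r2"] = r2
    report["pass_flag"] = [not r for r in reasons]
    report["fail_reasons"] = [";".join(r) for r in reasons]

    return gm.subset(report["pass_flag"].to_numpy()), report
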