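"""Fixed-effects meta-analysis, heterogeneity and genome-wide calibration."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "fixed_effects_meta", "woolf_heterogeneity", "genomic_lambda", "qq_points"]

# strata with wilder estimates are treated as unstable and dropped from meta
MAX_ABS_BETA = 10.0
MAX_SE = 10.0

_CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    Q: float
    df: int
    het_p: float
    k: int
    strata: list[tuple[float, float, float]] = field(default_factory=list)  # (beta, se, weight)


def _clean(estimates):
    out = []
    for b, s in estimates:
        if np.isfinite(b) and np.isfinite(s) and 0 < s <= MAX_SE and abs(b) <= MAX_ABS_BETA:
            out.append((float(b), float(s)))
    return out


def fixed_effects_meta(estimates, drop_unstable: bool = True) -> MetaResult:
    """Inverse-variance weighted pooling of per-stratum (beta, se) pairs.

    Unstable strata (|beta| > 10 or se > 10 or non-finite) are excluded when
    `drop_unstable`; the pooled Wald z and two-sided p plus Woolf
    heterogeneity come along for free.
    """
    est = _clean(estimates) if drop_unstable else [(float(b), float(s)) for b, s in estimates]
    if not est:
        raise ValueError("no usable stratum estimates")
    for _, s in est:
        if s <= 0:
            raise ValueError("standard errors must be positive")
    b = np.array([x[0] for x in est])
    w = np.array([1.0 / (x[1] * x[1]) for x in est])
    pooled = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    if len(est) >= 2:
        Q = float((w * (b - pooled) ** 2).sum())
        df = len(est) - 1
        het_p = float(stats.chi2.sf(Q, df))
    else:
        Q, df, het_p = 0.0, 0, 1.0
    return MetaResult(
        beta=pooled, se=se, z=float(z), p=p, Q=Q, df=df, het_p=het_p, k=len(est),
        strata=[(bi, si, 1.0 / (si * si)) for bi, si in est],
    )


def woolf_heterogeneity(estimates) -> tuple[float, int, float]:
    """Woolf's inverse-variance chi-square test of log-OR homogeneity:
    Q = sum w_i (beta_i - pooled)^2 on k-1 df."""
    est = [(float(b), float(s)) for b, s in estimates]
    if len(est) < 2:
        raise ValueError("heterogeneity needs at least 2 strata")
    res = fixed_effects_meta(est, drop_unstable=False)
    return res.Q, res.df, res.het_p


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median implied 1-df chi-square over its
    null median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_1DF_MEDIAN)


def qq_points(p_values) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 p quantile pairs, both ascending;
    expected quantiles (i - 0.5)/m."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    m = p.size
    expected = np.sort(-np.log10((np.arange(1, m + 1) - 0.5) / m))
    observed = np.sort(-np.log10(p))
    return expected, observed
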