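"""Per-stratum interaction estimators.

The primary model is a case-control logistic regression of disease status on
dosage (log-additive), indicator-coded exposure, their products, and the
adjustment covariates; each GxE product coefficient is Wald-tested.  The
case-only estimator regresses an exposure contrast on dosage among cases
(valid only under genotype-exposure independence), and the empirical-Bayes
estimator shrinks between the two according to the evidence of
genotype-exposure dependence among controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import logistic_fit

__all__ = [
    "StratumFit",
    "EstimatorResult",
    "fit_interaction_cc",
    "fit_case_only",
    "eb_combine",
    "build_design",
]

DEFAULT_COVARIATES = ("age", "pc1", "pc2", "pc3")


@dataclass
class StratumFit:
    stratum: str
    params: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_cases: int
    n_controls: int
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.params)

    def z(self, term: str) -> float:
        return float(self.params[term] / self.se[term])

    def p(self, term: str) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z(term))))

    def wald_joint(self, terms: tuple[str, ...] = ("G:E1", "G:E2")) -> tuple[float, int, float]:
        """Joint Wald chi-square test of several coefficients (e.g. a 2-df
        test of both interaction terms)."""
        b = self.params[list(terms)].to_numpy()
        V = self.cov.loc[list(terms), list(terms)].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        df = len(terms)
        return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class EstimatorResult:
    method: str   # case_control | case_only | empirical_bayes
    beta: float
    se: float

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


def build_design(
    data: pd.DataFrame,
    dosage: np.ndarray,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "alcohol_cat",
    include_sex: bool = False,
    include_study: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Assemble (y, X, term names, kept-row mask) for the interaction model.

    Rows with missing dosage or exposure are dropped (they are excluded
    from this variant's analysis only).  Term order: const, covariates,
    [sex], [study dummies], E1, E2, G, G:E1, G:E2.
    """
    d = np.asarray(dosage, dtype=float)
    e = data[exposure_col].to_numpy(dtype=float)
    keep = np.isfinite(d) & np.isfinite(e)
    for c in covariates:
        keep &= np.isfinite(data[c].to_numpy(dtype=float))
    df = data.loc[keep]
    d = d[keep]
    e = e[keep]

    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for c in covariates:
        cols[c] = df[c].to_numpy(dtype=float)
    if include_sex and df["sex"].nunique() > 1:
        cols["male"] = (df["sex"] == "male").to_numpy(dtype=float)
    if include_study and df["study"].nunique() > 1:
        for s in sorted(df["study"].unique())[1:]:
            cols[f"study[{s}]"] = (df["study"] == s).to_numpy(dtype=float)
    e1 = (e == 1).astype(float)
    e2 = (e == 2).astype(float)
    cols["E1"] = e1
    if e2.any():
        cols["E2"] = e2
    cols["G"] = d
    cols["G:E1"] = d * e1
    if e2.any():
        cols["G:E2"] = d * e2

    names = list(cols)
    X = np.column_stack([cols[k] for k in names])
    y = df["status"].to_numpy(dtype=float)
    return y, X, names, keep


def fit_interaction_cc(
    stratum_data: pd.DataFrame,
    dosage: np.ndarray,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "alcohol_cat",
    include_sex: bool = False,
    include_study: bool = False,
    stratum: str = "",
    min_mac: float = 5.0,
) -> StratumFit:
    """ML logistic fit of the case-control interaction model for one stratum.

    Raises on degenerate input (single outcome class, constant non-intercept
    column); separation or iteration-limit exits set converged=False so the
    stratum can be excluded downstream with a logged reason.
    """
    y, X, names, keep = build_design(
        stratum_data, dosage, covariates, exposure_col, include_sex, include_study
    )
    if y.size == 0 or y.min() == y.max():
        raise ValueError(f"stratum {stratum or '?'}: needs both cases and controls")
    sd = X.std(axis=0)
    const_cols = [names[i] for i in range(1, len(names)) if sd[i] == 0.0]
    if const_cols:
        raise ValueError(f"stratum {stratum or '?'}: constant columns {const_cols}")
    d = X[:, names.index("G")]
    mac = float(min(d.sum(), 2 * d.size - d.sum()))
    beta, cov, ll, converged = logistic_fit(y, X)
    if mac <= min_mac:
        converged = False
    se = np.sqrt(np.diag(cov)) if converged else np.full(len(names), np.nan)
    return StratumFit(
        stratum=stratum,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=float(ll),
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        converged=converged,
    )


def fit_case_only(
    cases_data: pd.DataFrame,
    dosage: np.ndarray,
    exposure_pair: tuple[int, int] = (0, 1),
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "alcohol_cat",
    include_study: bool = False,
) -> EstimatorResult:
    """Case-only interaction estimator for one exposure contrast.

    Logistic regression of the exposure indicator (second vs first level of
    `exposure_pair`) on dosage among cases, covariate-adjusted.  The dosage
    coefficient estimates the interaction log-OR under genotype-exposure
    independence in the source population.
    """
    df = cases_data[cases_data["status"] == 1]
    d = np.asarray(dosage, dtype=float)[cases_data["status"].to_numpy() == 1]
    e = df[exposure_col].to_numpy(dtype=float)
    keep = np.isfinite(d) & np.isin(e, exposure_pair)
    for c in covariates:
        keep &= np.isfinite(df[c].to_numpy(dtype=float))
    df, d, e = df.loc[keep], d[keep], e[keep]
    y = (e == exposure_pair[1]).astype(float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("fewer than 2 exposure levels among cases")
    cols = [np.ones(y.size)] + [df[c].to_numpy(dtype=float) for c in covariates]
    if include_study and df["study"].nunique() > 1:
        for s in sorted(df["study"].unique())[1:]:
            cols.append((df["study"] == s).to_numpy(dtype=float))
    cols.append(d)
    X = np.column_stack(cols)
    beta, cov, _, converged = logistic_fit(y, X)
    if not converged:
        raise RuntimeError("case-only fit did not converge")
    return EstimatorResult(method="case_only", beta=float(beta[-1]), se=float(np.sqrt(cov[-1, -1])))


def eb_combine(
    beta_cc: float,
    var_cc: float,
    beta_co: float,
    var_co: float,
    theta_hat: float,
    var_theta: float,
) -> EstimatorResult:
    """Empirical-Bayes shrinkage between case-control and case-only estimates.

        beta_EB = (theta^2 * beta_cc + var_cc * beta_co) / (theta^2 + var_cc)

    where theta_hat is the genotype-exposure log-OR among controls.  When the
    controls show no G-E association (theta ~ 0) the estimator leans on the
    efficient case-only estimate; strong dependence (|theta| large) pushes it
    back to the robust case-control estimate.

    Variance by the delta method on f(beta_cc, beta_co, theta), treating the
    three inputs as independent:

        K            = theta^2 / (theta^2 + var_cc)
        df/dbeta_cc  = K
        df/dbeta_co  = 1 - K
        df/dtheta    = 2 theta var_cc (beta_cc - beta_co) / (theta^2 + var_cc)^2
        var(beta_EB) = K^2 var_cc + (1-K)^2 var_co + (df/dtheta)^2 var_theta
    """
    if var_cc <= 0 or var_co <= 0:
        raise ValueError("variances must be positive")
    t2 = theta_hat * theta_hat
    denom = t2 + var_cc
    k = t2 / denom
    beta = k * beta_cc + (1.0 - k) * beta_co
    dtheta = 2.0 * theta_hat * var_cc * (beta_cc - beta_co) / (denom * denom)
    var = k * k * var_cc + (1.0 - k) ** 2 * var_co + dtheta * dtheta * max(var_theta, 0.0)
    return EstimatorResult(method="empirical_bayes", beta=float(beta), se=float(np.sqrt(var)))
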