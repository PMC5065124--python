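"""Genome-wide single-step interaction scan.

Each variant is fitted per analysis stratum (study x sex by default, the
stratification used for alcohol; study-level with sex as a covariate for
smoking-style exposures) with the case-control interaction model, and the
stratum estimates of each GxE term are pooled by inverse-variance
fixed-effects meta-analysis with Woolf heterogeneity.  Fits are vectorised
across variants through the batched IRLS engine; the per-variant path in
`models.fit_interaction_cc` is the reference implementation the batch path
is tested against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .glm import batched_logistic
from .meta import MAX_ABS_BETA, MAX_SE
from .models import DEFAULT_COVARIATES

__all__ = ["iter_strata", "interaction_scan", "stratum_estimates"]


def iter_strata(cohort: pd.DataFrame, scheme: str = "study_sex"):
    """Yield (label, positional row indices) per analysis stratum."""
    if scheme == "study_sex":
        keys = cohort["study"].astype(str) + "/" + cohort["sex"].astype(str)
    elif scheme == "study":
        keys = cohort["study"].astype(str)
    elif scheme == "none":
        keys = pd.Series("all", index=cohort.index)
    else:
        raise ValueError(f"unknown stratification scheme {scheme!r}")
    arr = keys.to_numpy()
    for lab in sorted(pd.unique(arr)):
        yield lab, np.flatnonzero(arr == lab)


def _shared_columns(df: pd.DataFrame, covariates, include_sex: bool):
    cols = {"const": np.ones(len(df))}
    for c in covariates:
        cols[c] = df[c].to_numpy(dtype=float)
    if include_sex and df["sex"].nunique() > 1:
        cols["male"] = (df["sex"] == "male").to_numpy(dtype=float)
    return cols


def stratum_estimates(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "alcohol_cat",
    scheme: str = "study_sex",
    chunk: int = 256,
    min_mac: float = 5.0,
):
    """Batched per-stratum fits for every variant.

    Returns dict term -> (beta (k, m), se (k, m)) plus the list of stratum
    labels; entries for unusable stratum/variant fits are NaN.
    """
    m = gm.n_variants
    include_sex = scheme != "study_sex"
    strata = []
    res: dict[str, list[np.ndarray]] = {}
    terms = None
    for lab, idx in iter_strata(cohort, scheme):
        df = cohort.iloc[idx]
        e = df[exposure_col].to_numpy(dtype=float)
        keep = np.isfinite(e) & np.isfinite(df[list(covariates)].to_numpy(dtype=float)).all(axis=1)
        df = df.iloc[np.flatnonzero(keep)]
        idx = idx[keep]
        y = df["status"].to_numpy(dtype=float)
        e = e[keep]
        if y.size == 0 or y.min() == y.max():
            continue
        e1 = (e == 1).astype(float)
        e2 = (e == 2).astype(float)
        has_e2 = bool(e2.any()) and bool((e1 + e2 < 1).any())
        if not e1.any():
            continue
        cols = _shared_columns(df, covariates, include_sex)
        cols["E1"] = e1
        if has_e2:
            cols["E2"] = e2
        shared = np.column_stack(list(cols.values()))
        drop = [k for i, k in enumerate(cols) if i > 0 and shared[:, i].std() == 0.0]
        if drop:
            keep_cols = [i for i, k in enumerate(cols) if k not in drop]
            shared = shared[:, keep_cols]
        sp = shared.shape[1]
        n = y.size
        stratum_terms = ["G", "G:E1"] + (["G:E2"] if has_e2 else [])
        if terms is None:
            terms = ["G", "G:E1", "G:E2"]
            for t in terms:
                res[t] = []
        bmat = {t: np.full(m, np.nan) for t in terms}
        smat = {t: np.full(m, np.nan) for t in terms}
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            D = gm.dosage[lo:hi][:, idx]
            w = np.isfinite(D).astype(float)
            Dz = np.nan_to_num(D)
            mc = hi - lo
            p = sp + len(stratum_terms)
            X = np.empty((mc, n, p))
            X[:, :, :sp] = shared[None, :, :]
            X[:, :, sp] = Dz
            X[:, :, sp + 1] = Dz * e1[None, :]
            if has_e2:
                X[:, :, sp + 2] = Dz * e2[None, :]
            fit = batched_logistic(y, X, obs_weight=w)
            se = fit.se
            # minor allele count gate per variant within the stratum
            alt = (Dz * w).sum(axis=1)
            tot = 2.0 * w.sum(axis=1)
            mac = np.minimum(alt, tot - alt)
            ok = fit.converged & (mac > min_mac)
            for j, t in enumerate(stratum_terms):
                col = sp + j
                bmat[t][lo:hi] = np.where(ok, fit.beta[:, col], np.nan)
                smat[t][lo:hi] = np.where(ok, se[:, col], np.nan)
        strata.append(lab)
        for t in terms:
            res[t].append((bmat[t], smat[t]))
    if terms is None:
        raise ValueError("no usable analysis strata")
    out = {}
    for t in terms:
        if not any(np.isfinite(b).any() for b, _ in res[t]):
            continue
        B = np.vstack([b for b, _ in res[t]])
        S = np.vstack([s for _, s in res[t]])
        out[t] = (B, S)
    return out, strata


def _meta_columns(B: np.ndarray, S: np.ndarray):
    """Vectorised fixed-effects meta over the stratum axis (axis 0)."""
    valid = (
        np.isfinite(B) & np.isfinite(S) & (S > 0) & (S <= MAX_SE) & (np.abs(B) <= MAX_ABS_BETA)
    )
    W = np.where(valid, 1.0 / np.where(valid, S, 1.0) ** 2, 0.0)
    k = valid.sum(axis=0)
    wsum = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (W * np.where(valid, B, 0.0)).sum(axis=0) / wsum
        se = 1.0 / np.sqrt(wsum)
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        Q = (W * (np.where(valid, B, 0.0) - beta[None, :]) ** 2).sum(axis=0)
        het_p = np.where(k >= 2, stats.chi2.sf(Q, np.maximum(k - 1, 1)), 1.0)
    empty = k == 0
    for arr in (beta, se, z, p, Q, het_p):
        arr[empty] = np.nan
    return beta, se, z, p, Q, het_p, k


def interaction_scan(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "alcohol_cat",
    scheme: str = "study_sex",
    chunk: int = 256,
    min_mac: float = 5.0,
) -> pd.DataFrame:
    """Scan every variant; one row per variant with pooled estimates.

    Columns per term T in {G, GxE1, GxE2}: beta_T, se_T, z_T, p_T, Q_T,
    het_p_T, k_T.  The G term is the genotype main effect within the
    interaction model, reported for completeness; the GxE terms carry the
    interaction inference.
    """
    ests, strata = stratum_estimates(cohort, gm, covariates, exposure_col, scheme, chunk, min_mac)
    out = gm.variants[["chrom", "pos", "id", "ref", "alt"]].copy()
    for term, (B, S) in ests.items():
        tag = term.replace("G:E", "GxE")
        beta, se, z, p, Q, het_p, k = _meta_columns(B, S)
        out[f"beta_{tag}"] = beta
        out[f"se_{tag}"] = se
        out[f"z_{tag}"] = z
        out[f"p_{tag}"] = p
        out[f"Q_{tag}"] = Q
        out[f"het_p_{tag}"] = het_p
        out[f"k_{tag}"] = k
    out.attrs["strata"] = strata
    return out
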