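"""Two-step "Cocktail" genome-wide GxE procedure.

Step 1 (screening) ranks every variant by the more significant of two
statistics computed on cases and controls combined: the marginal
genotype-disease association and the genotype-exposure correlation.  Step 2
(testing) partitions the ranked variants into geometrically growing groups
with geometrically decaying per-variant alpha budgets (weighted hypothesis
testing), then tests each variant's interaction with the case-only test if
its marginal screen won, or the case-control test if the correlation screen
won.  The total allocated alpha never exceeds the family-wise budget.

The procedure operates on a single binary exposure contrast (by default
light-to-moderate vs non/occasional drinking) so each variant receives one
screening rank and one test p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .glm import batched_logistic

__all__ = ["allocate_weighted_alpha", "screen_variants", "cocktail_scan"]


def allocate_weighted_alpha(n_variants: int, base_group_size: int = 5, alpha: float = 0.05):
    """Per-rank alpha thresholds under the doubling weighted-hypothesis scheme.

    Group j (1-based) holds B * 2^(j-1) ranks and each of its variants gets
    threshold alpha * 2^(-j) / (B * 2^(j-1)); summed over groups the budget
    is alpha * sum_j 2^-j < alpha.  Returns (thresholds, group_index), both
    aligned to rank order (rank 1 first).
    """
    if base_group_size < 1:
        raise ValueError("base_group_size must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    thresholds = np.empty(n_variants)
    groups = np.empty(n_variants, dtype=int)
    j, start = 1, 0
    while start < n_variants:
        size = base_group_size * 2 ** (j - 1)
        stop = min(start + size, n_variants)
        thresholds[start:stop] = alpha * 2.0 ** (-j) / size
        groups[start:stop] = j
        start = stop
        j += 1
    return thresholds, groups


def _study_dummies(df: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(df))]
    if df["study"].nunique() > 1:
        for s in sorted(df["study"].unique())[1:]:
            cols.append((df["study"] == s).to_numpy(dtype=float))
    return np.column_stack(cols)


def _batched_last_z(y, shared, D, chunk=512):
    """z statistic of the dosage column added to a shared design, per variant."""
    m, n = D.shape
    sp = shared.shape[1]
    z = np.full(m, np.nan)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        Dc = D[lo:hi]
        w = np.isfinite(Dc).astype(float)
        X = np.empty((hi - lo, n, sp + 1))
        X[:, :, :sp] = shared[None, :, :]
        X[:, :, sp] = np.nan_to_num(Dc)
        fit = batched_logistic(y, X, obs_weight=w)
        se = fit.se[:, sp]
        with np.errstate(invalid="ignore"):
            zc = fit.beta[:, sp] / se
        z[lo:hi] = np.where(fit.converged, zc, np.nan)
    return z


def screen_variants(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix,
    exposure_pair: tuple[int, int] = (0, 1),
    exposure_col: str = "alcohol_cat",
    chunk: int = 512,
) -> pd.DataFrame:
    """Step-1 screening statistics for every variant.

    Marginal screen: logistic regression of case status on dosage (study
    indicators adjusted) over all subjects.  Correlation screen: logistic
    regression of the exposure indicator on dosage over cases and controls
    combined, restricted to the two contrasted exposure levels.  The winner
    is the larger |z| (ties go to the marginal screen, then ranks are
    tie-broken by genomic position).
    """
    e = cohort[exposure_col].to_numpy(dtype=float)
    y = cohort["status"].to_numpy(dtype=float)

    shared_all = _study_dummies(cohort)
    z_marg = _batched_last_z(y, shared_all, gm.dosage, chunk)

    in_pair = np.isin(e, exposure_pair)
    dfp = cohort.iloc[np.flatnonzero(in_pair)]
    y_e = (e[in_pair] == exposure_pair[1]).astype(float)
    shared_pair = _study_dummies(dfp)
    z_corr = _batched_last_z(y_e, shared_pair, gm.dosage[:, in_pair], chunk)

    rec = gm.variants[["chrom", "pos", "id"]].copy()
    rec["z_marginal"] = z_marg
    rec["p_marginal"] = 2.0 * stats.norm.sf(np.abs(z_marg))
    rec["z_corr"] = z_corr
    rec["p_corr"] = 2.0 * stats.norm.sf(np.abs(z_corr))
    am, ac = np.abs(np.nan_to_num(z_marg)), np.abs(np.nan_to_num(z_corr))
    rec["winner"] = np.where(am >= ac, "marginal", "correlation")
    rec["screen_stat"] = np.maximum(am, ac)
    rec["test_method"] = np.where(rec["winner"] == "marginal", "case_only", "case_control")
    return rec


def cocktail_scan(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix,
    exposure_pair: tuple[int, int] = (0, 1),
    exposure_col: str = "alcohol_cat",
    alpha: float = 0.05,
    base_group_size: int = 5,
    chunk: int = 512,
) -> pd.DataFrame:
    """Full two-step scan; one completed screening record per variant.

    Testing step: case-only test = logistic regression of the exposure
    indicator on dosage among cases; case-control test = Wald test of the
    GxE product term in the interaction model restricted to the contrasted
    exposure levels.  Both are study-indicator adjusted and computed on the
    pooled sample.  `significant` compares the test p to the rank's
    weighted-alpha threshold.
    """
    rec = screen_variants(cohort, gm, exposure_pair, exposure_col, chunk)

    screen_p = 2.0 * stats.norm.sf(rec["screen_stat"].to_numpy())
    order = np.lexsort((rec["pos"].to_numpy(), rec["chrom"].astype(str).to_numpy(), screen_p))
    rank = np.empty(len(rec), dtype=int)
    rank[order] = np.arange(1, len(rec) + 1)
    rec["rank"] = rank
    thresholds, groups = allocate_weighted_alpha(len(rec), base_group_size, alpha)
    rec["group_index"] = groups[rank - 1]
    rec["alpha_threshold"] = thresholds[rank - 1]

    e = cohort[exposure_col].to_numpy(dtype=float)
    y = cohort["status"].to_numpy(dtype=float)
    in_pair = np.isin(e, exposure_pair)

    # case-only: exposure indicator ~ dosage among cases in the contrast
    co_rows = in_pair & (y == 1)
    df_co = cohort.iloc[np.flatnonzero(co_rows)]
    y_co = (e[co_rows] == exposure_pair[1]).astype(float)
    z_co = _batched_last_z(y_co, _study_dummies(df_co), gm.dosage[:, co_rows], chunk)
    p_co = 2.0 * stats.norm.sf(np.abs(z_co))

    # case-control: status ~ E + G + GxE (+ studies) in the contrast
    df_cc = cohort.iloc[np.flatnonzero(in_pair)]
    y_cc = y[in_pair]
    e_ind = (e[in_pair] == exposure_pair[1]).astype(float)
    shared = np.column_stack([_study_dummies(df_cc), e_ind])
    D = gm.dosage[:, in_pair]
    m, n = D.shape
    sp = shared.shape[1]
    p_cc = np.full(m, np.nan)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        Dc = D[lo:hi]
        w = np.isfinite(Dc).astype(float)
        Dz = np.nan_to_num(Dc)
        X = np.empty((hi - lo, n, sp + 2))
        X[:, :, :sp] = shared[None, :, :]
        X[:, :, sp] = Dz
        X[:, :, sp + 1] = Dz * e_ind[None, :]
        fit = batched_logistic(y_cc, X, obs_weight=w)
        se = fit.se[:, sp + 1]
        with np.errstate(invalid="ignore"):
            zc = fit.beta[:, sp + 1] / se
        p_cc[lo:hi] = np.where(fit.converged, 2.0 * stats.norm.sf(np.abs(zc)), np.nan)

    use_co = rec["test_method"].to_numpy() == "case_only"
    rec["test_p"] = np.where(use_co, p_co, p_cc)
    rec["significant"] = rec["test_p"].to_numpy() < rec["alpha_threshold"].to_numpy()
    rec.loc[~np.isfinite(rec["test_p"]), "significant"] = False
    return rec
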