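"""Empirical p-values by stratified case-control label permutation.

Case/control status is shuffled within each analysis stratum (study x sex by
default), preserving per-stratum case counts, and the full per-stratum
fit + fixed-effects meta-analysis pipeline is re-run on every permuted
dataset.  The empirical p uses the add-one estimator (r + 1)/(B + 1), which
is valid (never anti-conservative) for any B.  The number of permutations a
reported p-value warrants is ceil(1/p) - e.g. 20,000,000 for p = 5e-8; that
is cluster-scale, and the engine runs any requested B with the same
bookkeeping.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .glm import batched_logistic
from .models import DEFAULT_COVARIATES
from .scan import _meta_columns, iter_strata

__all__ = ["required_permutations", "permute_labels", "empirical_pvalue"]


def required_permutations(p_value: float) -> int:
    """ceil(1 / p): the permutation count a reported p-value calls for."""
    if not (0.0 < p_value < 1.0):
        raise ValueError(f"p-value must be in (0, 1), got {p_value}")
    return math.ceil(1.0 / p_value)


def _perm_rng(base_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=base_seed, spawn_key=(3, index)))


def permute_labels(cohort: pd.DataFrame, seed: int, scheme: str = "study_sex", index: int = 0) -> pd.DataFrame:
    """Shuffle case/control labels within each stratum; everything else is
    untouched.  (seed, index) fully determines the permutation."""
    rng = _perm_rng(seed, index)
    status = cohort["status"].to_numpy().copy()
    for _, idx in iter_strata(cohort, scheme):
        status[idx] = status[idx][rng.permutation(idx.size)]
    out = cohort.copy()
    out["status"] = status
    out.attrs.update(cohort.attrs)
    return out


def _pipeline_pvalues(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    Y: np.ndarray,
    term: str,
    covariates,
    exposure_col: str,
    scheme: str,
) -> np.ndarray:
    """Interaction meta p for each row of label matrix Y ((B, n)).

    The model is fitted on the exposure contrast the term refers to
    (G:E1 -> levels {0, 1}; G:E2 -> levels {0, 2}), so sparse cells of the
    other exposure level cannot destabilise the permuted fits.
    """
    level = {"G:E1": 1.0, "G:E2": 2.0}[term]
    B_betas, B_ses = [], []
    e_all = cohort[exposure_col].to_numpy(dtype=float)
    for lab, idx in iter_strata(cohort, scheme):
        d = dosage[idx]
        e = e_all[idx]
        keep = np.isfinite(d) & np.isin(e, [0.0, level])
        cov = cohort.iloc[idx][list(covariates)].to_numpy(dtype=float)
        keep &= np.isfinite(cov).all(axis=1)
        idx = idx[keep]
        if idx.size == 0:
            continue
        d, e, cov = d[keep], e[keep], cov[keep]
        ys = Y[:, idx]
        if (ys.min(axis=1) == ys.max(axis=1)).all():
            continue
        e_ind = (e == level).astype(float)
        cols = [np.ones(idx.size), *cov.T, e_ind, d, d * e_ind]
        X = np.column_stack(cols)
        sd = X[:, 1:].std(axis=0)
        if (sd == 0.0).any():
            continue
        j = X.shape[1] - 1
        fit = batched_logistic(ys, X)
        se = fit.se[:, j]
        beta = fit.beta[:, j]
        bad = ~fit.converged
        beta = np.where(bad, np.nan, beta)
        se = np.where(bad, np.nan, se)
        B_betas.append(beta)
        B_ses.append(se)
    if not B_betas:
        raise ValueError("no usable strata for the permutation pipeline")
    Bm = np.vstack(B_betas)
    Sm = np.vstack(B_ses)
    _, _, _, p, _, _, _ = _meta_columns(Bm, Sm)
    return p


def empirical_pvalue(
    variant_id: str,
    cohort: pd.DataFrame,
    gm: GenotypeMatrix,
    B: int,
    base_seed: int,
    term: str = "G:E1",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "alcohol_cat",
    scheme: str = "study_sex",
    max_budget: int = 1_000_000,
    batch: int = 512,
) -> tuple[float, int, float]:
    """Permutation empirical p for one variant's interaction term.

    The observed statistic and every permuted statistic come from the same
    per-stratum fit + meta pipeline, restricted to the exposure contrast of
    `term`.  Returns (p_emp, r, p_observed) with p_emp = (r + 1)/(B + 1),
    r = number of permutation meta p-values <= the observed one.  Refuses B
    beyond `max_budget` (raise it explicitly for cluster-scale runs).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B > max_budget:
        raise ValueError(
            f"B={B} exceeds the configured budget ({max_budget}); raise max_budget "
            "explicitly if you really want a run of this size"
        )
    dosage = gm.get(variant_id)
    status = cohort["status"].to_numpy(dtype=float)
    p_obs = float(
        _pipeline_pvalues(cohort, dosage, status[None, :], term, covariates, exposure_col, scheme)[0]
    )
    if not np.isfinite(p_obs):
        raise ValueError("observed interaction p is undefined for this variant")

    strata = list(iter_strata(cohort, scheme))
    r = 0
    done = 0
    while done < B:
        nb = min(batch, B - done)
        Y = np.tile(status, (nb, 1))
        for i in range(nb):
            rng = _perm_rng(base_seed, done + i)
            for _, idx in strata:
                Y[i, idx] = status[idx][rng.permutation(idx.size)]
        p_perm = _pipeline_pvalues(cohort, dosage, Y, term, covariates, exposure_col, scheme)
        r += int(np.sum(p_perm[np.isfinite(p_perm)] <= p_obs))
        done += nb
    return (r + 1) / (B + 1), r, p_obs
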