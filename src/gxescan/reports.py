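"""Genotype-stratified odds-ratio tables.

Two layouts: (1) within-genotype exposure ORs against the non/occasional
reference (the classic three-row stratification table), each genotype
stratum analysed per study x sex and pooled by fixed-effects meta-analysis;
(2) a joint-reference table in which all genotype x exposure cells are
contrasted against the (genotype 0, exposure reference) cell from a single
model, the form the absolute-risk calculation needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .glm import logistic_fit
from .meta import fixed_effects_meta
from .models import DEFAULT_COVARIATES
from .qc import _hard_calls
from .scan import iter_strata

__all__ = ["genotype_stratified_or", "joint_reference_or"]


def _stratum_exposure_fit(df, e_ind, covariates):
    y = df["status"].to_numpy(dtype=float)
    if y.min() == y.max():
        return None
    cols = [np.ones(len(df)), e_ind]
    for c in covariates:
        cols.append(df[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if (X[:, 1:].std(axis=0) == 0.0).any():
        return None
    beta, cov, _, converged = logistic_fit(y, X)
    if not converged:
        return None
    return float(beta[1]), float(np.sqrt(cov[1, 1]))


def genotype_stratified_or(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix,
    variant_id: str,
    exposure_level: int = 1,
    reference_level: int = 0,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "alcohol_cat",
    scheme: str = "study_sex",
) -> pd.DataFrame:
    """Per-genotype OR of one exposure contrast vs its reference.

    Hard genotypes come from rounded dosage.  Within each genotype stratum,
    the covariate-adjusted exposure log-OR is fitted per analysis stratum
    and pooled by fixed-effects meta-analysis; case/control counts are
    tabulated per exposure level.  Reference rows carry OR = 1.
    """
    d = gm.get(variant_id)
    g = _hard_calls(d)
    e = cohort[exposure_col].to_numpy(dtype=float)
    rows = []
    for geno in (0, 1, 2):
        sel = (g == geno) & np.isin(e, [reference_level, exposure_level])
        if not sel.any():
            raise ValueError(f"empty genotype stratum {geno}")
        sub = cohort.iloc[np.flatnonzero(sel)]
        e_sub = e[sel]
        if len(np.unique(e_sub)) < 2:
            raise ValueError(f"empty contrast in genotype stratum {geno}")
        e_ind_all = (e_sub == exposure_level).astype(float)
        ests = []
        for lab, idx in iter_strata(sub.reset_index(drop=True), scheme):
            est = _stratum_exposure_fit(sub.iloc[idx], e_ind_all[idx], covariates)
            if est is not None:
                ests.append(est)
        meta = fixed_effects_meta(ests) if ests else None
        status = sub["status"].to_numpy()
        counts = {
            "n_cases_ref": int(((status == 1) & (e_sub == reference_level)).sum()),
            "n_controls_ref": int(((status == 0) & (e_sub == reference_level)).sum()),
            "n_cases_exp": int(((status == 1) & (e_sub == exposure_level)).sum()),
            "n_controls_exp": int(((status == 0) & (e_sub == exposure_level)).sum()),
        }
        if meta is None:
            orr = ci_lo = ci_hi = pval = het = np.nan
        else:
            orr = float(np.exp(meta.beta))
            ci_lo = float(np.exp(meta.beta - 1.959963984540054 * meta.se))
            ci_hi = float(np.exp(meta.beta + 1.959963984540054 * meta.se))
            pval = meta.p
            het = meta.het_p
        rows.append({"genotype": geno, **counts, "or_ref": 1.0, "or": orr,
                     "ci_lower": ci_lo, "ci_upper": ci_hi, "p": pval, "het_p": het,
                     "k_strata": 0 if meta is None else meta.k})
    return pd.DataFrame(rows)


def joint_reference_or(
    cohort: pd.DataFrame,
    gm: GenotypeMatrix,
    variant_id: str,
    exposure_level: int = 1,
    reference_level: int = 0,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "alcohol_cat",
    scheme: str = "study_sex",
) -> pd.DataFrame:
    """All genotype x exposure cells vs the (genotype 0, reference) cell.

    One model per analysis stratum with indicator terms for the five
    non-reference cells, pooled across strata; the reference cell has OR 1
    exactly.  Also reports each cell's prevalence among controls (the input
    the absolute-risk formula needs).
    """
    d = gm.get(variant_id)
    g = _hard_calls(d)
    e = cohort[exposure_col].to_numpy(dtype=float)
    sel = np.isfinite(g) & np.isin(e, [reference_level, exposure_level])
    sub = cohort.iloc[np.flatnonzero(sel)].reset_index(drop=True)
    g_sub = g[sel]
    e_ind = (e[sel] == exposure_level).astype(int)

    cells = [(gg, ee) for ee in (0, 1) for gg in (0, 1, 2)]
    nonref = [c for c in cells if c != (0, 0)]
    ests: dict[tuple[int, int], list[tuple[float, float]]] = {c: [] for c in nonref}
    for lab, idx in iter_strata(sub, scheme):
        df = sub.iloc[idx]
        y = df["status"].to_numpy(dtype=float)
        if y.size == 0 or y.min() == y.max():
            continue
        cols = [np.ones(idx.size)]
        for c in nonref:
            cols.append(((g_sub[idx] == c[0]) & (e_ind[idx] == c[1])).astype(float))
        for c in covariates:
            cols.append(df[c].to_numpy(dtype=float))
        X = np.column_stack(cols)
        if (X[:, 1:].std(axis=0) == 0.0).any():
            continue
        beta, cov, _, converged = logistic_fit(y, X)
        if not converged:
            continue
        for j, c in enumerate(nonref, start=1):
            ests[c].append((float(beta[j]), float(np.sqrt(cov[j, j]))))

    status = sub["status"].to_numpy()
    ctrl = status == 0
    n_ctrl = int(ctrl.sum())
    rows = []
    for gg, ee in cells:
        in_cell = (g_sub == gg) & (e_ind == ee)
        prev = float((in_cell & ctrl).sum() / n_ctrl) if n_ctrl else np.nan
        if (gg, ee) == (0, 0):
            rows.append({"genotype": gg, "exposure": ee, "or": 1.0, "se_log_or": 0.0,
                         "ci_lower": 1.0, "ci_upper": 1.0, "p": np.nan,
                         "control_prevalence": prev, "n": int(in_cell.sum()), "k_strata": 0})
            continue
        if not ests[(gg, ee)]:
            raise ValueError(f"no usable strata for cell genotype={gg}, exposure={ee}")
        meta = fixed_effects_meta(ests[(gg, ee)])
        rows.append({
            "genotype": gg, "exposure": ee,
            "or": float(np.exp(meta.beta)), "se_log_or": meta.se,
            "ci_lower": float(np.exp(meta.beta - 1.959963984540054 * meta.se)),
            "ci_upper": float(np.exp(meta.beta + 1.959963984540054 * meta.se)),
            "p": meta.p, "control_prevalence": prev, "n": int(in_cell.sum()),
            "k_strata": meta.k,
        })
    return pd.DataFrame(rows)


def render_stratified_table(table: pd.DataFrame, variant_id: str, interaction_p: float | None = None) -> str:
    """Aligned plain-text rendering of the genotype-stratified OR table."""
    lines = [f"Stratification by genotype of {variant_id} "
             "(reference: non/occasional drinkers within genotype)"]
    hdr = f"{'Genotype':>8} {'Cases0':>7} {'Ctrl0':>7} {'OR0':>4} {'Cases1':>7} {'Ctrl1':>7} {'OR (95% CI)':>20} {'P':>9}"
    lines.append(hdr)
    for _, r in table.iterrows():
        ci = f"{r['or']:.2f} ({r['ci_lower']:.2f}-{r['ci_upper']:.2f})"
        lines.append(
            f"{int(r['genotype']):>8} {int(r['n_cases_ref']):>7} {int(r['n_controls_ref']):>7} "
            f"{'1.0':>4} {int(r['n_cases_exp']):>7} {int(r['n_controls_exp']):>7} {ci:>20} {r['p']:>9.2e}"
        )
    if interaction_p is not None:
        lines.append(f"Overall interaction p = {interaction_p:.3e}")
    return "\n".join(lines)
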