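"""Genotype-stratified ORs and absolute risks for the top hit.

Reproduces the two reporting layouts for the spiked variant: the
within-genotype exposure ORs (non/occasional drinkers as reference in each
genotype row) and the six-cell joint-reference table, then converts the
joint ORs and control prevalences into absolute incidence rates anchored to
the SEER age-adjusted marginal rate of 74.5 per 100,000 person-years, with
stratified-bootstrap 95% CIs.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONSORTIUM, SPIKED_VARIANT, outdir

from gxescan.absrisk import DEFAULT_INCIDENCE, bootstrap_ci
from gxescan.reports import genotype_stratified_or, joint_reference_or, render_stratified_table
from gxescan.scan import interaction_scan
from gxescan.simulate import simulate_cohort


def main() -> None:
    cohort, gm = simulate_cohort(CONSORTIUM)

    strat = genotype_stratified_or(cohort, gm, SPIKED_VARIANT)
    strat.to_csv(outdir() / "07_genotype_stratified_or.tsv", sep="\t", index=False,
                 float_format="%.4g")
    scan_row = interaction_scan(cohort, gm.subset([gm.index_of(SPIKED_VARIANT)])).iloc[0]
    print(render_stratified_table(strat, SPIKED_VARIANT, interaction_p=scan_row["p_GxE1"]))

    joint = joint_reference_or(cohort, gm, SPIKED_VARIANT)
    joint.to_csv(outdir() / "07_joint_reference_or.tsv", sep="\t", index=False,
                 float_format="%.4g")

    risks = bootstrap_ci(cohort, gm, SPIKED_VARIANT,
                         incidence=DEFAULT_INCIDENCE, n_boot=200, seed=CONSORTIUM.seed)
    risks.to_csv(outdir() / "07_absolute_risk.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print(f"\nAbsolute CRC-style incidence per 100,000/year "
          f"(marginal rate {DEFAULT_INCIDENCE}):")
    print(risks.round(1).to_string(index=False))
    conserved = (risks["prevalence"] * risks["rate"]).sum()
    print(f"Prevalence-weighted mean of cell rates: {conserved:.6f} "
          f"(equals the marginal rate by construction)")
    ref = risks.iloc[0]["rate"]
    lm = risks.set_index("cell")
    for g in (1, 2):
        drop = lm.loc[f"g{g}_e0", "rate"] - lm.loc[f"g{g}_e1", "rate"]
        print(f"Genotype {g}: light-to-moderate drinking is associated with "
              f"{drop:.1f} fewer cases per 100,000 per year than non/occasional drinking.")


if __name__ == "__main__":
    main()
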