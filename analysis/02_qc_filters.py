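"""Variant QC on the simulated consortium.

Applies the standard filters (call rate >= 0.98, exact HWE p >= 1e-4 in
controls for typed variants, MAF >= 0.05, per-study MAC > 5, imputation
R^2 > 0.3 for imputed variants) and writes the per-variant report.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONSORTIUM, outdir

from gxescan.qc import qc_filter
from gxescan.simulate import simulate_cohort


def main() -> None:
    cohort, gm = simulate_cohort(CONSORTIUM)
    kept, report = qc_filter(gm, cohort)
    report.to_csv(outdir() / "02_qc_report.tsv", sep="\t", index=False)

    n_fail = int((~report["pass_flag"]).sum())
    print(f"{kept.n_variants}/{gm.n_variants} variants pass QC ({n_fail} excluded).")
    if n_fail:
        why = report.loc[~report["pass_flag"], "fail_reasons"].str.split(";").explode()
        print("Exclusion reasons:")
        print(why.value_counts().to_string())


if __name__ == "__main__":
    main()
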