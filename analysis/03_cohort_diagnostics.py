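#!/usr/bin/env python
"""Cohort-level statistics on the simulated 72-patient population.

Reads results/cohort.csv (written by 01_simulate_data.py), builds the
stratified population summary table, computes the mICP-P2/P1 correlation,
ROC/operating-point analyses for intracranial hypertension and early death,
and repeats the hypertension analyses after excluding decompressive-
craniectomy patients.  Outputs: results/summary_table.csv,
results/cohort_report.json, results/scatter.csv.
"""

import json
from pathlib import Path

import pandas as pd

from icpw.analysis_run import cohort_report
from icpw.cohort import build_summary_table, read_cohort_csv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort.csv")
    report = cohort_report(cohort)

    build_summary_table(cohort).to_dataframe().to_csv(
        RESULTS / "summary_table.csv", index=False
    )
    pd.DataFrame(report.pop("scatter")).to_csv(RESULTS / "scatter.csv", index=False,
                                               float_format="%.6g")
    report.pop("summary_table", None)
    (RESULTS / "cohort_report.json").write_text(
        json.dumps(report, indent=2, default=float)
    )

    prim = report["primary"]
    r = prim["pearson_micp_p2p1"]
    print(f"n = {prim['n']}; mICP-P2/P1 correlation r = {r['r']:.3f} (p = {r['p']:.2g})")
    if "p2p1_vs_iht" in prim:
        roc = prim["p2p1_vs_iht"]["roc"]
        perf = prim["p2p1_vs_iht"]["at_cutoff"]
        print(f"P2/P1 vs IHT: AUROC {roc['auc']:.3f} "
              f"[{roc['ci_low']:.3f}-{roc['ci_high']:.3f}], "
              f"at cutoff 1.2 sens {100*perf['sensitivity']:.0f}% / "
              f"spec {100*perf['specificity']:.0f}%")
    if "early_death" in prim:
        ed = prim["early_death"]
        print(f"early death: P2/P1 AUROC {ed['p2p1_roc']['auc']:.3f}, "
              f"BCI AUROC {ed['bci_roc']['auc']:.3f}, "
              f"paired DeLong p = {ed['delong_compare']['p']:.3f}")
    if "craniectomy_excluded" in report:
        sub = report["craniectomy_excluded"]
        print(f"craniectomy-excluded sensitivity analysis: n = {sub['n']}, "
              f"r = {sub['pearson_micp_p2p1']['r']:.3f}")


if __name__ == "__main__":
    main()
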