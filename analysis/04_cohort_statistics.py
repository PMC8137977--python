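"""Cohort statistics on the simulated treated cohort.

Reads results/simulated_cohort_manifest.csv (run 02_simulate_cohort.py
first), builds the paired change report (means, SDs, rank-test p values,
relative ratios), the stable/unstable group comparison, and the Spearman
correlations of biomarker percent change against CRT percent change.

Writes results/simulated_change_report.csv,
results/simulated_crt_correlations.csv and
results/simulated_group_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from mcnvquant.biomarkers import PANEL_COLUMNS
from mcnvquant.cli import read_manifest
from mcnvquant.cohort import build_change_report, format_p, group_compare

OUT = Path(__file__).resolve().parents[1] / "results"
MANIFEST = OUT / "simulated_cohort_manifest.csv"


def main() -> None:
    if not MANIFEST.exists():
        raise SystemExit("run analysis/02_simulate_cohort.py first")
    records = read_manifest(MANIFEST)
    report = build_change_report(records, method="rank_sum")
    tbl = report.table.copy()
    tbl["p_display"] = [format_p(p) for p in tbl.p_value]
    tbl.to_csv(OUT / "simulated_change_report.csv", float_format="%.4f")
    print(f"Paired change report over {report.n_pairs} eyes ({report.test_method}):")
    print(tbl[["baseline_mean", "post_mean", "RR_pct", "p_display"]]
          .to_string(float_format=lambda v: f"{v:.3f}"))
    dec = tbl[tbl.RR_pct < 100].sort_values("RR_pct")
    print(f"\nMost sensitive biomarker in the simulation: {dec.index[0]} "
          f"(RR {dec.RR_pct.iloc[0]:.2f}%), least sensitive decreasing marker: "
          f"{dec.index[-1]} (RR {dec.RR_pct.iloc[-1]:.2f}%).")

    corr = report.correlations_with("CRT")
    corr.to_csv(OUT / "simulated_crt_correlations.csv", index=False)
    print("\nPercent-change correlations with CRT:")
    print(corr.to_string(index=False))

    rows = []
    for marker in PANEL_COLUMNS:
        try:
            p = group_compare(records, marker)
        except ValueError:
            p = float("nan")
        rows.append({"biomarker": marker, "mannwhitney_p": round(p, 3)})
    grp = pd.DataFrame(rows)
    grp.to_csv(OUT / "simulated_group_comparison.csv", index=False)
    print("\nStable (<=2 inj.) vs unstable baseline comparison (Mann-Whitney p):")
    print(grp.to_string(index=False))


if __name__ == "__main__":
    main()
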