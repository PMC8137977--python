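"""Published reference values for a 31-eye myopic-CNV anti-VEGF cohort.

These printed group-level numbers — per-eye qualitative OCTA features,
baseline / post-injection biomarker means and SDs with relative ratios, and
Spearman correlations of percent changes against central retinal thickness —
are the inputs of the table-level analyses (the per-eye raw images of the
cohort were never deposited).  CRT summary values are in micrometres.

Two printed relative ratios (vessel density and tortuosity) disagree at the
second decimal with the ratio of their own printed, rounded means — they were
evidently computed from unrounded means — and are flagged accordingly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: biomarkers whose printed RR is reproducible from the printed means
RR_CONSISTENT = ("mCNV_area", "VA", "FD", "VD", "VL", "VJ", "JD", "CRT")
#: printed RR computed from unrounded means; excluded from exact checks
RR_FROM_UNROUNDED = ("VLD", "VT")

#: baseline / post-injection summary per biomarker:
#: (baseline_mean, baseline_sd, post_mean, post_sd, p_printed, rr_printed)
CHANGE_SUMMARY = {
    "mCNV_area": (0.40, 0.52, 0.28, 0.41, "<0.001", 70.00),
    "VA": (0.20, 0.20, 0.13, 0.14, "<0.001", 65.00),
    "VLD": (0.55, 0.09, 0.56, 0.14, "0.829", 102.82),
    "FD": (1.08, 0.15, 0.95, 0.23, "<0.001", 87.96),
    "VD": (31.11, 3.78, 37.47, 13.94, "0.027", 120.44),
    "VL": (6.96, 7.92, 4.38, 5.81, "<0.001", 62.93),
    "VT": (1.26, 0.07, 1.36, 0.33, "0.276", 107.93),
    "VJ": (49.36, 47.43, 24.50, 28.25, "<0.001", 49.64),
    "JD": (7.52, 1.65, 5.09, 2.26, "<0.001", 67.69),
    "CRT": (316.75, 72.72, 257.39, 30.66, "<0.001", 81.26),
}

#: printed mean decrease (%) of the significantly decreasing biomarkers
PRINTED_DECREASES = {
    "mCNV_area": 30.00, "FD": 12.04, "VA": 35.00, "VL": 37.07,
    "VJ": 50.36, "JD": 32.31, "CRT": 18.74,
}
#: printed mean increase (%) of the increasing biomarkers
PRINTED_INCREASES = {"VLD": 1.82, "VD": 20.44, "VT": 7.93}

#: Spearman correlation of percent change of each biomarker with that of CRT
CRT_CORRELATIONS = {
    "mCNV_area": (0.552, 0.002),
    "VA": (0.518, 0.005),
    "VLD": (-0.251, 0.197),
    "FD": (0.446, 0.017),
    "VD": (-0.190, 0.333),
    "VL": (0.440, 0.019),
    "VT": (-0.152, 0.467),
    "VJ": (0.357, 0.062),
    "JD": (-0.090, 0.649),
}

#: the four correlations the source flags as statistically significant
SIGNIFICANT_CRT_CORRELATIONS = ("mCNV_area", "VA", "FD", "VL")


def load_cohort_features() -> pd.DataFrame:
    """Per-eye demographics and qualitative OCTA features of the 31 eyes."""
    with resources.files(__package__).joinpath("data/cohort_features.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"patient_id": str}, na_values=["NA"])
    return df
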