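"""Cohort-level statistics for paired baseline / post-injection biomarker panels.

The statistical layer mirrors how anti-VEGF response is summarised in small
retrospective OCTA cohorts: qualitative feature frequencies, paired rank
tests per biomarker, the relative ratio RR = 100 x post-mean / baseline-mean
as the effect-size measure (decrease% = 100 - RR), Mann-Whitney comparison of
"stable" (<= 2 injections over follow-up) versus "unstable" (> 2) eyes, and
Spearman rank correlation between per-eye percent changes of the OCTA
biomarkers and of central retinal thickness, with the conventional strength
labels (|r| >= 0.90 very strong, 0.70-0.89 strong, 0.40-0.69 moderate,
0.10-0.39 weak, below 0.10 negligible).

Two rank tests are provided for the paired comparison: the rank-sum
(Mann-Whitney) test applied to the two timepoint groups, and the Wilcoxon
signed-rank test on the paired differences.  The signed-rank test is the
statistically conventional choice for paired data; the report computes both
and records which was used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import PANEL_COLUMNS, BiomarkerPanel

#: qualitative OCTA feature columns and their long names
FEATURE_COLUMNS = {
    "overall_pattern": "overall pattern (OI / DVL)",
    "exuberant_capillaries": "exuberant capillaries",
    "anastomoses_loops": "anastomoses and loops",
    "hypointense_halo": "perilesional hypointense halo",
    "feeder_vessel": "feeder vessel",
}

STRENGTH_BINS = (
    (0.90, "very strong"),
    (0.70, "strong"),
    (0.40, "moderate"),
    (0.10, "weak"),
)


@dataclass
class EyeRecord:
    """One study eye: demographics, qualitative features, paired panels."""

    patient_id: str
    eye: str  # "L" or "R"
    age_years: Optional[float] = None
    sex: Optional[str] = None
    se_diopters: Optional[float] = None  # None encodes "NA"
    overall_pattern: str = "OI"
    exuberant_capillaries: str = "N"
    anastomoses_loops: str = "N"
    hypointense_halo: str = "N"
    feeder_vessel: str = "N"
    n_injections: int = 1
    baseline: Optional[BiomarkerPanel] = None
    post_ivi: Optional[BiomarkerPanel] = None

    def __post_init__(self) -> None:
        if self.overall_pattern not in ("OI", "DVL"):
            raise ValueError("overall_pattern must be 'OI' or 'DVL'")
        for name in ("exuberant_capillaries", "anastomoses_loops",
                     "hypointense_halo", "feeder_vessel"):
            if getattr(self, name) not in ("Y", "N"):
                raise ValueError(f"{name} must be 'Y' or 'N'")

    @property
    def group(self) -> str:
        """'stable' for one or two injections, 'unstable' for more than two."""
        return "stable" if self.n_injections <= 2 else "unstable"

    @property
    def is_complete_pair(self) -> bool:
        return self.baseline is not None and self.post_ivi is not None


def summarize_features(records: Sequence[EyeRecord] | pd.DataFrame) -> pd.DataFrame:
    """Count and percentage (2 decimals) of each qualitative feature.

    Accepts EyeRecords or a feature table with the columns of
    :data:`FEATURE_COLUMNS`.  The overall pattern is summarised as the
    frequency of both phenotypes; binary features as the frequency of "Y".
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        if len(records) == 0:
            raise ValueError("no records to summarise")
        df = pd.DataFrame(
            {col: [getattr(r, col) for r in records] for col in FEATURE_COLUMNS}
        )
    if df.empty:
        raise ValueError("no records to summarise")
    n = len(df)
    rows = []
    for value in ("OI", "DVL"):
        k = int((df["overall_pattern"] == value).sum())
        rows.append({"feature": value, "count": k, "total": n,
                     "percent": round(100.0 * k / n, 2)})
    for col in list(FEATURE_COLUMNS)[1:]:
        k = int((df[col] == "Y").sum())
        rows.append({"feature": col, "count": k, "total": n,
                     "percent": round(100.0 * k / n, 2)})
    return pd.DataFrame(rows)


def relative_ratio(baseline_mean: float, post_mean: float) -> float:
    """Post-treatment group mean as a percentage of baseline, to 2 decimals."""
    if baseline_mean == 0:
        raise ValueError("relative ratio undefined for zero baseline mean")
    return round(100.0 * post_mean / baseline_mean, 2)


def _clean_pairs(x: Iterable[float], y: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def paired_change_test(
    baseline: Iterable[float], post: Iterable[float], method: str = "signed_rank"
) -> float:
    """Two-sided p for a baseline/post difference.

    ``signed_rank`` is the Wilcoxon signed-rank test on paired differences;
    ``rank_sum`` ranks the two timepoints as independent groups
    (Mann-Whitney).  Small samples without ties use the exact permutation
    null; otherwise the normal approximation with tie correction is used.
    Missing pairs are dropped.
    """
    x, y = _clean_pairs(baseline, post)
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if method == "signed_rank":
        d = y - x
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 1.0
        nz = d[d != 0]
        exact_ok = len(nz) <= 12
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=True,
            alternative="two-sided", method="exact" if exact_ok else "approx",
        )
        return float(res.pvalue)
    if method == "rank_sum":
        exact_ok = min(len(x), len(y)) <= 12
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if exact_ok else "asymptotic",
        )
        return float(res.pvalue)
    raise ValueError("method must be 'signed_rank' or 'rank_sum'")


def group_compare(
    records: Sequence[EyeRecord], biomarker: str, timepoint: str = "baseline"
) -> float:
    """Two-sided Mann-Whitney p between stable and unstable eyes."""
    if biomarker not in PANEL_COLUMNS:
        raise ValueError(f"unknown biomarker {biomarker!r}")
    values: dict[str, list[float]] = {"stable": [], "unstable": []}
    for r in records:
        panel = r.baseline if timepoint == "baseline" else r.post_ivi
        if panel is None:
            continue
        v = panel.to_row()[biomarker]
        if not math.isnan(v):
            values[r.group].append(v)
    a, b = values["stable"], values["unstable"]
    if not a or not b:
        raise ValueError("both stable and unstable groups must be non-empty")
    exact_ok = min(len(a), len(b)) <= 12
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
    )
    return float(res.pvalue)


def spearman_with_label(
    x: Iterable[float], y: Iterable[float]
) -> tuple[float, float, str]:
    """Spearman rank correlation with a conventional strength label."""
    x, y = _clean_pairs(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p), correlation_strength(r)


def correlation_strength(r: float) -> str:
    """Map |r| to the conventional strength label."""
    a = abs(r)
    for cutoff, label in STRENGTH_BINS:
        if a >= cutoff:
            return label
    return "negligible"


@dataclass
class ChangeReport:
    """Per-biomarker paired-change table plus per-eye percent-change vectors."""

    table: pd.DataFrame  # indexed by biomarker
    percent_change: pd.DataFrame  # eyes x biomarkers, PC = 100*(post-base)/base
    n_pairs: int
    test_method: str

    def correlations_with(self, target: str = "CRT") -> pd.DataFrame:
        """Spearman correlation of each biomarker's percent change with
        the percent change of ``target`` (conventionally CRT)."""
        out = []
        tgt = self.percent_change[target]
        for col in self.percent_change.columns:
            if col == target:
                continue
            try:
                r, p, label = spearman_with_label(self.percent_change[col], tgt)
            except ValueError:
                r, p, label = float("nan"), float("nan"), "undefined"
            out.append({"biomarker": col, "r": round(r, 3), "p": round(p, 3),
                        "strength": label})
        return pd.DataFrame(out)


def build_change_report(
    records: Sequence[EyeRecord], method: str = "rank_sum"
) -> ChangeReport:
    """Means, SDs, paired p, RR and decrease%% per biomarker, plus PC vectors.

    Eyes without a post-injection panel (e.g. fully regressed lesions that can
    no longer be outlined) are excluded.  RR is the ratio of group means, not
    the mean of per-eye ratios.
    """
    pairs = [r for r in records if r.is_complete_pair]
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete baseline/post pairs")
    base = pd.DataFrame([r.baseline.to_row() for r in pairs],
                        index=[f"{r.patient_id}_{r.eye}" for r in pairs])
    post = pd.DataFrame([r.post_ivi.to_row() for r in pairs], index=base.index)

    rows = []
    for col in PANEL_COLUMNS:
        b, a = base[col], post[col]
        bm, bs = float(b.mean()), float(b.std(ddof=1))
        am, asd = float(a.mean()), float(a.std(ddof=1))
        try:
            p = paired_change_test(b, a, method=method)
        except ValueError:
            p = float("nan")
        rr = relative_ratio(bm, am) if bm != 0 else float("nan")
        rows.append({
            "biomarker": col,
            "baseline_mean": bm, "baseline_sd": bs,
            "post_mean": am, "post_sd": asd,
            "p_value": p,
            "RR_pct": rr,
            "decrease_pct": round(100.0 - rr, 2) if not math.isnan(rr) else float("nan"),
        })
    table = pd.DataFrame(rows).set_index("biomarker")

    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 100.0 * (post - base) / base
    pc = pc.replace([np.inf, -np.inf], np.nan)

    return ChangeReport(table=table, percent_change=pc,
                        n_pairs=len(pairs), test_method=method)


def format_p(p: float) -> str:
    """Display convention: three decimals, floored at '<0.001'."""
    if math.isnan(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"
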