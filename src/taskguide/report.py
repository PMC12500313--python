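"""Study-style statistical summaries of session datasets.

Descriptives are median (Q1–Q3, linear-interpolation quantiles).
Between-group comparisons use the Mann-Whitney rank-sum test, paired
within-group comparisons across the two conditions use the Wilcoxon
signed-rank test (exact for small n, normal approximation above 25
non-tied pairs), and binary covariates are compared with Fisher's exact
test.  All tests are two-sided at alpha = 0.05; with the small cohorts
this serves, no multiplicity correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonReport",
    "summarize",
    "percent_change",
    "rank_sum",
    "signed_rank",
    "DEFAULT_METRICS",
]

DEFAULT_METRICS = ("completion_time_s", "completion_score", "efpt_score")


def percent_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``: 100*(before-after)/before,
    rounded to one decimal place.  Positive = reduction/improvement.

    Scale-invariant: percent_change(k*b, k*a) == percent_change(b, a).
    """
    if before <= 0:
        raise ValueError(f"'before' must be positive, got {before}")
    return round(100.0 * (before - after) / before, 1)


def rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for the first sample, p)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def signed_rank(
    before: Sequence[float], after: Sequence[float]
) -> tuple[Optional[float], Optional[float], str]:
    """Two-sided Wilcoxon signed-rank on paired samples.

    Returns (W, p, note).  Pairs with missing values are dropped; if
    every pair is tied the test is not computable and (None, None,
    reason) is returned rather than raising.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(b) | np.isnan(a))
    b, a = b[keep], a[keep]
    if b.size == 0:
        return (None, None, "no complete pairs")
    diffs = b - a
    nonzero = int(np.count_nonzero(diffs))
    if nonzero == 0:
        return (None, None, "all pairs tied; signed-rank not computable")
    # scipy's auto policy: exact when n is small and there are no
    # ties/zeros, normal approximation otherwise — matches small-cohort use
    res = stats.wilcoxon(b, a, alternative="two-sided", method="auto")
    return (float(res.statistic), float(res.pvalue), "")


@dataclass
class GroupComparisonReport:
    descriptives: pd.DataFrame  # group, condition, metric, n, median, q1, q3
    between_group: pd.DataFrame  # metric, condition, statistic, p_value
    within_group: pd.DataFrame  # group, metric, statistic, p_value, note
    percent_change_of_medians: pd.DataFrame  # group, metric, value
    categorical: Optional[dict]  # Fisher exact on a binary covariate

    def to_json(self, path=None) -> str:
        payload = {
            "descriptives": self.descriptives.to_dict(orient="records"),
            "between_group": self.between_group.to_dict(orient="records"),
            "within_group": self.within_group.to_dict(orient="records"),
            "percent_change_of_medians": self.percent_change_of_medians.to_dict(
                orient="records"
            ),
            "categorical": self.categorical,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _median_iqr(values: pd.Series) -> tuple[float, float, float]:
    v = values.dropna().to_numpy(dtype=float)
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def summarize(
    dataset: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_METRICS,
    group_col: str = "group",
    condition_col: str = "condition",
    participant_col: str = "participant_id",
    binary_covariate: Optional[str] = "sex",
) -> GroupComparisonReport:
    """Summarize a paired two-group session dataset.

    Expects one row per session with a group label, a condition label
    (``unassisted``/``assisted``), and the metric columns.  Produces
    median (IQR) descriptives per group x condition, rank-sum tests
    between groups per condition, signed-rank tests within group across
    conditions, percent change of group medians from unassisted to
    assisted, and (when a binary covariate column is present) a Fisher
    exact comparison of its distribution between groups.
    """
    groups = sorted(dataset[group_col].dropna().unique())
    conditions = sorted(dataset[condition_col].dropna().unique())
    for g in groups:
        if (dataset[group_col] == g).sum() < 1:
            raise ValueError(f"group {g!r} has no sessions")
    metrics = [m for m in metrics if m in dataset.columns]

    desc_rows = []
    for g in groups:
        for cond in conditions:
            sub = dataset[(dataset[group_col] == g) & (dataset[condition_col] == cond)]
            for metric in metrics:
                med, q1, q3 = _median_iqr(sub[metric])
                desc_rows.append(
                    {
                        "group": g,
                        "condition": cond,
                        "metric": metric,
                        "n": int(sub[metric].notna().sum()),
                        "median": med,
                        "q1": q1,
                        "q3": q3,
                    }
                )
    descriptives = pd.DataFrame(desc_rows)

    between_rows = []
    if len(groups) == 2:
        ga, gb = groups
        for cond in conditions:
            for metric in metrics:
                xa = dataset[
                    (dataset[group_col] == ga) & (dataset[condition_col] == cond)
                ][metric].dropna()
                xb = dataset[
                    (dataset[group_col] == gb) & (dataset[condition_col] == cond)
                ][metric].dropna()
                stat, p = rank_sum(xa, xb)
                between_rows.append(
                    {
                        "metric": metric,
                        "condition": cond,
                        "statistic": stat,
                        "p_value": p,
                    }
                )
    between_group = pd.DataFrame(
        between_rows, columns=["metric", "condition", "statistic", "p_value"]
    )

    within_rows = []
    pct_rows = []
    if len(conditions) == 2:
        ca, cb = conditions  # sorted: ("assisted", "unassisted")
        unassisted, assisted = (cb, ca) if ca == "assisted" else (ca, cb)
        for g in groups:
            sub = dataset[dataset[group_col] == g]
            wide = sub.pivot_table(
                index=participant_col, columns=condition_col, aggfunc="first"
            )
            for metric in metrics:
                before = wide[(metric, unassisted)]
                after = wide[(metric, assisted)]
                stat, p, note = signed_rank(before.to_numpy(), after.to_numpy())
                within_rows.append(
                    {
                        "group": g,
                        "metric": metric,
                        "statistic": stat,
                        "p_value": p,
                        "note": note,
                    }
                )
                med_before = float(np.nanmedian(before.to_numpy(dtype=float)))
                med_after = float(np.nanmedian(after.to_numpy(dtype=float)))
                pct_rows.append(
                    {
                        "group": g,
                        "metric": metric,
                        "median_unassisted": med_before,
                        "median_assisted": med_after,
                        "percent_change": percent_change(med_before, med_after)
                        if med_before > 0
                        else None,
                    }
                )
    within_group = pd.DataFrame(
        within_rows, columns=["group", "metric", "statistic", "p_value", "note"]
    )
    pct = pd.DataFrame(
        pct_rows,
        columns=[
            "group",
            "metric",
            "median_unassisted",
            "median_assisted",
            "percent_change",
        ],
    )

    categorical = None
    if (
        binary_covariate
        and binary_covariate in dataset.columns
        and len(groups) == 2
    ):
        per_participant = dataset.drop_duplicates(subset=[participant_col])
        table = pd.crosstab(
            per_participant[group_col], per_participant[binary_covariate]
        )
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table.to_numpy())
            categorical = {
                "covariate": binary_covariate,
                "table": table.to_dict(),
                "odds_ratio": float(odds),
                "p_value": float(p),
            }

    return GroupComparisonReport(
        descriptives=descriptives,
        between_group=between_group,
        within_group=within_group,
        percent_change_of_medians=pct,
        categorical=categorical,
    )
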