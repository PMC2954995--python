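"""Paired and two-sample statistics, group summaries, splits and dropout.

The paired analysis follows the endpoint design: for each client the
difference baseline - LOCF is formed, and

    t = mean(d) / (sd(d) / sqrt(n)),      d_Cohen = mean(d) / sd(d),

with the n-1 (sample) standard deviation, so t = d_Cohen * sqrt(n) and the
p-value comes from the t distribution with n-1 degrees of freedom
(two-sided).  Cohen's d here is the paired effect size: the mean change in
units of the between-client standard deviation of the changes.

Two-sample comparisons use Welch's unequal-variance t with the
Welch-Satterthwaite degrees of freedom (a pooled-variance Student t is
available behind a flag).  No multiple-testing correction is applied; the
analysis reports each test as-is.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    ClientProfile,
    CohortSummary,
    PairedTestResult,
    SeverityEndpoints,
    TwoSampleTestResult,
)

__all__ = [
    "paired_test",
    "two_sample_test",
    "summarize_group",
    "split_analyses",
    "dropout_analysis",
]


def paired_test(baseline: Sequence[float], locf: Sequence[float]) -> PairedTestResult:
    """Paired t-test of baseline vs LOCF with Cohen's d on the differences.

    Zero variance of the differences is flagged degenerate (t, p = NaN)
    rather than returned as an infinity.
    """
    b = np.asarray(baseline, dtype=float)
    l = np.asarray(locf, dtype=float)
    if b.shape != l.shape:
        raise ValueError("paired vectors must have equal length")
    n = b.size
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    d = b - l
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        return PairedTestResult(n, mean_d, 0.0, math.nan, n - 1, math.nan, math.nan, True)
    es = mean_d / sd_d
    t = es * math.sqrt(n)
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTestResult(n, mean_d, sd_d, t, n - 1, float(p), es)


def two_sample_test(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = True
) -> TwoSampleTestResult:
    """Two-sample t-test of group means (Welch by default).

    With ``welch=False`` the classic pooled-variance Student t is used.
    Both groups having zero variance is flagged degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        return TwoSampleTestResult(
            na, nb, float(a.mean()), float(b.mean()), math.nan, math.nan, math.nan, True
        )
    diff = float(a.mean() - b.mean())
    if welch:
        se2a, se2b = va / na, vb / nb
        se = math.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TwoSampleTestResult(na, nb, float(a.mean()), float(b.mean()), t, float(df), float(p))


# ---------------------------------------------------------------- summaries


def _pct_change(before: float, after: float) -> float | None:
    return 100.0 * (after - before) / before if before > 0 else None


def summarize_group(
    endpoints: Sequence[SeverityEndpoints], label: str
) -> CohortSummary:
    """Aggregate one group's endpoints into a summary-table row.

    Percent changes of means and of medians are computed from the group
    aggregates; responder fractions use the strict per-client thresholds and
    exclude clients whose percent change is undefined (baseline 0), whose
    count is reported separately.
    """
    if len(endpoints) < 2:
        raise ValueError(f"group {label!r} needs >= 2 members with endpoints")
    base = np.array([e.baseline_severity for e in endpoints], dtype=float)
    locf = np.array([e.locf_severity for e in endpoints], dtype=float)
    test = paired_test(base, locf)

    pcts = [e.pct_change for e in endpoints if e.pct_change is not None]
    n_defined = len(pcts)
    n_undefined = len(endpoints) - n_defined

    def frac(flag: str) -> float:
        if n_defined == 0:
            return 0.0
        return sum(getattr(e, flag) for e in endpoints if e.pct_change is not None) / n_defined

    b_med, l_med = float(np.median(base)), float(np.median(locf))
    return CohortSummary(
        group_label=label,
        n=len(endpoints),
        baseline_mean=float(base.mean()),
        baseline_median=b_med,
        baseline_sd=float(base.std(ddof=1)),
        locf_mean=float(locf.mean()),
        locf_median=l_med,
        locf_sd=float(locf.std(ddof=1)),
        pct_change_of_means=_pct_change(float(base.mean()), float(locf.mean())),
        pct_change_of_medians=_pct_change(b_med, l_med),
        effect_size_d=None if test.degenerate else test.effect_size_d,
        t_statistic=None if test.degenerate else test.t_statistic,
        p_value=None if test.degenerate else test.p_value,
        frac_reduction_gt_30=frac("responder_30"),
        frac_reduction_gt_50=frac("responder_50"),
        frac_symptom_free=sum(e.symptom_free for e in endpoints) / len(endpoints),
        frac_worsened=sum(e.worsened for e in endpoints) / len(endpoints),
        median_pct_change=float(np.median(pcts)) if pcts else None,
        n_pct_undefined=n_undefined,
    )


def _summary_or_none(endpoints, label):
    try:
        return summarize_group(endpoints, label)
    except ValueError:
        return None


def _cross_tests(side_a, side_b, welch: bool) -> dict:
    """Welch comparisons of the two sides at baseline and at LOCF; None when
    a side is too small."""
    out = {"baseline": None, "locf": None}
    if len(side_a) >= 2 and len(side_b) >= 2:
        out["baseline"] = two_sample_test(
            [e.baseline_severity for e in side_a], [e.baseline_severity for e in side_b], welch
        )
        out["locf"] = two_sample_test(
            [e.locf_severity for e in side_a], [e.locf_severity for e in side_b], welch
        )
    return out


def split_analyses(
    endpoints: Sequence[SeverityEndpoints],
    profiles: Mapping[str, ClientProfile],
    label_prefix: str = "",
    age_cut: int = 12,
    welch: bool = True,
) -> dict:
    """Median, age and sex splits of one group, each with cross-group tests.

    Baseline-median split: clients sorted by (baseline severity, client_id);
    the lower half is "below" — with odd n the median client falls in
    "below".  Age split: "older" is age >= ``age_cut`` at monitoring start.
    Each split maps to {sides: {name: CohortSummary|None}, tests: {baseline,
    locf}} where a side with fewer than two members is None and its tests
    unavailable.
    """
    eps = list(endpoints)
    out: dict[str, dict] = {}

    ordered = sorted(eps, key=lambda e: (e.baseline_severity, e.client_id))
    n_below = (len(ordered) + 1) // 2
    below, above = ordered[:n_below], ordered[n_below:]
    out["baseline_median"] = {
        "sides": {
            "above": _summary_or_none(above, f"{label_prefix}above_baseline_median"),
            "below": _summary_or_none(below, f"{label_prefix}below_baseline_median"),
        },
        "tests": _cross_tests(above, below, welch),
    }

    older = [e for e in eps if profiles[e.client_id].age_years >= age_cut]
    younger = [e for e in eps if profiles[e.client_id].age_years < age_cut]
    out["age"] = {
        "sides": {
            "older": _summary_or_none(older, f"{label_prefix}age_{age_cut}_plus"),
            "younger": _summary_or_none(younger, f"{label_prefix}age_under_{age_cut}"),
        },
        "tests": _cross_tests(older, younger, welch),
    }

    male = [e for e in eps if profiles[e.client_id].sex == "male"]
    female = [e for e in eps if profiles[e.client_id].sex == "female"]
    out["sex"] = {
        "sides": {
            "male": _summary_or_none(male, f"{label_prefix}male"),
            "female": _summary_or_none(female, f"{label_prefix}female"),
        },
        "tests": _cross_tests(male, female, welch),
    }
    return out


def dropout_analysis(
    endpoints: Sequence[SeverityEndpoints], welch: bool = True
) -> dict:
    """Outcomes by last reported month, and stop-vs-continue comparisons.

    Per LOCF month 3-6: n, median per-client percent reduction, and the
    paired baseline-vs-LOCF test (None when n < 2).  For each month m in
    {3, 4, 5}: a Welch test of baseline severity between clients whose last
    month was m and clients who continued past m (None when a side has
    fewer than two clients).
    """
    eps = list(endpoints)
    by_month = pd.DataFrame(
        {
            "month": [e.locf_month for e in eps],
            "base": [e.baseline_severity for e in eps],
            "locf": [e.locf_severity for e in eps],
            "reduction": [None if e.pct_change is None else -e.pct_change for e in eps],
        }
    )
    rows = []
    tests: dict[int, PairedTestResult | None] = {}
    for m in range(3, 7):
        g = by_month[by_month["month"] == m]
        reds = g["reduction"].dropna()
        tests[m] = (
            paired_test(g["base"].to_numpy(), g["locf"].to_numpy()) if len(g) >= 2 else None
        )
        rows.append(
            {
                "last_month": m,
                "n": int(len(g)),
                "median_pct_reduction": float(np.median(reds)) if len(reds) else None,
                "t_statistic": getattr(tests[m], "t_statistic", None),
                "p_value": getattr(tests[m], "p_value", None),
                "effect_size_d": getattr(tests[m], "effect_size_d", None),
            }
        )
    stop_vs_continue: dict[int, TwoSampleTestResult | None] = {}
    for m in (3, 4, 5):
        stopped = by_month[by_month["month"] == m]["base"]
        continued = by_month[by_month["month"] > m]["base"]
        stop_vs_continue[m] = (
            two_sample_test(stopped, continued, welch)
            if len(stopped) >= 2 and len(continued) >= 2
            else None
        )
    return {
        "table": pd.DataFrame(rows),
        "paired_tests": tests,
        "stop_vs_continue": stop_vs_continue,
    }
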