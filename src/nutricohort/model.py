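"""Domain records for daily-checklist cohort analysis.

The data model mirrors a naturalistic monitoring database: clients (children
aged 7 to <18 with a parent-reported bipolar and/or ADHD diagnosis), daily
item-level symptom checklists on two scales, and dated medication dose
statements.  Day numbering is anchored at treatment start: day 0 is the first
day on the formula, negative days are pre-treatment.

Scales
------
``bipolar``
    16 mood items, each scored 0-3; severity is the sum of all 16 items
    (range 0-48).
``adhd``
    8 recorded items, each scored 0-3, but only the first three (inattention,
    impulsivity, hyperactivity) are specific to ADHD; severity is the sum of
    those three items (range 0-9).  All 8 items are retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "SCALES",
    "SCALE_N_ITEMS",
    "SEVERITY_N_ITEMS",
    "SEVERITY_MAX",
    "MAX_ITEM_SCORE",
    "ITEM_COLUMNS",
    "scale_severity",
    "ClientProfile",
    "SymptomReport",
    "MedicationRecord",
    "SeverityEndpoints",
    "MedicationIndexResult",
    "CohortSummary",
    "SampleDefinition",
    "PairedTestResult",
    "TwoSampleTestResult",
    "ValidationError",
    "EndpointUndefined",
]

SCALES = ("bipolar", "adhd")
#: number of item scores recorded per report
SCALE_N_ITEMS = {"bipolar": 16, "adhd": 8}
#: number of leading items that enter the severity total
SEVERITY_N_ITEMS = {"bipolar": 16, "adhd": 3}
SEVERITY_MAX = {"bipolar": 48, "adhd": 9}
MAX_ITEM_SCORE = 3
#: CSV column names for item scores, widest scale first
ITEM_COLUMNS = tuple(f"item_{i}" for i in range(1, 17))

MIN_AGE_YEARS = 7
MAX_AGE_YEARS_EXCL = 18


class ValidationError(ValueError):
    """Raised when raw input rows violate the documented schemas."""


class EndpointUndefined(ValueError):
    """Raised when a client lacks the data required for an endpoint.

    Carries a machine-readable ``reason`` (e.g. ``"too_few_reporting_days"``,
    ``"no_locf_month"``) so callers can tally exclusions.
    """

    def __init__(self, reason: str, message: str | None = None):
        super().__init__(message or reason)
        self.reason = reason


def scale_severity(scale: str, item_scores: Sequence[int]) -> int:
    """Severity total for one report under the scale's scoring rule.

    Bipolar sums all 16 items; ADHD sums only the first three recorded items.
    """
    if scale not in SCALES:
        raise ValidationError(f"unknown scale {scale!r}")
    n = SCALE_N_ITEMS[scale]
    if len(item_scores) != n:
        raise ValidationError(
            f"{scale} report needs {n} item scores, got {len(item_scores)}"
        )
    for i, s in enumerate(item_scores, start=1):
        if s not in (0, 1, 2, 3):
            raise ValidationError(f"item_{i} score {s!r} outside 0..3")
    return int(sum(item_scores[: SEVERITY_N_ITEMS[scale]]))


@dataclass(frozen=True)
class ClientProfile:
    """Demographics, parent-reported diagnoses and the treatment-start anchor."""

    client_id: str
    age_years: int
    sex: str  # "male" | "female"
    dx_bipolar: bool
    dx_adhd: bool
    treatment_start_day: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")

    @property
    def age_eligible(self) -> bool:
        return MIN_AGE_YEARS <= self.age_years < MAX_AGE_YEARS_EXCL


@dataclass(frozen=True)
class SymptomReport:
    """One client-day's item-level checklist for one scale.

    ``severity`` is derived from ``item_scores`` by :func:`scale_severity`;
    passing ``severity=None`` computes it.
    """

    client_id: str
    day: int
    scale: str
    item_scores: tuple
    severity: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_scores", tuple(int(s) for s in self.item_scores))
        expected = scale_severity(self.scale, self.item_scores)
        if self.severity is None:
            object.__setattr__(self, "severity", expected)
        elif int(self.severity) != expected:
            raise ValidationError(
                f"severity {self.severity} inconsistent with items (expect {expected})"
            )


@dataclass(frozen=True)
class MedicationRecord:
    """A dated dose statement; dose 0 marks discontinuation from that day.

    Doses are in arbitrary per-medication units: the Medication Index is
    unit-free because each medication is normalised by the client's own
    maximum dose of it.
    """

    client_id: str
    day: int
    medication: str
    dose: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValidationError(f"dose must be >= 0, got {self.dose}")


@dataclass(frozen=True)
class SeverityEndpoints:
    """Per-client baseline and LOCF severity on one scale, with responder flags.

    ``pct_change`` is 100 x (LOCF - baseline)/baseline — negative means
    improvement — and is ``None`` (undefined) when baseline is 0.  Responder
    flags use strict thresholds: ``responder_30`` iff reduction > 30%,
    ``responder_50`` iff reduction > 50%.
    """

    client_id: str
    scale: str
    baseline_severity: float
    locf_severity: float
    locf_month: int
    pct_change: float | None
    responder_30: bool
    responder_50: bool
    symptom_free: bool
    worsened: bool


@dataclass(frozen=True)
class MedicationIndexResult:
    """Dose-normalised Medication Index at baseline and LOCF for one client.

    The index sums, over medications, the in-effect dose divided by the
    client's personal maximum dose of that medication; it equals the count of
    active medications exactly when each is at its personal maximum.
    """

    client_id: str
    baseline_index: float
    locf_index: float
    personal_max: Mapping[str, float]


#: fixed field/column order for summary exports
COHORT_SUMMARY_FIELDS = (
    "group_label",
    "n",
    "baseline_mean",
    "baseline_median",
    "baseline_sd",
    "locf_mean",
    "locf_median",
    "locf_sd",
    "pct_change_of_means",
    "pct_change_of_medians",
    "effect_size_d",
    "t_statistic",
    "p_value",
    "frac_reduction_gt_30",
    "frac_reduction_gt_50",
    "frac_symptom_free",
    "frac_worsened",
    "median_pct_change",
    "n_pct_undefined",
)


@dataclass(frozen=True)
class CohortSummary:
    """One aggregate row per group, mirroring the severity summary tables.

    Two median-percent-change conventions are reported side by side:
    ``pct_change_of_medians`` (percent change of the group medians) and
    ``median_pct_change`` (median of the per-client percent changes).
    Clients whose per-client percent change is undefined (baseline 0) are
    excluded from responder fractions and counted in ``n_pct_undefined``.
    """

    group_label: str
    n: int
    baseline_mean: float
    baseline_median: float
    baseline_sd: float
    locf_mean: float
    locf_median: float
    locf_sd: float
    pct_change_of_means: float | None
    pct_change_of_medians: float | None
    effect_size_d: float | None
    t_statistic: float | None
    p_value: float | None
    frac_reduction_gt_30: float
    frac_reduction_gt_50: float
    frac_symptom_free: float
    frac_worsened: float
    median_pct_change: float | None
    n_pct_undefined: int


@dataclass
class SampleDefinition:
    """An analysis sample: label, member ids, and a tally of exclusions."""

    label: str
    member_ids: set = field(default_factory=set)
    excluded_counts: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test with Cohen's d on the within-client differences.

    ``effect_size_d`` = mean(diff)/sd(diff) with the n-1 denominator, so
    ``t_statistic`` = d * sqrt(n).  ``degenerate`` flags sd(diff) == 0, in
    which case t and p are NaN rather than infinite.
    """

    n: int
    mean_diff: float
    sd_diff: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    effect_size_d: float
    degenerate: bool = False


@dataclass(frozen=True)
class TwoSampleTestResult:
    """Welch unequal-variance two-sample t-test."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    degenerate: bool = False
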