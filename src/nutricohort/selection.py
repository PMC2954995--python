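"""Eligibility filtering into analysis samples.

A client enters the Primary Sample when the parent reported a bipolar
diagnosis, age at monitoring start is 7 to <18, symptom reports cover at
least 60 distinct days of the first 180, and at least one report falls in
months 3-6 (otherwise no LOCF month exists and the endpoint analysis is
undefined).  The Primary Sample splits into bipolar-without-ADHD and
bipolar-with-ADHD sub-samples; the Alternative Sample holds ADHD-but-not-
bipolar clients under the same reporting rules.

Reporting days are counted across scales: any checklist submitted on a day
counts that day once.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .endpoints import LOCF_FIRST_MONTH, assign_month
from .io import reports_to_frame
from .model import ClientProfile, SampleDefinition, SymptomReport

__all__ = [
    "count_reporting_days",
    "select_samples",
    "SAMPLE_LABELS",
    "selection_report",
]

SAMPLE_LABELS = (
    "primary_bipolar",
    "bipolar_not_adhd",
    "bipolar_and_adhd",
    "adhd_not_bipolar",
)

#: exclusion reasons, in the order they are checked per client
EXCLUSION_REASONS = ("age", "no_qualifying_dx", "insufficient_reporting", "no_locf_month")


def count_reporting_days(reports, window_days: int = 180) -> int:
    """Distinct days d with 0 <= d < window_days having any symptom report.

    ``reports`` may be SymptomReport records or a frame with a ``day`` column;
    all must belong to one client.  Pre-treatment days do not count.
    """
    days = _days_array(reports)
    if days.size == 0:
        return 0
    in_window = days[(days >= 0) & (days < window_days)]
    return int(np.unique(in_window).size)


def _days_array(reports) -> np.ndarray:
    if isinstance(reports, pd.DataFrame):
        return reports["day"].to_numpy(dtype=int) if len(reports) else np.array([], int)
    return np.array([r.day for r in reports], dtype=int)


def _has_locf_month(days: np.ndarray, window_days: int) -> bool:
    months = np.array([assign_month(int(d)) or 0 for d in days[(days >= 0) & (days < window_days)]])
    return bool((months >= LOCF_FIRST_MONTH).any())


def select_samples(
    clients: Iterable[ClientProfile],
    reports: Iterable[SymptomReport] | pd.DataFrame,
    min_days: int = 60,
    window: int = 180,
) -> list[SampleDefinition]:
    """Partition clients into the four analysis samples.

    Returns SampleDefinitions for ``primary_bipolar``, its two diagnosis
    sub-samples, and ``adhd_not_bipolar``, each carrying a tally of exclusion
    reasons (age, no_qualifying_dx, insufficient_reporting, no_locf_month).
    A client failing several rules is tallied under the first in that order.
    """
    rdf = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(list(reports))
    if len(rdf):
        days_by_client = {
            cid: g["day"].to_numpy(dtype=int) for cid, g in rdf.groupby("client_id")
        }
    else:
        days_by_client = {}

    samples = {label: SampleDefinition(label, set(), Counter()) for label in SAMPLE_LABELS}

    for c in clients:
        if c.dx_bipolar:
            targets = ["primary_bipolar", "bipolar_and_adhd" if c.dx_adhd else "bipolar_not_adhd"]
        elif c.dx_adhd:
            targets = ["adhd_not_bipolar"]
        else:
            targets = []

        reason = None
        if not c.age_eligible:
            reason = "age"
        elif not targets:
            reason = "no_qualifying_dx"
        else:
            days = days_by_client.get(c.client_id, np.array([], dtype=int))
            if count_reporting_days(days_to_frame(days), window) < min_days:
                reason = "insufficient_reporting"
            elif not _has_locf_month(days, window):
                reason = "no_locf_month"

        if reason is None:
            for label in targets:
                samples[label].member_ids.add(c.client_id)
        else:
            # clients with neither diagnosis are tallied once, on the primary sample
            for label in targets or ["primary_bipolar"]:
                samples[label].excluded_counts[reason] += 1

    for s in samples.values():
        s.excluded_counts = dict(s.excluded_counts)
    return [samples[label] for label in SAMPLE_LABELS]


def days_to_frame(days: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"day": days})


def selection_report(samples: Sequence[SampleDefinition]) -> pd.DataFrame:
    """Flat exclusion/membership tally, one row per sample."""
    rows = []
    for s in samples:
        row = {"sample": s.label, "n_members": len(s.member_ids)}
        for reason in EXCLUSION_REASONS:
            row[f"excluded_{reason}"] = s.excluded_counts.get(reason, 0)
        rows.append(row)
    return pd.DataFrame(rows)
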