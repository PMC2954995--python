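"""The dose-normalised Medication Index.

For each psychiatric medication a client reports, the dose in effect on a
day is the last recorded dose carried forward (0 before the first record,
and 0 after an explicit zero-dose record, which marks discontinuation).
Each medication is normalised by the client's *personal maximum* — the
largest dose of it they recorded anywhere from baseline through month 6 —
and the index over a window is the sum over medications of the window-mean
in-effect dose divided by that maximum.

A client taking four medications at their personal maxima therefore has an
index of 4; if one of the four drops by 25% of its maximum for the whole
final reporting month, the index over that month is 3.75.  Because the
normalisation is per-client and per-medication, the index is invariant to
the units each dose happens to be recorded in.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .endpoints import MONTH_DAYS, N_MONTHS
from .model import MedicationIndexResult, MedicationRecord

__all__ = [
    "personal_max_doses",
    "index_at_window",
    "client_medication_index",
    "medication_summary",
]

#: records on days >= this are outside the analysis span
SPAN_END_DAY = MONTH_DAYS * N_MONTHS


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            [
                {"client_id": r.client_id, "day": r.day, "medication": r.medication, "dose": r.dose}
                for r in records
            ],
            columns=["client_id", "day", "medication", "dose"],
        )
    return df[df["day"] < SPAN_END_DAY]


def personal_max_doses(records: Iterable[MedicationRecord] | pd.DataFrame) -> dict[str, float]:
    """Per-medication maximum dose for one client over baseline..month 6.

    Medications that never have a positive dose are omitted.
    """
    df = _records_frame(records)
    if len(df) == 0:
        return {}
    maxima = df.groupby("medication")["dose"].max()
    return {med: float(d) for med, d in maxima.items() if d > 0}


def _mean_dose_in_effect(days: np.ndarray, doses: np.ndarray, window: np.ndarray) -> float:
    """Window-mean of the carried-forward step function of one medication."""
    idx = np.searchsorted(days, window, side="right") - 1
    in_effect = np.where(idx >= 0, doses[np.clip(idx, 0, None)], 0.0)
    return float(in_effect.mean())


def index_at_window(
    records: Iterable[MedicationRecord] | pd.DataFrame,
    window_days: Sequence[int],
    personal_max: Mapping[str, float] | None = None,
) -> float:
    """Medication Index for one client over a set of days.

    ``window_days`` is the set of days the index is averaged over (for the
    baseline index, the same days the severity baseline used; for the LOCF
    index, the days of the LOCF month).  ``personal_max`` defaults to the
    maxima computed from ``records`` over the whole span.
    """
    window = np.asarray(sorted(set(int(d) for d in window_days)), dtype=int)
    if window.size == 0:
        raise ValueError("empty medication-index window")
    df = _records_frame(records)
    if personal_max is None:
        personal_max = personal_max_doses(df)
    total = 0.0
    for med, g in df.groupby("medication"):
        pmax = personal_max.get(med, 0.0)
        if pmax <= 0:
            continue
        g = g.sort_values("day")
        mean_dose = _mean_dose_in_effect(
            g["day"].to_numpy(dtype=int), g["dose"].to_numpy(dtype=float), window
        )
        total += mean_dose / pmax
    return total


def client_medication_index(
    records: Iterable[MedicationRecord] | pd.DataFrame,
    client_id: str,
    baseline_days: Sequence[int],
    locf_month: int,
) -> MedicationIndexResult:
    """Baseline and LOCF indices for one client.

    The LOCF window is every day of the client's LOCF month; a client with
    no medication records has both indices 0.
    """
    df = _records_frame(records)
    df = df[df["client_id"] == client_id]
    pmax = personal_max_doses(df)
    locf_days = range(MONTH_DAYS * (locf_month - 1), MONTH_DAYS * locf_month)
    if not pmax:
        return MedicationIndexResult(client_id, 0.0, 0.0, {})
    return MedicationIndexResult(
        client_id=client_id,
        baseline_index=index_at_window(df, baseline_days, pmax),
        locf_index=index_at_window(df, locf_days, pmax),
        personal_max=pmax,
    )


def _pct_change(before: float, after: float) -> float | None:
    return 100.0 * (after - before) / before if before > 0 else None


def medication_summary(
    label: str, indices: Sequence[MedicationIndexResult]
) -> pd.DataFrame:
    """Three-row medication summary for one sample.

    Rows: percent of clients with a positive index (baseline, LOCF, relative
    change); mean index among clients medicated at baseline; mean index over
    all clients — each with the percent change of the means.  Percent changes
    are None when the baseline figure is 0 (a medication-free cohort).
    """
    if not indices:
        raise ValueError(f"empty sample {label!r}")
    base = np.array([r.baseline_index for r in indices], dtype=float)
    locf = np.array([r.locf_index for r in indices], dtype=float)
    takers = base > 0

    pct_base = 100.0 * takers.mean()
    pct_locf = 100.0 * (locf > 0).mean()
    mean_base_takers = float(base[takers].mean()) if takers.any() else 0.0
    mean_locf_takers = float(locf[takers].mean()) if takers.any() else 0.0

    rows = [
        {
            "sample": label,
            "measure": "pct_taking_medication",
            "baseline": pct_base,
            "locf": pct_locf,
            "pct_change": _pct_change(pct_base, pct_locf),
        },
        {
            "sample": label,
            "measure": "mean_index_baseline_takers",
            "baseline": mean_base_takers,
            "locf": mean_locf_takers,
            "pct_change": _pct_change(mean_base_takers, mean_locf_takers),
        },
        {
            "sample": label,
            "measure": "mean_index_all_clients",
            "baseline": float(base.mean()),
            "locf": float(locf.mean()),
            "pct_change": _pct_change(float(base.mean()), float(locf.mean())),
        },
    ]
    return pd.DataFrame(rows)
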