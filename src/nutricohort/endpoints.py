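"""Baseline and Last-Observation-Carried-Forward severity endpoints.

Baseline: the mean severity over all pre-treatment reporting days when at
least three such days exist; otherwise the mean over the earliest three
distinct reporting days, which may include the first days on treatment — a
conservative fallback, since any early treatment effect then shrinks the
measured change.

LOCF: months are 30-day half-open bins anchored at day 0 (month m covers
days [30(m-1), 30m)), so the 180-day window is exactly six months.  The LOCF
month is the latest of months 3-6 containing at least one report, and the
LOCF severity is the mean over all reporting days in that month.  Clients
with no report in months 3-6 have no defined endpoint.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import EndpointUndefined, SeverityEndpoints, SymptomReport

__all__ = [
    "MONTH_DAYS",
    "N_MONTHS",
    "LOCF_FIRST_MONTH",
    "assign_month",
    "compute_baseline",
    "compute_locf",
    "make_endpoints",
    "baseline_days_used",
    "compute_endpoints_frame",
]

MONTH_DAYS = 30
N_MONTHS = 6
LOCF_FIRST_MONTH = 3
MIN_BASELINE_DAYS = 3


def assign_month(day: int) -> int | None:
    """Month bin (1-6) for a day offset, or None outside [0, 180)."""
    if 0 <= day < MONTH_DAYS * N_MONTHS:
        return 1 + day // MONTH_DAYS
    return None


def _arrays(reports) -> tuple[np.ndarray, np.ndarray]:
    """(days, severities) for one client+scale, deduplicated by day (mean)."""
    if isinstance(reports, pd.DataFrame):
        days = reports["day"].to_numpy(dtype=int)
        sev = reports["severity"].to_numpy(dtype=float)
    else:
        reports = list(reports)
        days = np.array([r.day for r in reports], dtype=int)
        sev = np.array([r.severity for r in reports], dtype=float)
    if days.size == 0:
        return days, sev
    order = np.argsort(days, kind="stable")
    days, sev = days[order], sev[order]
    uniq, start = np.unique(days, return_index=True)
    if uniq.size != days.size:  # same-day duplicates: average severities
        sev = np.array([sev[s:e].mean() for s, e in zip(start, np.append(start[1:], days.size))])
        days = uniq
    return days, sev


def _baseline_from_arrays(days: np.ndarray, sev: np.ndarray) -> tuple[float, np.ndarray]:
    """Baseline severity and the day set it was averaged over."""
    if days.size < MIN_BASELINE_DAYS:
        raise EndpointUndefined(
            "too_few_reporting_days",
            f"baseline needs >= {MIN_BASELINE_DAYS} reporting days, have {days.size}",
        )
    pre = days < 0
    if pre.sum() >= MIN_BASELINE_DAYS:
        return float(sev[pre].mean()), days[pre]
    return float(sev[:MIN_BASELINE_DAYS].mean()), days[:MIN_BASELINE_DAYS]


def _locf_from_arrays(days: np.ndarray, sev: np.ndarray) -> tuple[float, int]:
    months = np.array([assign_month(int(d)) or 0 for d in days])
    eligible = months >= LOCF_FIRST_MONTH
    if not eligible.any():
        raise EndpointUndefined("no_locf_month", "no report in months 3-6")
    locf_month = int(months[eligible].max())
    in_month = months == locf_month
    return float(sev[in_month].mean()), locf_month


def compute_baseline(reports: Iterable[SymptomReport] | pd.DataFrame) -> float:
    """Baseline severity for one client on one scale."""
    days, sev = _arrays(reports)
    return _baseline_from_arrays(days, sev)[0]


def baseline_days_used(reports: Iterable[SymptomReport] | pd.DataFrame) -> np.ndarray:
    """The distinct days the baseline average ran over (for the medication
    baseline window, which reuses the severity-baseline days)."""
    days, sev = _arrays(reports)
    return _baseline_from_arrays(days, sev)[1]


def compute_locf(reports: Iterable[SymptomReport] | pd.DataFrame) -> tuple[float, int]:
    """(LOCF severity, LOCF month) for one client on one scale."""
    days, sev = _arrays(reports)
    return _locf_from_arrays(days, sev)


def make_endpoints(
    client_id: str,
    scale: str,
    baseline: float,
    locf: float,
    locf_month: int,
) -> SeverityEndpoints:
    """Derive percent change and responder flags from the two endpoints.

    Percent change is undefined (None) when baseline is 0; responder flags
    use strict thresholds (>30%, >50% reduction) and are False when the
    percent change is undefined.
    """
    if baseline > 0:
        pct = 100.0 * (locf - baseline) / baseline
        reduction = -pct
        r30, r50 = reduction > 30.0, reduction > 50.0
    else:
        pct, r30, r50 = None, False, False
    return SeverityEndpoints(
        client_id=client_id,
        scale=scale,
        baseline_severity=float(baseline),
        locf_severity=float(locf),
        locf_month=int(locf_month),
        pct_change=pct,
        responder_30=r30,
        responder_50=r50,
        symptom_free=(locf == 0 and baseline > 0),
        worsened=(locf > baseline),
    )


def compute_endpoints_frame(
    reports: pd.DataFrame | Sequence[SymptomReport],
) -> tuple[list[SeverityEndpoints], pd.DataFrame]:
    """Endpoints for every (client, scale) with enough data.

    Returns the endpoint records plus a frame of clients that fell out, with
    the exclusion reason (``too_few_reporting_days`` or ``no_locf_month``).
    """
    if not isinstance(reports, pd.DataFrame):
        from .io import reports_to_frame

        reports = reports_to_frame(list(reports))
    endpoints: list[SeverityEndpoints] = []
    undefined = []
    if len(reports) == 0:
        return endpoints, pd.DataFrame(columns=["client_id", "scale", "reason"])
    for (cid, scale), g in reports.groupby(["client_id", "scale"], sort=True):
        days, sev = _arrays(g)
        try:
            baseline, _ = _baseline_from_arrays(days, sev)
            locf, month = _locf_from_arrays(days, sev)
        except EndpointUndefined as exc:
            undefined.append({"client_id": cid, "scale": scale, "reason": exc.reason})
            continue
        endpoints.append(make_endpoints(str(cid), scale, baseline, locf, month))
    return endpoints, pd.DataFrame(undefined, columns=["client_id", "scale", "reason"])


def endpoints_to_frame(endpoints: Sequence[SeverityEndpoints]) -> pd.DataFrame:
    """Per-client endpoint export (endpoints.csv shape)."""
    return pd.DataFrame(
        [
            {
                "client_id": e.client_id,
                "scale": e.scale,
                "baseline": e.baseline_severity,
                "locf": e.locf_severity,
                "locf_month": e.locf_month,
                "pct_change": e.pct_change,
                "responder_30": e.responder_30,
                "responder_50": e.responder_50,
                "symptom_free": e.symptom_free,
                "worsened": e.worsened,
            }
            for e in endpoints
        ]
    )
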