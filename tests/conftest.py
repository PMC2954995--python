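"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nutricohort.model import (
    SCALE_N_ITEMS,
    SEVERITY_N_ITEMS,
    ClientProfile,
    SymptomReport,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def items_for_severity(scale: str, severity: int) -> tuple:
    """Item scores whose total under the scale rule equals ``severity``."""
    n_items = SCALE_N_ITEMS[scale]
    n_sev = SEVERITY_N_ITEMS[scale]
    if not 0 <= severity <= 3 * n_sev:
        raise ValueError(f"severity {severity} out of range for {scale}")
    items = [0] * n_items
    remaining = severity
    for k in range(n_sev):
        items[k] = min(3, remaining)
        remaining -= items[k]
    return tuple(items)


def make_report(cid: str, day: int, scale: str, severity: int) -> SymptomReport:
    return SymptomReport(cid, day, scale, items_for_severity(scale, severity))


def daily_reports(cid, days, scale="bipolar", severity=10):
    """One report per day at a constant severity (or per-day severities)."""
    sev = np.broadcast_to(np.asarray(severity), (len(list(days)),))
    return [make_report(cid, d, scale, int(s)) for d, s in zip(days, sev)]


def make_client(cid, age=12, sex="male", bipolar=True, adhd=False) -> ClientProfile:
    return ClientProfile(cid, age, sex, bipolar, adhd)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
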