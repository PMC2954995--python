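"""Personal-maximum normalisation and the Medication Index."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutricohort.medication import (
    client_medication_index,
    index_at_window,
    medication_summary,
    personal_max_doses,
)
from nutricohort.model import MedicationIndexResult, MedicationRecord


def _recs(cid, triples):
    return [MedicationRecord(cid, d, m, dose) for d, m, dose in triples]


class TestPersonalMax:
    def test_maximum_over_span(self):
        recs = _recs("c", [(0, "a", 100), (30, "a", 150), (60, "a", 150), (90, "a", 75)])
        assert personal_max_doses(recs) == {"a": 150.0}

    def test_zero_only_medication_omitted(self):
        recs = _recs("c", [(0, "a", 100), (0, "b", 0), (30, "b", 0)])
        assert personal_max_doses(recs) == {"a": 100.0}

    def test_late_introduction_counts(self):
        """A medication started in month 4 still gets a window-wide maximum."""
        recs = _recs("c", [(100, "a", 50)])
        assert personal_max_doses(recs) == {"a": 50.0}

    def test_records_beyond_month_six_ignored(self):
        recs = _recs("c", [(0, "a", 100), (200, "a", 400)])
        assert personal_max_doses(recs) == {"a": 100.0}


class TestIndexAtWindow:
    def test_four_meds_at_maximum_is_four(self):
        """Four medications held at their personal maxima: index 4 over the
        baseline window; dropping one by 25% of its maximum for the final
        month gives 3.75 over that month."""
        recs = _recs(
            "c", [(-7, m, d) for m, d in (("a", 100), ("b", 2), ("c", 900), ("d", 40))]
        )
        assert index_at_window(recs, range(-7, 0)) == pytest.approx(4.0)
        recs_taper = recs + _recs("c", [(150, "d", 30)])  # 40 -> 30 is -25% of max
        assert index_at_window(recs_taper, range(150, 180)) == pytest.approx(3.75)
        # baseline window unchanged by the later taper
        assert index_at_window(recs_taper, range(-7, 0)) == pytest.approx(4.0)

    def test_no_medications_is_zero(self):
        assert index_at_window([], range(-7, 0)) == 0.0

    def test_empty_window_is_an_error(self):
        with pytest.raises(ValueError):
            index_at_window(_recs("c", [(0, "a", 10)]), [])

    def test_carry_forward_semantics(self):
        """Dose is 0 before the first record, persists until a new record,
        and is 0 after an explicit discontinuation."""
        recs = _recs("c", [(10, "a", 100), (20, "a", 0)])
        assert index_at_window(recs, range(0, 10)) == 0.0
        assert index_at_window(recs, range(10, 20)) == pytest.approx(1.0)
        assert index_at_window(recs, range(20, 30)) == 0.0
        # a window straddling the change averages the step function
        assert index_at_window(recs, range(0, 20)) == pytest.approx(0.5)

    def test_mid_study_increase_normalises_history(self):
        """The personal maximum spans the whole study, so a later increase
        deflates the baseline index."""
        recs = _recs("c", [(-7, "a", 100), (60, "a", 200)])
        assert index_at_window(recs, range(-7, 0)) == pytest.approx(0.5)


@given(
    doses=st.lists(st.floats(min_value=0.1, max_value=1e3), min_size=1, max_size=5),
    scale=st.floats(min_value=1e-3, max_value=1e3),
    change_day=st.integers(min_value=1, max_value=179),
)
def test_unit_invariance(doses, scale, change_day):
    """Multiplying one medication's doses by a positive constant leaves the
    index unchanged."""
    recs = []
    for k, d in enumerate(doses):
        recs += _recs("c", [(-7, f"m{k}", d), (change_day, f"m{k}", d * 0.5)])
    scaled = [
        MedicationRecord(r.client_id, r.day, r.medication,
                         r.dose * scale if r.medication == "m0" else r.dose)
        for r in recs
    ]
    window = range(0, 180)
    assert index_at_window(scaled, window) == pytest.approx(
        index_at_window(recs, window), rel=1e-9
    )


@given(
    n_meds=st.integers(min_value=1, max_value=4),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_index_bounded_by_medication_count(n_meds, seed):
    rng = np.random.default_rng(seed)
    recs = []
    for k in range(n_meds):
        days = sorted(rng.choice(np.arange(-7, 180), size=3, replace=False))
        for d in days:
            recs += _recs("c", [(int(d), f"m{k}", float(rng.uniform(0, 10)))])
    idx = index_at_window(recs, range(0, 180))
    n_active = len(personal_max_doses(recs))
    assert 0.0 <= idx <= n_active + 1e-9


def test_constant_doses_give_equal_baseline_and_locf():
    recs = _recs("c", [(-7, "a", 10), (-7, "b", 20)])
    res = client_medication_index(recs, "c", [-3, -2, -1], locf_month=6)
    assert res.baseline_index == pytest.approx(res.locf_index) == pytest.approx(2.0)


class TestMedicationSummary:
    def test_hand_worked_four_clients(self):
        """Baseline indices {2,2,0,0} and LOCF {1,0,0,0}: 50% -> 25% taking
        (-50% relative); taker means 2.0 -> 0.5 (-75%)."""
        res = [
            MedicationIndexResult("a", 2.0, 1.0, {"x": 1}),
            MedicationIndexResult("b", 2.0, 0.0, {"x": 1}),
            MedicationIndexResult("c", 0.0, 0.0, {}),
            MedicationIndexResult("d", 0.0, 0.0, {}),
        ]
        df = medication_summary("demo", res).set_index("measure")
        taking = df.loc["pct_taking_medication"]
        assert (taking["baseline"], taking["locf"]) == (50.0, 25.0)
        assert taking["pct_change"] == pytest.approx(-50.0)
        takers = df.loc["mean_index_baseline_takers"]
        assert (takers["baseline"], takers["locf"]) == (2.0, 0.5)
        assert takers["pct_change"] == pytest.approx(-75.0)
        overall = df.loc["mean_index_all_clients"]
        assert overall["baseline"] == pytest.approx(1.0)
        assert overall["pct_change"] == pytest.approx(-75.0)

    def test_cohort_mean_index_arithmetic(self):
        """Printed-scale means 2.06 -> 0.54 round to a -74% change."""
        from nutricohort.io import round_half_away

        res = [MedicationIndexResult("a", 2.06, 0.54, {"x": 1})] * 2
        df = medication_summary("demo", res).set_index("measure")
        pct = df.loc["mean_index_baseline_takers", "pct_change"]
        assert int(round_half_away(pct)) == -74

    def test_medication_free_cohort_flags_undefined(self):
        res = [MedicationIndexResult(c, 0.0, 0.0, {}) for c in "ab"]
        df = medication_summary("demo", res).set_index("measure")
        assert (df["baseline"] == 0).all()
        assert df["pct_change"].isna().all()

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            medication_summary("demo", [])
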