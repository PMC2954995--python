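"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS_DIR = ROOT / "results"

SEED = 42


def load_cohort():
    """Read the generated cohort back through the validating CSV readers."""
    from nutricohort.io import read_cohort

    return read_cohort(
        COHORT_DIR / "clients.csv",
        COHORT_DIR / "symptom_reports.csv",
        COHORT_DIR / "medications.csv",
    )


def run_pipeline():
    from nutricohort.pipeline import run_analysis

    clients, reports, medications = load_cohort()
    return run_analysis(clients, reports, medications)
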