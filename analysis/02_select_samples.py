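"""Apply the eligibility rules and tally the analysis samples.

A client enters the Primary (bipolar) Sample with a parent-reported bipolar
diagnosis, age 7 to <18, reports on at least 60 of the first 180 days, and
at least one report in months 3-6; the ADHD-only clients form the
Alternative Sample under the same reporting rules.
"""

from _common import RESULTS_DIR, load_cohort
from nutricohort.selection import select_samples, selection_report


def main() -> None:
    clients, reports, _ = load_cohort()
    samples = select_samples(clients, reports)
    report = selection_report(samples)
    RESULTS_DIR.mkdir(exist_ok=True)
    report.to_csv(RESULTS_DIR / "selection_report.csv", index=False)
    print(report.to_string(index=False))
    primary = next(s for s in samples if s.label == "primary_bipolar")
    print(f"\nPrimary Sample n={len(primary.member_ids)}; "
          f"exclusions {primary.excluded_counts or 'none'}")


if __name__ == "__main__":
    main()
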