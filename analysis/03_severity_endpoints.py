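"""Baseline-to-LOCF severity change, responder tables and subgroup splits.

Computes per-client endpoints, summarises each sample on its defining scale
(paired t, Cohen's d on the differences, both median-percent-change
conventions), classifies responders at the strict >30% and >50% reduction
thresholds, and runs the baseline-median, age-12 and sex splits with Welch
cross-comparisons.
"""

from _common import RESULTS_DIR, run_pipeline
from nutricohort.io import write_summary
from nutricohort.pipeline import _split_summaries


def main() -> None:
    res = run_pipeline()
    RESULTS_DIR.mkdir(exist_ok=True)
    res["endpoints_frame"].to_csv(RESULTS_DIR / "endpoints.csv", index=False)
    severity = list(res["summary_severity"]) + _split_summaries(res["splits"])
    write_summary(severity, RESULTS_DIR / "summary_severity.csv")
    res["summary_responders"].to_csv(RESULTS_DIR / "summary_responders.csv", index=False)

    for s in res["summary_severity"]:
        print(f"{s.group_label}: n={s.n}  baseline {s.baseline_mean:.1f} -> "
              f"LOCF {s.locf_mean:.1f}  ({s.pct_change_of_means:+.0f}% of means, "
              f"{s.pct_change_of_medians:+.0f}% of medians)  "
              f"d={s.effect_size_d:.2f}  t({s.n - 1})={s.t_statistic:.1f}  p={s.p_value:.2g}")
    print("\nresponders (strict thresholds):")
    print(res["summary_responders"].to_string(index=False))
    for split_name, split in res["splits"].items():
        tests = split["tests"]
        if tests["baseline"] is not None:
            print(f"\n{split_name} split: baseline Welch p={tests['baseline'].p_value:.2f}, "
                  f"LOCF Welch p={tests['locf'].p_value:.2f}")


if __name__ == "__main__":
    main()
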