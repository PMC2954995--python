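"""Do early stoppers look like non-responders?

Groups the Primary Sample by last reported month, reports the median
per-client percent reduction and the paired test per group, and compares
baseline severity between clients who stopped at month m and those who
continued past it (Welch).
"""

from _common import RESULTS_DIR, run_pipeline


def main() -> None:
    res = run_pipeline()
    RESULTS_DIR.mkdir(exist_ok=True)
    dropout = res["dropout"]
    dropout["table"].to_csv(RESULTS_DIR / "dropout.csv", index=False)
    print(dropout["table"].round(2).to_string(index=False))
    print("\nstopped-at-m vs continued-past-m, baseline severity (Welch):")
    for m, test in dropout["stop_vs_continue"].items():
        if test is None:
            print(f"  month {m}: unavailable (too few clients)")
        else:
            print(f"  month {m}: t={test.t_statistic:+.2f}, p={test.p_value:.2f} "
                  f"(stoppers mean {test.mean_a:.1f} vs continuers {test.mean_b:.1f})")


if __name__ == "__main__":
    main()
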