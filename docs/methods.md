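# Methods

## Setting and data model

The package analyses daily parent-reported symptom checklists from a
naturalistic monitoring cohort of children (7 to <18 years) with a
parent-reported bipolar and/or ADHD diagnosis who began a micronutrient
formula. Three long-format tables drive everything: client profiles,
item-level daily symptom reports, and dated medication dose statements.
Days are integer offsets from treatment start (day 0 = first dose; negative
days are pre-treatment).

Two scales are scored. The mood checklist has 16 items scored 0–3 and its
severity is the plain sum (0–48). The ADHD checklist records 8 items but
only the first three (inattention, impulsivity, hyperactivity) are specific
to ADHD, so its severity is the sum of those three (0–9); the remaining
items are retained for audit but never scored. Same-day duplicate reports
for one client/scale are merged at ingestion by item-wise averaging with
half-up rounding — the least informative-loss rule we could adopt, since
the source design never defines duplicates.

## Eligibility

A client enters the Primary (bipolar) Sample when all of the following
hold: parent-reported bipolar diagnosis; age 7 to <18 at monitoring start;
symptom reports on at least 60 distinct days of the first 180 (counting a
day once regardless of how many scales were submitted — the permissive
reading, since per-scale counting is not specified in the source design);
and at least one report in months 3–6, without which no endpoint exists.
The Primary Sample partitions into bipolar-without-ADHD and
bipolar-with-ADHD sub-samples; ADHD-but-not-bipolar clients form the
Alternative Sample under the same rules. Every exclusion is tallied by its
first failing reason (age, no qualifying diagnosis, insufficient reporting,
no LOCF month).

## Endpoints

**Baseline.** The mean severity over all pre-treatment reporting days when
at least three exist; otherwise the mean over the earliest three distinct
reporting days, which may include the first days on treatment. The
fallback is conservative: titration starts at low doses, and any early
treatment effect inside the baseline shrinks the measured change. Fewer
than three reporting days in total leaves the endpoint undefined.

**LOCF.** Months are 30-day half-open bins anchored at day 0 (month m =
days [30(m−1), 30m)), so the 180-day window is exactly six months; the
source design never defines "month" and uniform bins are the only choice
that tiles the window. The LOCF month is the latest of months 3–6 with at
least one report — no minimum within-month density is imposed, as none is
stated — and the LOCF severity is the mean over that month's reporting
days.

**Derived flags.** Percent change is 100 × (LOCF − baseline)/baseline,
undefined when baseline is 0 (such clients are excluded from responder
fractions and counted separately). Responder thresholds are strict
(reduction > 30%, > 50%), matching the published ">" notation; symptom-free
means LOCF exactly 0 from a positive baseline; worsened means LOCF above
baseline.

## Medication Index

Doses are arbitrary per-medication units. The dose in effect on a day is
the last recorded dose carried forward (0 before the first record; an
explicit 0 record marks discontinuation) — carry-forward matches
prescription semantics, and the published description fixes only the
endpoint arithmetic, not the interpolation. Each medication is normalised
by the client's *personal maximum* dose over baseline-through-month-6; the
index over a window is the sum over medications of the window-mean
in-effect dose divided by that maximum. Consequences worth knowing:

- the index equals the count of active medications exactly when every one
  is at its personal maximum (four medications at maximum → 4; one reduced
  by 25% of its maximum for the whole final month → 3.75);
- it is invariant to per-medication unit rescaling;
- a mid-study dose *increase* retroactively deflates earlier windows,
  because the maximum spans the whole study.

The baseline index is averaged over the same days the severity baseline
used, for internal consistency; the LOCF index over every day of the LOCF
month. Cohort summaries report, per sample: % of clients with a positive
index at baseline and LOCF with the *relative* change of those percentages
(79% → 38% prints as −52%, not −41 points); the mean index among clients
medicated at baseline; and the mean over all clients.

## Statistics

Paired change uses t = mean(d)/(sd(d)/√n) on the within-client differences
d = baseline − LOCF, with the n−1 standard deviation (the denominator
convention is not stated in the source design; sample SD is used
throughout). The effect size is Cohen's d for paired data, mean(d)/sd(d),
so t = d·√n identically; p-values are two-sided from t with n−1 df. Zero
variance is flagged degenerate rather than returned as infinity. These
statistics are implemented from closed form and the test suite requires
agreement with `scipy.stats` reference implementations to 1e-10.

Two-sample comparisons default to Welch's unequal-variance t with
Welch–Satterthwaite df (a pooled-variance option exists behind a flag);
the source design says only "two-sample t-tests" and Welch is the robust
default. No multiple-testing correction is applied, matching the original
endpoint-based analysis; output metadata records this.

Two median-percent-change conventions appear in the field's tables and are
deliberately both emitted: the percent change of the group medians, and
the median of per-client percent changes. Report columns round percents to
the nearest integer, half away from zero, with raw values kept alongside.

Splits: baseline-median (sorted by baseline severity then client id; the
lower half takes the median client when n is odd), age at 12 (≥12 is
"older"), and sex; each side is summarised and the sides are compared by
Welch tests at baseline and LOCF. The dropout analysis groups clients by
LOCF month (3–6), reports n, median per-client percent reduction and the
paired test per group, and compares baseline severity between month-m
stoppers and continuers for m = 3, 4, 5. Sides or groups with fewer than
two members are flagged unavailable, never silently dropped.

## Synthetic cohort generator

The original database is proprietary, so the generator emulates its printed
moments and is the test bed for every stage:

- **Baselines.** Latent bipolar baseline ~ Normal(17.8, 10.1) clipped to
  [1, 46]; ADHD baseline Normal(6.0, 2.5) for ADHD-only and Normal(5.0,
  2.9) for comorbid clients, clipped to [0.5, 8.5]. Diagnosis mix defaults
  to 91:29:41 (bipolar-only : comorbid : ADHD-only); ages uniform 7–17;
  41% female.
- **Effects.** With probability 0.19 a client worsens by a folded-normal
  proportional increase |N(0.15, 0.10)|; otherwise the proportional
  reduction is N(0.60, 0.25) truncated to [0.02, 0.95]. The implied
  population mean reduction is ≈ 0.46, matching the printed −46% change of
  means. Severity approaches baseline × (1 − c) exponentially with a
  21-day half-life — consistent with the reported ~2-week onset — so
  month-3 stoppers are measured slightly short of their asymptote.
- **Reports.** Each day from −7 through the end of the client's last month
  is reported independently with probability 0.8 (high enough that month-3
  stoppers still clear the 60-of-180 rule, as the real eligible cohort did
  by construction). Daily noise with SD 2.0 severity points (scaled to each
  scale's range; no within-client variance is published, so this is a free
  choice) perturbs the latent level, which is converted to item scores by
  independent Binomial(3, p) draws whose expected total equals the level.
  With noise set to 0 the items are generated deterministically from the
  rounded level, making null-effect configurations exactly reproducible.
- **Dropout.** Last reported month is categorical over months 3/4/5/6 at
  18/17/16/49%.
- **Medications.** 79% of bipolar (41% of ADHD-only) clients are medicated
  at baseline with 1 + Poisson(1.06) medications (matching a taker mean
  index of ~2.06), at constant doses equal to their personal maxima. Each
  month, each active medication tapers by 25% of its maximum with
  probability sigmoid(−1.0 + 3.0c) — improvement-coupled cross-tapering.
  This reproduces the direction and rough magnitude of the published
  medication table, not its exact percentages.

The truth record stores every client's latent baseline, effect, last month
and medication schedule, plus the analytic moments implied by the
configuration (truncated-normal and folded-normal means), and
`truth_compare` reports estimate/configured/realised values with biases and
per-client RMSE.

**What the generator does not emulate:** item-level correlation structure
(items are conditionally independent given the day's level), seasonal or
episodic mood cycling, reporting gaps correlated with symptom state,
medication dose increases, co-occurring diagnoses, and any placebo or
expectancy dynamics. Passing recovery tests therefore show the *pipeline*
is unbiased under the stated missingness and heterogeneity — they say
nothing about causal effects in real data, and the generated cohorts are
somewhat more homogeneous than the real one (e.g. larger effect sizes at
the same mean reduction).

## Problem sizes and numerical choices

Recovery checks use 500-client cohorts over 20 seeds (test suite) or 10
seeds (analysis script); type-I calibration uses 2000 replicates at n = 30
per arm — sizes chosen so the whole suite runs in well under a minute per
module on one core while keeping Monte-Carlo error small relative to the
tolerances (±5 percentage points for mean-reduction recovery, ±0.05 for
the worsened fraction, ±0.02 around the 0.05 rejection rate). Ties in the
median split break by client id; duplicate-day severities average; month
bins are half-open so day 30k belongs to month k+1. Degenerate inputs
(zero-variance differences, zero baselines, medication-free cohorts, empty
month groups) are flagged explicitly rather than propagated as infinities
or NaNs.

## Known limitations

- LOCF is the only imputation implemented; no mixed-model or
  multiple-imputation alternative.
- The exact checklists behind the two scales are not reproduced; items are
  anonymous indices.
- Whether the original baseline fallback used exactly the earliest three
  days, and whether eligibility counted days per scale, are unstated in
  the source design; the choices here are documented above and
  configurable where they matter.
- The Medication Index has no dose-equivalence across medications by
  design; it is a within-client tapering measure, not a pharmacological
  load measure.
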