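# Methods

## Staging model

Every creatinine measurement is staged by its fold-rise over a
per-measurement baseline. The baseline window is strictly before the index
time and inclusive at its far edge, $[t - 365\,\mathrm{d},\, t)$: a
measurement never serves as its own baseline, and two results with the
identical timestamp are excluded from each other's windows while an
earlier same-day result remains eligible. Ties for the window minimum are
equivalent (equal values give the same baseline); the implementation keeps
the earliest-timestamped minimum in its rolling structure. Values that
themselves alerted are *not* excluded from later baseline windows — the
baseline is simply the lowest prior-year value — but
`exclude_alert_values_from_baseline` is available for sensitivity
analyses.

Stage thresholds are lower-inclusive (1.5×, 2×, 3×). Exactly 1.5× is
stage 1, exactly 2× is stage 2, exactly 3× is stage 3.

When the window is empty the baseline falls back to the age-referenced
upper limit, and the measurement is additionally flagged `above_reference`
when it exceeds that limit. The per-measurement operations emit an alert
object for any fold-rise ≥1.5 regardless of baseline provenance (the
provenance is recorded on the alert), but the cohort report counts only
prior-minimum-provenance alerts in its headline rates, stage mix and
patient summaries: a single high value with no prior-year baseline is not
reported as AKI. Reference-provenance alerts are carried as a separate
count (`n_reference_baseline_alerts`) so the information is not lost. The
simulation scorecard counts detection through either path, since for
detection purposes a fallback-staged alert is still an alert.

Time is measured in 365-day years throughout — the lookback window, the
eligibility bounds (29 days to <18 years) and the age bands — so that an
age of exactly 365 days sits at the lower edge of the 1–<6 year band.
Age at measurement (not at admission) drives the reference lookup and the
banding; a patient's band is fixed at their first alert, so a patient
alerting across a birthday is counted once.

## Reference limits

Upper reference limits are half-open age intervals in µmol/L. Lookup
resolves sex-specific rows before `any` rows; the shipped default table is
age-only because the staging algorithm is age-referenced, and its values
are plausible enzymatic paediatric upper limits included so the package
runs out of the box — they are illustrative, not a clinical reference, and
any production analysis must supply a validated local table. Table
validation enforces positive limits, non-overlap within a sex category and
gap-free coverage of the eligible range for every resolved sex, naming the
offending rows on failure.

## Cohort aggregation and rounding

Percentages are rounded half-away-from-zero: one decimal for
measurement-level rates, integers for stage-mix and age-band percentages
(both configurable). A rate with a zero denominator is reported as
undefined (JSON `null`), never as 0. The restricted incidence divides
alerts by baseline-bearing measurements; the above-reference fraction
divides flagged single high values by baseline-free measurements. The
published headline incidence of 10.8% cannot be reconstructed from the
published margins (alerts over all measurements gives 9.3%, over
baseline-bearing ones 12.4%), so the report prints both computable rates
and takes no position on the discrepancy.

Report JSON is emitted with sorted keys and no timestamps, so identical
inputs give byte-identical reports; the run manifest carries the
configuration and SHA-256 input checksums instead.

## Comparison statistics

The 2×2 comparison (alert rate among baseline-bearing measurements versus
above-reference rate among baseline-free ones) derives its second column
as denominator minus events, since only margins are available. The default
test is Pearson chi-squared without continuity correction; the
Yates-corrected variant is available for 2×2 tables and is never larger
than the uncorrected statistic. Zero margins raise a degenerate-table
error rather than returning a value. Centre heterogeneity uses the same
statistic on the r×2 table of alerting versus non-alerting measurements
per centre. The Mann–Whitney U is exact (full enumeration) when both
groups have ≤10 untied observations and otherwise uses the tie-corrected
normal approximation with continuity correction; the t-test is the
pooled-variance independent-samples form, with zero pooled variance
resolved explicitly (equal means → p = 1; unequal → infinite-statistic
marker with p = 0). These are standard procedures and are delegated to
scipy.stats behind the module surface.

## Synthetic cohorts

The generator emulates a six-month multi-centre extract
(2012-07-01 to 2012-12-31): per patient an age band is drawn
(default weights 0.20/0.39/0.17/0.19/0.05 across <1, 1–<6, 6–<11, 11–<16,
16–<18 years, the observed distribution of alerted children), an age
uniform within the band, a centre from six centres weighted by their
measurement volumes, and a stable latent baseline drawn uniformly at
0.4–0.8 of the age reference limit — healthy-range values that leave
headroom for a fold-rise to be meaningful. Measurement counts are Poisson
(default mean 4 per patient per window, a realistic order for children
having bloods taken in hospital); with probability `lookback_coverage`
(default 0.75, matching the observed 75.2% baseline coverage) the patient
also has 1–3 measurements 1–90 days before the window, which guarantees
they fall inside the 365-day lookback of every in-window measurement. An
injected episode (default prevalence 0.12, the observed restricted
incidence) is a rectangular elevation over a contiguous 2–14 day interval:
the latent value is multiplied by a factor drawn uniformly in the target
stage's fold-rise interval ([1.5,2), [2,3), [3,6]), with the target stage
drawn from the 62/16/22 stage mix. If the Poisson times miss the episode
entirely, one measurement is added at its midpoint, so every injected
episode is observable. Noise is multiplicative mean-one lognormal
(creatinine is positive and right-skewed; default CV 0.05, a typical
enzymatic-assay imprecision), applied to the latent value. Infant ages
start at 40 days so a pre-window measurement always has room to exist.

Each patient consumes two independent RNG substreams —
demographics/times/noise, and episode — with the episode-presence uniform
drawn first, so raising `episode_prevalence` under a fixed seed only adds
episodes and never perturbs existing patients: the number of alerted
patients is monotone in prevalence.

What the generator does **not** emulate: renal physiology (no creatinine
kinetics, no gradual rise or recovery ramp — episodes are rectangles),
chronic kidney disease trajectories, assay calibration drift between
centres, repeat-testing intensification after an abnormal result, or
laboratory value quantisation. Passing recovery tests therefore shows the
*algorithmic* pipeline is correct on data whose generating process is
known, not that the clinical performance figures transfer to real
extracts.

### Recovery properties

With zero noise and full lookback coverage, recovery is exact: every
episode is detected and the assigned worst stage equals the target stage
(diagonal confusion), because the observed fold-rise is exactly the drawn
factor. Under nonzero noise exact stage agreement is impossible in
general — an episode factor drawn near a stage boundary crosses it under
arbitrarily small multiplicative noise — so the diagonal-confusion claim
is checked in the noise-free limit, while stage-3 *detection* (which has
a 2× margin over the alert threshold) is checked at CV 0.05. At the
default conditions the detected episode rate across 20 seeds sits
slightly below the latent-truth oracle rate (about 0.2 percentage
points: borderline stage-1 episodes whose noisy ratio lands below 1.5),
well within three standard errors of the rate.

Test and acceptance problem sizes — cohorts of 40–500 patients for
equivalence checks, 300 for exact recovery, 20 × 1,000 patients for the
detection-rate comparison — were chosen as the smallest sizes at which the
binomial standard errors make the comparisons informative.

## Numerical and degenerate-input choices

- Stream evaluation sorts rows canonically (patient, time, value) and is
  therefore invariant to input row order; the rolling window minimum uses
  a monotonic deque (O(n) per patient), and equivalence with the naive
  full-scan definition is tested exhaustively on random cohorts.
- Rounding uses decimal arithmetic on the shortest repr of the float, so
  printed-precision ties (e.g. 2.5 → 3) behave as half-away-from-zero
  rather than binary-float artefacts.
- Empty input tables produce an all-zero report with undefined rates and
  exit successfully; malformed rows are rejected with named reasons and
  counted, never dropped.
- The CLI is a thin layer over the library: `run` (extract → report),
  `simulate` (cohort → pipeline → scorecard), `report` (render saved
  JSON).

## Known limitations

- The two-window national algorithm variant (separate short- and
  long-horizon reference values) is not implemented; the single 12-month
  lowest-value window is.
- Urine output, eGFR back-calculation baselines and height-based baseline
  estimation are out of scope.
- The default reference table is illustrative; sex-stratified adolescent
  limits are supported by the table format but not populated by default.
- Alert deduplication within a clinical episode is intentionally absent:
  every qualifying measurement alerts, matching a measurement-level
  incidence reading.
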