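# Methods

## Psychometric model

The probability of a clockwise (CW) judgement of a center grating tilted
θ degrees from vertical (CW positive) under a given surround is

    p(θ) = l + (1 − 2l) · logistic( k (θ − μ) / σ ),   k = ln(21/4) = ln 5.25

with bias μ (the point of subjective equality — the orientation perceived
as vertical), threshold σ, and lapse rate l ∈ [0, 0.5). The slope
constant deserves a note: "log(21/4)" admits two readings, ln(21/4) =
ln 5.25 ≈ 1.658 and ln(2^{1/4}) ≈ 0.173. Only the first makes σ the
84%-correct half-width — logistic(ln 5.25) = 5.25/6.25 = 0.84 exactly —
which is how the threshold is defined throughout this literature, so
`tiltlab` implements ln 5.25. The model assumes a memoryless observer:
every response is an independent Bernoulli draw, with no sequential
dependencies, learning, or criterion drift.

## Staircases

Stimulus placement is a weighted up-down rule on a 1° base step: CW
responses move the level by −down steps, CCW by +up steps, equilibrating
where P(CW) = up/(up+down). Each surround runs two reciprocal 40-trial
tracks: track A starts at +21° with (up=2, down=5), converging at
P(CW) = 2/7 (below the PSE); track B starts at −21° with (up=5, down=2),
converging at 5/7 (above the PSE). Starts therefore lie opposite their
convergence points and both tracks sweep the transition region. Seven
surrounds × 80 trials give 560 trials per measurement.

Two choices the design leaves open:

* **Clamp.** Levels are bounded at ±45° (configurable). The original
  procedure states no bound, but without one a high-lapse observer can
  drive the track to meaningless orientations; ±45° is far outside the
  transition region of any plausible observer here.
* **Schedule.** The two tracks (and in full studies, the seven surrounds)
  are interleaved trial-by-trial under the session seed; blocked
  presentation is also supported (`interleave=False`). For a memoryless
  observer all schedules are statistically equivalent, so this choice
  affects only row order.

## Bayesian fitting

The posterior over (μ, σ, l) combines the Bernoulli likelihood with
priors l ~ Beta(1.2, 15), σ ~ Gamma(2.5, 2.5), μ ~ Uniform[−25, 25]°
(the window sits just beyond the ±21° staircase starts; configurable).
Two deliberate resolutions of ambiguity:

* **Gamma parameterization.** Gamma(2.5, 2.5) is read in the shape–scale
  convention (mean 6.25°), not shape–rate (mean 1°): plausible
  vertical-orientation thresholds under strong surrounds (a few degrees)
  sit inside the bulk of the shape–scale prior, whereas shape–rate
  concentrates mass implausibly below 2°. The convention is a `PriorSpec`
  field, so the alternative is one argument away.
* **Estimator.** Point estimates are posterior means, not MAP: staircase
  sampling concentrates trials near the PSE and can leave plateaued
  posteriors on which the mode is unstable.

The posterior is evaluated on a deterministic dense grid, by default
121 × 81 × 61 points over μ ∈ [−25, 25], σ ∈ (0, 20], l ∈ (0, 0.35].
σ and l axes are cell midpoints of their intervals, which keeps the
integrand off the singular boundary and makes marginal means
second-order accurate; doubling the resolution moves each estimate by
well under 1% of its posterior SD on an 80-trial session. The grid
buys exact reproducibility and testable refinement behaviour at
desk-scale cost (~0.1–0.2 s per 80-trial fit, dominated by the number of
distinct staircase levels, over which the likelihood is aggregated as
binomial counts). Grid truncation matters only for near-data-free fits:
the Gamma prior has ≈1.3% mass above σ = 20, so a *prior-only* fit on
the default grid returns a σ mean of ≈6.03 rather than 6.25; validation
against the closed-form prior means therefore uses a widened grid
(σ ≤ 80, l ≤ 0.45) where truncation is negligible. With 80 trials the
likelihood confines σ far below 20 and the truncation is irrelevant.
The lapse grid stops at 0.35, beyond every QC-relevant value (the
exclusion rule triggers at 0.20) while keeping the (1 − 2l) factor well
away from degeneracy.

Per measurement block, the seven fitted biases are mean-centered
(`normalize_block_biases`), removing the observer's overall internal-
vertical miscalibration.

## Summary variables and statistics

Per block: bias(s) = (μ(+s) − μ(−s))/2 — positive = repulsion; at s = 0
the single adjusted μ(0) is used since no symmetric partner exists —
threshold(s) = (σ(+s) + σ(−s))/2, and lapse summarized as the mean of
log10 l (lapse rates are analyzed on the log10 scale).

The battery: two-way fully-within-subject ANOVA (condition × absolute
orientation) with Greenhouse–Geisser correction; paired t contrasts per
orientation at Bonferroni-corrected α = 0.05/4 = 0.0125; one-sample
tests of the 75° attraction against zero; twelve Pearson bias–threshold
correlations at α = 0.05/12 ≈ 0.0042; and a QC rule flagging any
measurement with ≥ 4 of 7 lapse estimates above 0.20. Epsilon is the
Greenhouse–Geisser (Box) epsilon-hat computed from orthonormal contrast
transforms of the per-subject covariance — Huynh–Feldt is deliberately
not offered. Complete balanced tables are required (complete-case
analysis); unbalanced input is rejected rather than silently dropped.
Both uncorrected and GG-adjusted p values are reported, since published
tables often print nominal dfs alongside adjusted p. All of these are
implemented in-package and verified against pingouin, scipy.stats and
R `car::Anova` on shared fixtures; note that pingouin's two-way
*interaction* epsilon differs from the standard contrast-matrix
definition (pingouin warns about this itself) — `tiltlab` matches
`car::Anova`.

## Dosing

Ethanol dose from anthropometrics: TBW regressions per sex (the male
equation uses age, the female one does not), A = c·1.055·TBW/0.8 grams
for target maximum BAC c (mg/ml, default 1.5), and beverage volume
V = A/((vol/100)·0.8) ml at strength vol (percent by volume, default
40), mixed with an equal juice volume. The constants are implemented
exactly as conventionally printed, including their loose mg/ml-vs-g/L
unit bookkeeping (the discrepancy is folded into the constants); no
absorption-deficit correction is modelled — in practice peak BAC is
verified by breathalyzer, not predicted.

## Synthetic cohorts

`EffectProfile` defaults encode the qualitative effect pattern the
analysis is designed to detect, at magnitudes typical of tilt-illusion
psychophysics (group effects in the source material are reported only
graphically, so these are explicit assumptions, not measured values):

| parameter | default | meaning |
|---|---|---|
| bias_base | 0 / 2.5 / 2.0 / −0.5 ° | repulsion at 0/15/30°, attraction at 75° |
| sigma_base | 2.0 / 2.6 / 2.4 / 2.2 ° | baseline thresholds per \|surround\| |
| lapse_base | 0.04 | baseline lapse rate |
| bias_delta_15 / 30 | +1.2 / +1.0 ° | alcohol-induced extra repulsion |
| threshold_delta | +0.8 ° | alcohol threshold elevation, all surrounds |
| lapse_multiplier | 2.5 | global alcohol lapse inflation |
| placebo deltas | 0 / 0 / ×1 | placebo changes nothing in truth |
| subject SDs | 1.0 / 0.8 / 0.5 / 0.35 | vertical offset, repulsion, σ, log-lapse |
| session SDs | 0.5 / 0.3 / 0.15 | per-cell bias, σ, log-lapse noise |

Alcohol alters bias only at ±15°/±30° in truth — the 75° attraction and
0° bias are untouched — so the generator embodies the selective-effect
structure the interaction test must detect. Repulsion is antisymmetric
(+b at +s, −b at −s), so the half-difference recovers b. Between-subject
deviations persist across conditions; session-level noise is drawn per
measurement cell and is what makes repeated measurements differ.
Seeds spawn hierarchically (master → subject → cell → staircase), so any
sub-unit regenerates byte-identically.

What the generator does *not* emulate: sequential dependencies and
criterion drift within sessions, time-varying intoxication across the
three alcohol measurements, non-stationary lapsing (e.g. an observer who
disengages mid-block responds randomly *from some trial onward*, whereas
a high constant lapse is the closest stationary analogue), and any
correlation structure between bias, threshold and lapse beyond shared
condition effects. Passing tests therefore demonstrate that the
estimator and battery recover effects of the assumed structure and size
from stationary Bernoulli observers — not that real observers satisfy
those assumptions.

## Calibration problem sizes

Validation runs use desk-scale sizes chosen as the package's own test
design: bias recovery over a 3 × 2 × 2 truth design with 100 seeded
80-trial sessions per cell (mean absolute μ error ≈ 0.6°, 2-SD coverage
≈ 97%); type-I calibration of the GG-adjusted interaction over 200
null-profile cohorts of n = 26 (observed rate ≈ 4.5% at nominal 5%);
power and the 15°/30°-but-not-0°/75° significance pattern over 50
effect-profile cohorts. The calibration cohorts are evaluated on
truth-level summaries: the generator's session noise stands in for the
combined session-state, trial-sampling and estimation variability at the
summary level, which is the level the battery operates on. The full
simulate → fit → summarize → test path is exercised separately on single
cohorts (`end_to_end_recovery`), where group-mean recovered biases land
within a few tenths of a degree of the generating truth.

## Known limitations

* The fitter assumes a stationary lapse; the QC rule catches gross
  non-stationarity only after the fact, as in the original exclusion.
* The μ grid window [−25, 25]° silently shrinks posterior mass for
  observers whose true PSE approaches the window edge; widen
  `mu_bounds` for atypical designs.
* The ANOVA is the classical univariate within-subject decomposition;
  mixed-effects alternatives are out of scope.
* Dose arithmetic is a planning tool, not a pharmacokinetic model: no
  absorption deficit, elimination kinetics, or BAC time course.
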