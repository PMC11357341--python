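# Methods

`photolick` analyses home-cage limited-access drinking (the
Drinking-in-the-Dark schedule: four 2-h sessions Monday–Thursday and one
4-h session Friday, water for the first half of the schedule and 20 % v/v
alcohol for the second) jointly with dual-fiber, dual-wavelength fiber
photometry of a genetically encoded calcium indicator. This note records
the models, the parameters that matter, and the design choices made where
the procedure was genuinely open.

## Lickometer model

The device samples an infrared beam in front of the bottle valve and
writes to memory every 3 s. A stored record is one occupied window:
`n_events` beam breaks and `event_duration` seconds of beam-broken time.
Definitions used throughout:

- **Drink** — a maximal run of consecutive occupied 3-s windows. Merging
  is the only defensible reading of "any tube interaction within a 3-s
  window": an interaction spanning a window boundary is one drink, so
  drink length is always a multiple of 3 s.
- **Latency to drink** — the start of the first *raw* occupied window.
  Artifact cleaning targets leaks and chews, not the animal's first
  approach, so latency is computed before cleaning; every other feature
  uses cleaned drinks.
- **Mean inter-drink interval** — mean of successive drink start-to-start
  gaps (undefined with fewer than two drinks).
- **Front-loading** — events in windows starting within the first 30 min.
- **Intake** — bottle-weight difference converted to g/kg. Water uses the
  mass directly. For alcohol, the consumed solution mass is converted to
  volume with ρ(20 % v/v ethanol) = 0.9687 g/mL, and the 20 % ethanol
  volume to grams with ρ(EtOH) = 0.78945 g/mL; both densities are
  configurable. Inter-session water intake uses the water formula on the
  home-cage bottle weights.

### Artifact cleaning

Slow leaks produce long beam-broken durations with ordinary event counts;
chews produce many near-instantaneous breaks. Cleaning fits a line of
`n_events` on `event_duration` over a session's drinks and removes drinks
with an absolute raw residual above 3 (event-count units, configurable).

The line is fit with the **Theil–Sen estimator** (median of pairwise
slopes, intercept = median residual) rather than least squares. The choice
is forced by the geometry of the artifacts: a leak is a high-leverage
point on the duration axis, and a least-squares line rotates onto it —
the artifact then looks like an inlier and ordinary drinks like outliers,
inverting the rule. Theil–Sen tolerates up to ~29 % contamination, is
deterministic, and needs no tuning, so the published residual rule applies
unchanged around a line that reflects the session's clean licking.

Known limitation: with a *fixed* threshold in event units, the residual
scatter of a genuinely clean drink grows like √n_events (per-break
duration noise accumulates), so very long drinks (≳200 breaks) are
over-flagged at ~10 % per-break duration variability. Standardising
residuals per drink would remove this at the cost of departing from the
fixed-threshold rule; the package keeps the rule and exports both raw and
cleaned totals.

## Photometry model

Stage order is fixed:

1. **Trim** the first 300 frames (LED/camera settling). Time is re-zeroed
   and the removed span kept as `clock_offset` so event timestamps stay on
   the acquisition clock.
2. **Bleach fit** — nonlinear least squares of
   F(t) = A₁e^(−t/τ₁) + A₂e^(−t/τ₂) + C to the 415 nm isosbestic channel,
   bounds τ > 0, amplitudes ≥ 0, τ₁ ≤ τ₂ by post-sorting. The additive
   offset C is included because real baselines do not decay to zero and
   its omission biases both τ. Initialisation is deterministic (C from the
   last-decile median, A₁ = A₂ = (F₀ − C)/2, τ at 5 % and 50 % of the
   trace span); there are no random restarts. The fit is evaluated on an
   even subsample of ≤2000 frames (the curve is smooth; this is purely a
   cost choice), r² on the full trace.
3. **Shared-artifact censoring** — frames where the isosbestic residual
   (F415 − fit) exceeds 4 robust SD (1.4826 × MAD) are morphologically
   closed, padded by 2 frames, and replaced in the 470 channel by linear
   interpolation. The isosbestic channel is calcium-independent, so these
   excursions mark motion/cable artifacts common to both channels, while
   calcium transients (470-only) are untouched. Division by a *smooth*
   scaled fit corrects bleaching but cannot remove time-localised shared
   artifacts; this step is what does, and it can be disabled
   (`censor_motion: false`).
4. **RANSAC scaling** — robust linear regression of the 470 signal on the
   fitted bleach curve: 100 two-point trials, inlier threshold
   1.4826 × MAD of the initial OLS residuals, consensus winner refit by
   OLS on its inliers; a seed is mandatory. Transient and residual
   artifact frames fall outside the consensus, so they do not bias the
   scale.
5. **Lowpass** — 6 Hz second-order Butterworth applied forward and
   backward (zero phase, unit DC gain); skipped with a warning when the
   frame rate cannot support the cutoff.
6. **ΔF/F** — the filtered 470 signal divided by the scaled fit. The
   default is the literal ratio; `subtract` mode gives (F−fit)/fit. The
   two differ by exactly 1.0 pointwise and are identical after z-scoring,
   which the tests assert, so the choice is cosmetic.
7. **Session z-score** per fiber: mean 0, SD 1 over the whole trace.

**QC** (all configurable): r² ≥ 0.8 on the bleach fit, RANSAC inlier
fraction ≥ 0.5, no |z| > 10 excursion sustained beyond 1 s, and a strictly
positive control fit. Failures carry machine-readable reasons; failed
recordings are excluded from peri-event analysis.

## Peri-event analysis

Z-scored ΔF/F is aligned to drink starts on a fixed 150-bin grid from
−5 s to +5 s, t_k = −5 + k/15: the spacing matches the 15 Hz effective
per-channel rate and the grid contains t = 0 exactly. Rows are built by
linear interpolation; drinks whose window leaves the recording are dropped
and logged, never padded. Per event, over the drinking interval
[0, min(drink length, 5 s)]:

- **peak amplitude** — maximum z-scored ΔF/F;
- **time to peak** — its first-occurrence argmax;
- **AUC** — trapezoidal integral from the peak time to the drink end
  (capped at the window edge), z·s — an off-kinetics measure.

Group summaries are per-bin mean ± SEM over events within
sex × fluid × hemisphere (SEM flagged missing for singleton groups).
Drink-start times from binned lick logs are quantised to the 3-s window
start; rigs that record TTL-timestamped drink starts can pass those
directly for sharper alignment.

## Synthetic-data generator

Per fiber: F415 = bleach + motion + ε and
F470 = s·bleach + motion + Σᵢ Aᵢ·k(t − tᵢ) + ε, with s the true
inter-channel scale, ε i.i.d. Gaussian, motion additive boxcar pulses
identical on both channels of a fiber, and k a unit-peak double
exponential k(t) ∝ e^(−t/τ_d) − e^(−t/τ_r). One transient per drink, onset
at the drink's first beam break, amplitude drawn per drink from a normal
with group mean and 10 % CV (clipped at 0).

Defaults and why (all configurable in `SimConfig` / `CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| frame rate | 15 Hz/channel | a 10-s window spans exactly 150 samples |
| session length | 7200 s (14400 s Fridays) | the drinking schedule |
| bleach | A₁=3, τ₁=60 s, A₂=5, τ₂=900 s, C=10 a.u. | ≈44 % decay over 2 h, a fast and a slow fluorophore pool |
| channel scale s | 2.0 | 470 nm excitation is brighter than isosbestic |
| kernel | τ_r=0.3 s, τ_d=1.5 s | slow indicator kinetics; peak ≈0.6 s after onset |
| noise σ | 0.3 a.u. | ≈2 % of early-session brightness; peri-drink peaks land at ~5–10 z as in real recordings |
| motion | 0.5/min, 2.0 a.u., 1 s | rare but large shared cable artifacts (≈6.7 robust SD) |
| amplitudes | male L: 2.5 (water) / 4.0 (alcohol); male R: 2.5 / 1.5; female L: 2.0 / 2.4; female R: 2.2 / 2.0 a.u. | the lateralised, sex-dependent fluid effect, attenuated in females |
| bouts | 40/session (water), 45/32 male/female (alcohol), scaled by duration/7200 s | drink counts in the tens per 2-h session; females make fewer, longer-spaced alcohol drinks |
| bout sizes | 1 + NegBin(r=2), mean 20 breaks at 8 Hz, bursts of ~8 separated by 0.5–2.5 s pauses | overdispersed bout sizes and intra-bout pauses give the right-skewed drink-length distribution; pauses stay under 3 s so a bout maps to one drink |
| per-break duration | 70 ms ± 10 % | typical beam-break times |
| inter-bout gap | ≥10 s | guarantees bouts bin to distinct drinks (a gap must exceed two device windows, 6 s, to guarantee separation) |
| intakes | water 32 g/kg, ethanol 4 g/kg per 2 h, ×1.5 on Fridays, CV 20 % | binge-range intakes |
| inter-session water | 3.5 g/day males, 4.5 g females, CV 30 % | females drink more between sessions; daily water is highly variable |
| thirst coupling | water −0.25 both sexes; alcohol 0 males, −0.4 females | a quenched thirst state predicts lower next-session intake, female-specific for alcohol |

Artifact injection: leak drinks keep their event count with every break
duration multiplied (re-spaced so the bout stays contiguous); chew drinks
gain (multiplier − 1)× extra 1-ms breaks inside the bout span. Injected
indices are recorded in the ground truth.

All randomness derives from one seed via `numpy.random.SeedSequence`
spawning, split per animal, session, fiber and stage; identical configs
are byte-identical after serialization, which the end-to-end determinism
test checks over the full 14-animal, 6-week cohort (two complete runs,
roughly a minute each).

What the generator does *not* emulate — hence what passing tests do not
show about real data: hemodynamic contamination, wavelength crosstalk,
indicator nonlinearity/saturation, drift in the inter-channel scale,
non-boxcar motion, circadian structure in drinking, and any within-session
pharmacological change in transient shape.

## Cohort analysis

- **Weekly aggregation** averages within animal first, then across
  animals (animal is the experimental unit); group summaries are
  mean ± SEM with SEM missing for singleton groups.
- **Quartile binning** of drink lengths (per event) and drinks per session
  (per session) pools all water and alcohol sessions; breakpoints are the
  25/50/75th percentiles with linear interpolation, values on a breakpoint
  take the lower quartile, and labels are invariant under strictly
  monotone transforms.
- **Shepherd's pi**: squared Mahalanobis distance of every pair from the
  center/covariance of 200 bootstrap resamples, averaged; pairs above 6
  are bivariate outliers; Spearman on the rest with the p-value doubled.
  Under bivariate normality the rule trims ~5 % of clean data (χ²₂ tail
  above 6) — inherent to the published threshold, not a defect. The
  covariance inverse uses a pseudoinverse so exactly collinear data stays
  finite.
- **Inter-session coupling**: pairs (inter-session water intake preceding
  session k, intake during session k), pooled and per sex, per fluid,
  correlated with Shepherd's pi. The lag convention is day-before (the
  home-cage bottle weighed when the lickometer goes in).

Inferential models (mixed/repeated-measures ANOVA, ANCOVA, post-hoc
corrections, power) are deliberately not reimplemented; the pipeline
exports tidy per-session and per-event tables for any stats package.

## Problem sizes

The test suite and `scripts/acceptance.py` choose these sizes: 20 seeds
for the bleach (3600-s sessions), RANSAC (10 000 frames), motion (1200-s
sessions) and cleaning (30-drink sessions) studies; 1000 random schedules
and 1000 random rows for the oracle-equivalence checks; one 110-drink 2-h
session for amplitude recovery; twenty 3-animal, 2-week, shortened-session
cohorts for effect-direction recovery; 100 seeds at n = 200 for the
Shepherd null; and the full 14-animal, 6-week cohort (420 sessions, 840
recordings) run twice for determinism.
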