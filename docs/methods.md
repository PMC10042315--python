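# Methods

`kinemetrics` implements a complete at-home digital-phenotyping analysis for
degenerative ataxias: submovement-based features from continuous wrist/ankle
accelerometry, kinematic features from a point-and-click mouse task,
L1-regularized composite severity models evaluated with leave-one-out
cross-validation, and a reliability/validity statistics harness.  Because no
patient data ship with the package, every stage is exercised end to end on a
synthetic cohort whose latent severity drives all modalities; this note
documents the models, the defaults and the choices that were genuinely open.

## The wearable signal model

### Submovement primitive

The elementary unit of movement is the minimum-jerk velocity pulse

    v(t) = 30 (L/D) tau^2 (1 - tau)^2,   tau = t/D,

traversing a distance `L` (m) in duration `D` (s).  Its closed forms — peak
speed `15L/(8D)`, peak acceleration `(10/sqrt(3)) L/D^2`, squared-acceleration
integral `(120/7) L^2/D^3` — make it an exact oracle for the feature
extractors (`kinemetrics.minjerk`).

### Synthetic recordings

`generate_recording` produces a triaxial 100 Hz series spanning
`days + 0.5` 24-h periods, starting mid-day so the first full night is
interior.  Each 24-h period splits 2/3 day : 1/3 night.  Daytime contains:

* **Activity bouts** (mean gap `bout_gap_mean_s`, durations 5–15 s), each
  with its own random 3-D orientation.  Within a bout, two orthogonal
  in-bout axes (the future PC1/PC2 directions) carry independent trains of
  signed minimum-jerk pulses; the secondary axis is scaled by 0.5.
* **Ambient motion**: band-limited (< 2 Hz) noise at 0.04 m/s² — daily
  activity that is real movement but below the bout threshold.
* Severity effects (latent θ ∈ [0, 1], 0 = healthy): pulse peak speeds scale
  by `(1 − 0.6 θ)`, inter-pulse and inter-bout gaps by `(1 + 0.5 θ)`,
  durations by `(1 + 0.4 θ)`; with probability `0.7 θ` a pulse carries an
  overlapping same-sign echo subpulse (movement decomposition), and bouts
  carry 3–8 Hz action tremor with amplitude `0.3 θ` m/s².  Together these
  emulate the described ataxic phenotype: smaller, slower, less powerful,
  less smooth and more fragmented movement, with a narrower range of
  activity intensities.
* Gravity is a slowly rotating unit-g vector (periods of hours), so the
  0.1 Hz high-pass genuinely has to remove it; white sensor noise has
  sd 0.03 m/s² per axis.

Pulses are parameterized by peak speed (drawn uniformly from 0.15–1.0 m/s
for the primary direction) with `L = (8/15) v_peak D`; parameterizing by
speed keeps accelerations physiological and makes severity act on the
quantity the disease actually scales.  Every pulse, bout, rotation and night
boundary is recorded in a `GroundTruth` object, and in the noise-free
configuration the recording's total energy equals the sum of per-pulse
energies exactly (a generator invariant under test).

Nights are gravity + noise only.  Day-to-day severity fluctuates as
θ + N(0, `within_subject_sd`) (default 0.02), clipped to [0, 1].

### Time-compressed days

Real recordings are ~56 M samples per subject; a 40-subject cohort at that
scale is not a laptop-sized computation.  The synthetic clock is therefore
parameterized by `day_s`: the packaged study uses 3600 s "24-h" periods
(with `bout_gap_mean_s` 30 s), and all day-structure thresholds
(night duration 4–14 h, 1-h smoothing) are expressed on the recording's own
clock, so segmentation logic is scale-invariant.  The compressed cohort
yields ≈ 2–4 thousand submovements per subject per half-week — enough for
split-half reliabilities of the key aggregate features comparable to those
obtainable from full 16-h days.  `day_s = 86400` reproduces real time.

## Wearable preprocessing and features

* **Filtering**: sixth-order Butterworth band-pass, 0.1–20 Hz, applied
  forward–backward (`sosfiltfilt`).  Zero-phase filtering preserves
  kinematic timing; the effective magnitude response is |H|², which doubles
  stop-band attenuation (verified against the digital filter's frequency
  response in tests).
* **Noise floor**: mean per-axis variance over the lowest-decile-variance
  1-s windows, debiased by the truncated-chi-square factor for the
  selection effect (exact under Gaussian noise).
* **Day segmentation**: nights are maximal runs of a 1-h running-median
  activity-index profile below an adaptive threshold
  (5th percentile + 0.15 × (90th − 5th)), lasting 4–14 h.  Analysis periods
  are consecutive 24-h windows anchored at the first full night's onset,
  capped at six; later data are discarded.  A manual two-column override
  file replaces detection when provided.  The heuristic replaces the manual
  partitioning used with real recordings and is validated only against the
  generator's ground-truth boundaries (±30 min on the 24-h clock).
* **Activity index** (AI): per 1-s window,
  `sqrt(max(0, mean_axes(var_axis − mean_noise_var)))`.  Windows below
  0.02 AI units are inactive.  AI mean/median/mode/entropy use active
  windows only; mode and entropy use a fixed histogram (0–3 AI units,
  0.03-wide bins; natural-log entropy; mode = modal-bin midpoint).
  Intensity percentages (%low/%moderate/%high, cut-points 0.1/0.5 AI units)
  are computed over all daytime windows and sum to 100.  The cut-points and
  bin edges are package conventions — the source conventions are not
  published — and are configurable.
* **Directionality**: per active 1-s window, the top-eigenvalue share of the
  3×3 acceleration covariance, averaged within each intensity class.
* **Total power**: Welch PSD integrated over 0.1–5 Hz, summed over axes.
  For multi-period aggregates the per-period band powers are combined by
  duration-weighted mean.
* **Activity bouts**: maximal AI runs ≥ bout threshold (pipeline default
  0.1 AI units, above ambient), kept when 4–18 s long; over-long runs are
  discarded by default (strict reading of the 4–18 s definition) or
  truncated by configuration.  Bout features: across-bout mean/SD of peak
  ‖a‖ and of mean ‖da/dt‖ (central differences).

## Submovement extraction

Per bout: trapezoidal integration of the band-passed acceleration with a
linear detrend (velocity starts and ends at exactly zero); PCA of the
velocity covariance defines the movement plane (PC1/PC2), with the
projection kept uncentred so physical rest stays at zero velocity;
each projected axis is cut into candidate submovements at velocity zero
crossings (zero-valued samples act as separators), kept when peak speed
≥ 0.05 m/s and duration ≥ 0.08 s, sign-flipped so peaks are positive.
Short/long duration cutoff: 0.2 s (convention; the source value is
unpublished).  Kinematics per SM: distance ∫|v|dt, peak velocity, peak
acceleration, and normalized jerk

    NJ = sqrt( D^3 / v_peak^2 * ∫ j(t)^2 dt ),

with central-difference jerk (dimensionless; ≈ 14.3 for a pure minimum-jerk
pulse, rising with tremor and fragmentation).

The shape basis is an uncentred PCA (five components, 50-point resampled
unit-peak profiles) fitted on the pooled cohort's long submovements and
frozen, so scores are comparable across subjects and halves; component 1 is
the canonical single-hump pulse shape and higher components add
progressively higher-frequency structure.  With fewer than 50 profiles a
fixed orthonormalized sinusoid basis (0.5, 1, 1.5, 2, 2.5 cycles) is used.
Score features per component and direction: mean |score|, SD, and kurtosis
in the non-excess (Pearson) convention.

The canonical vector has 85 named features (10 AI + 1 spectral + 4 bout +
40 SM kinematic + 30 SM shape-score); 26 are flagged key (AI mean, AI
entropy, and all SM distance/velocity/acceleration aggregates).  Aggregates
over cells with fewer than two submovements are missing, not zero.

## Mouse task

Sessions are eight rounds of nine targets; the first target of each round
initiates the round and is excluded, leaving 64 analyzed (cued) trials — the
only reading consistent with both printed design numbers.  The generator
produces minimum-jerk paths with Fitts-law timing slowed by `(1 + 1.5 θ)`,
θ-scaled perpendicular wander and tremor, injected stationary pauses
(recorded in ground truth), overshoot-and-correct endings, a verification
dwell and a click with θ-dependent duration and slip.

Per cued trial (≥ 5 cursor samples): positions are smoothed with a 5-sample
moving average before differentiation.  Execution ends at the cursor's final
entry into the target disc before the successful button-down; verification
runs from that entry to the button-down, so execution + verification =
movement time exactly.  Pauses are runs with speed below
max(10 px/s, 5% of trial peak) lasting ≥ 100 ms; detected runs are padded by
the known moving-average edge erosion so durations are unbiased.  The speed
profile splits into submovements at local minima below 10% of peak speed;
the main SM covers the greatest path length.  Two related features are
deliberately distinct interpretations of an unpublished definition:
*fraction of distance covered in the main SM* = along-task-axis progress of
the main SM / full task distance, and *main submovement* = the main SM's
share of total path length.  Path-accuracy statistics (movement error /
offset / variability) use 100 arc-length-resampled points so dense sampling
near pauses does not dominate; crossings and direction changes count strict
sign changes (zeros ignored).  The noise-to-force ratio splits the speed
PSD at 4 Hz.  Session features: mean across cued trials, with CV (= SD/mean,
population denominator, missing unless mean > 0) or SD where named — 33
features in canonical order.  Across sessions, per-feature medians are taken
over all sessions or over the first ⌊n/2⌋ / last ⌈n/2⌉ halves (8 → 4/4,
6 → 3/3).

## Composite models

All 85 wearable features enter a lasso regression per clinical target (BARS
total for severity; PROM-Ataxia total for self-reported function).
Leave-one-out cross-validation wraps the entire preprocessing: for each
held-out subject, missing features are imputed with the training fold's
median, features are z-scored with training-fold parameters, and the
regularization weight is chosen by inner 5-fold CV with the
one-standard-error rule over a grid `sd(y_train) · logspace(−2.5, 0, 21)`
(the source's λ procedure is unstated; one-SE favours the sparse,
interpretable models the application wants).  Coefficients are reported on
the standardized scale; selection frequency is the fraction of outer folds
with a non-zero coefficient.  A recomputation test asserts that each fold's
prediction is reproducible from its training subjects alone (no leakage).

A caveat documented by test: with a null (permuted) target the one-SE rule
collapses to intercept-only models, and leave-one-out training means are
perfectly *anti*-correlated with held-out values — the classic LOOCV
pessimism artifact.  The no-leakage property is therefore one-sided (no
positive out-of-fold skill), not a bound on |r|.

## Statistics harness

* Pearson r with Fisher-z 95% CI and two-sided p; correlations with
  clinical scales use ataxia participants only (controls excluded) to avoid
  group-separation inflation.
* Test–retest ICC: two-way mixed-effects, single measure.  Both consistency
  (ICC(3,1) = (MS_R − MS_E)/(MS_R + MS_E)) and absolute-agreement forms are
  implemented; consistency is the default since the source states only
  "two-way mixed effects".  Cross-checked against `pingouin` to 1e-10.
  Wearable halves are days 1–3 vs 4–6; mouse halves are the first/last
  session groups.
* Group contrasts: Mann–Whitney U (exact by full enumeration semantics for
  < 20 total observations, verified against an enumeration oracle;
  tie-corrected normal approximation otherwise) and Cohen's d with
  (n−1)-weighted pooled SD.
* Benjamini–Hochberg step-up correction (via `statsmodels`, verified against
  a brute-force oracle), applied within one family per sensor type.

## Synthetic clinical scores

Each scale is `range_max · slope · θ + N(0, sd)`, clipped to its
remote-assessment range (SARA 0–36, BARS 0–30, MDS-UPDRS III 0–108,
PROM-Ataxia 0–280; slopes 1, 1, 0.5, 0.65; noise sd 1.5, 1.25, 3, 12).
Gait/arm/finger–nose–finger subscores follow the same recipe on their item
ranges; they are noisy monotone companions of the totals rather than exact
summands.  Preataxic subjects (θ ≤ 0.06) are truncated below the SARA < 3
criterion that defines the group.  Controls have θ = 0 and score near zero.

## What passing tests do and do not show

The synthetic cohort demonstrates that the pipeline is correct (closed-form
recoveries, ground-truth bookkeeping, oracle equivalences) and that under
the stated generative model the end-to-end behaviour reproduces the
qualitative structure reported for real cohorts: key submovement and AI
features fall monotonically with severity, mouse timing/pause/smoothness
features rise, composite models track severity with high out-of-fold
correlation and split-half reliability, and effect sizes separate disease
from control.  It does not show that real accelerometry obeys the
minimum-jerk pulse-train model, that real severity acts multiplicatively,
or that the specific correlation magnitudes transfer — synthetic
correlations are substantially higher than any real cohort's because the
generative link is exact.  Bout-schedule statistics are free parameters, not
estimates of real behaviour.

## Known limitations

* Normalized-jerk and duration mean features have noise-dominated,
  heavy-tailed distributions under the zero-crossing segmentation; their
  split-half ICC (≈ 0.5–0.95 at the packaged problem size) stays below that
  of the key distance/velocity/acceleration features, whose reliability the
  package asserts.  Reliability claims are therefore scoped to the key
  feature set.
* The day/night heuristic is validated only on synthetic ground truth; real
  recordings with unusual sleep patterns may need the manual override.
* Missing-data handling (median imputation) and the λ rule are conventions;
  both are exposed in configuration.
* Mouse trial metrics assume one successful click per trial and a
  reasonably continuous 60 Hz cursor stream; drops and device quirks of
  real logs are out of scope.
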