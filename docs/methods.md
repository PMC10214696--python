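# Methods

`dualgait` models a dual-task gait study in older adults with mobility
limitations: each participant walks a straight, level 20 m path once at
preferred speed (single task) and once while serially subtracting sevens
(dual task), wearing one inertial sensor (tri-axial accelerometer +
gyroscope, 100 Hz) near the instep of each shoe.  The package provides the
complete measurement and analysis chain plus a forward model that generates
such data with known ground truth.

## Gait model and stride parameters

A gait cycle is parameterised by nine quantities: stride time; stance ratio
(stance as % of stride); the three stance sub-phases — loading (heel strike
to foot flat), foot flat (full ground contact) and pushing (foot flat to
toe-off) — as % of stance; stride length; strike angle (signed foot pitch
at heel strike, negative); liftoff angle (foot pitch at toe-off, positive);
and minimum toe clearance (lowest toe height during mid-swing).  Swing
time/ratio and gait speed are derived.  Per-stride heel and toe 3D path
lengths and time-normalised trajectory variability (MAD) complete the
metric set.

## Synthetic data generator

The generator is a forward model that inverts the measurement chain.

**Kinematics.** A walk is a 2 s quiet stand, `n` movement intervals
separated by foot-flat intervals, and a final 2 s stand.  A movement
between foot-flats `m-1` and `m` is composed of pushing of stance `m-1`,
the swing, and loading of stance `m`, so each reconstructed stance
aggregates exactly one cycle's sub-phase durations.  Foot pitch follows
septic (7th-order) smoothsteps between phase knots — zero 1st–3rd
derivatives at each knot, i.e. jerk-continuous motion, as real limbs move;
lower-order knots put spurious high-frequency content into the rendered
inertial streams that no 100 Hz integration scheme can absorb.  Sensor
forward position follows one minimum-jerk-style septic per movement, making
the net displacement equal the stride length exactly.  Toe height is pinned
to the ground during pushing, follows a piecewise septic swing curve whose
mid-swing knot *is* the configured minimum toe clearance (segments on both
sides are monotone, so the local minimum is exact), and follows the rigid
foot pivoting on the grounded heel during loading.  Heel and toe are
rigid-body lever arms from the sensor (defaults −12 cm / +13 cm along the
foot, 7 cm above the sole).

**Impact transients.** Compact C² vertical position dips (cos⁴ window,
half-width 0.05 s, base amplitude 2–3 cm) are centred at the exact
heel-strike and toe-off instants, scaled with the strike/liftoff angle
(a steeper strike drops the foot further and lands harder) with a floor at
the base amplitude.  Real foot-worn accelerometers show exactly these
impact spikes, and they are the feature the event detector keys on.  The
transients leave net displacement and foot pitch untouched.

**Sensor rendering.** Positions are evaluated on a 5× oversampled grid and
differentiated centrally; the world acceleration plus gravity is rotated
into the sensor frame through an arbitrary constant mounting rotation
(default: random axis, angle up to 40°), then white noise (accel SD
0.05 m/s², gyro SD 0.005 rad/s — representative consumer-IMU figures) and
constant per-recording biases (SD 0.02 m/s², 0.002 rad/s) are added.
Ground truth (trajectories, events, per-stride parameters) is stored
unrotated.

**Cohorts.** Subjects are drawn hierarchically: subject-level single-task
means and dual-task effects (DTE, %) per metric from group profiles;
stride-level values around the condition mean at the profile's CV targets
(capped at 50% relative so signed metrics keep their sign); a left/right
split `mean·(1 ± r/2)` whose half-normal factor reproduces the symmetry-
index targets in expectation.  The default control and impaired profiles
encode the single-task means/SDs, DTE means/SDs, dual-task CV and asymmetry
targets of a 13 + 16 cohort of mobility-limited older adults.  Draws are
clipped to a physically valid region: stance sub-phases renormalised to
100%, strike angle ≤ −6° (a shallower strike makes loading
indistinguishable from rest to any angular-rate detector), foot flat
≥ 0.18 s, and toe clearance capped by the toe height the strike angle
implies at heel contact (otherwise the configured "minimum" would not be
the swing minimum).  These floors bind rarely and only in the tails.

**MoCA link.** `MoCA = a_g + 0.114·(speed DTE − mean_g) + ε`, rounded and
clipped to [0, 30], with group intercepts at the profile MoCA means (25.7 /
21.0), `ε ~ N(0, 1.2)` resampled (truncated) so labels respect the < 24
cutoff when enforcement is on.  The configured slope is therefore the
*within-group* slope: the printed group MoCA means and DTE means of the
study population imply a between-group slope of ≈ 0.45, which cannot
coexist with a single pooled line of slope 0.114, so a shared-line model
was rejected.  Consequently the unbiased recovery estimator is a
group-adjusted (or within-group) regression of MoCA on speed DTE; a plain
pooled bivariate fit is confounded by the intercept difference.  Because
the regression uses the *recovered* DTE (finitely many strides), a small
errors-in-variables attenuation of ~3–6% is expected and observed.

**Two modes.** `simulate_cohort(mode="signal")` renders IMU streams for
every subject × condition × foot and is used for end-to-end checks;
`mode="parameter"` draws the same stride-level values without signal
synthesis, making thousand-replicate power and type-I studies tractable.
Trajectory MAD exists only in signal mode (it is a property of
trajectories, not scalar parameters).

## Reconstruction pipeline

1. **Zero-velocity detection.** A sample is stationary iff the windowed
   (0.1 s) mean squared angular-rate magnitude is below 0.05 (rad/s)².
   Interval bounds are then refined to the longest per-sample run below
   a tenth of that threshold and expanded while the instantaneous energy
   stays below it: the windowed statistic alone clips bounds by up to half
   a window, while expanding at the full threshold would place the
   integration anchors where the foot already moves at cm/s.  Intervals
   shorter than 0.15 s are dropped (short angular-rate lulls around heel
   strike are not ground contact), as are edge-touching intervals shorter
   than 0.5 s.
2. **Orientation.** A complementary filter: trapezoidal gyro integration
   (the endpoint rule drifts by degrees at swing rates), corrected toward
   the accelerometer gravity direction with per-sample gain 0.08 weighted
   by Gaussian gates on ||f|−g| (scale 0.5 m/s²) and |ω| (scale
   0.2 rad/s), and down-weighted 20× outside detected stationary samples —
   instants with |f|≈g and ω≈0 *during* a movement are not rest.  The
   initial attitude comes from the gravity direction averaged over the
   first stationary interval; yaw is unobservable and left free.
3. **Displacement.** Gravity-removed world acceleration is integrated
   forward and backward from zero velocity between consecutive stationary
   intervals; the two solutions are blended with a linear 0→1 ramp, which
   pins velocity at both anchors and cancels the linear drift of any
   constant residual bias.  Position is the trapezoidal integral; on the
   level walkway the per-movement vertical drift is additionally pinned to
   zero (every foot flat sits at the same height).
4. **Events.** Heel strike = peak of the 20 Hz low-pass-filtered
   specific-force magnitude in the trailing 45% of the preceding movement,
   refined to sub-sample precision on the 4–20 Hz band-passed vertical
   acceleration (the magnitude peak rides on the sloping swing
   deceleration and lands a sample early otherwise).  Toe-off = the
   vertical-acceleration peak with the largest two-sided prominence in the
   leading 60% of the following movement, capped below the next heel
   strike; smooth swing peaks can be taller than the push-off transient
   but lack its deep negative flanks.  Foot-flat bounds are the stationary
   interval bounds.  Invalid strides (missing or mis-ordered events) are
   dropped and logged, never interpolated.
5. **Metrics.** Stride `s` is anchored on stance `s`: stride time =
   HS(s)→HS(s+1); stance = HS(s)→TO(s); the sub-phase times partition the
   stance exactly, so the ratio-conservation identities hold to rounding.
   Stride length is the horizontal displacement between the two
   mid-stances, whose direction also defines the per-stride forward axis
   (removing unobservable yaw).  Contact angles are the signed pitch of
   the relative rotation `R(t)·R(foot-flat)⁻¹` projected on the forward
   axis — the constant mounting cancels in this product, which is what
   makes every metric mounting-invariant.  Heel/toe points come from
   rigid-body lever arms through the yaw-aligned foot-flat frame.  Minimum
   toe clearance is the minimum toe height over the central 35–75% of the
   swing (excluding the toe-off departure from the ground and the
   pre-strike descent), relative to the toe height at mid-stance.  The
   first and last two strides of each pass are excluded (steady state).

## Numerical choices and degenerate inputs

Quaternions are kept unit-norm and sign-continuous; event times are refined
by parabolic interpolation of the filtered peak; the stride grid for
time-normalisation has 101 points (0–100%); MAD uses positions expressed
relative to each stride's start in the forward component, so stride-length
variability rather than cumulative distance drives it; sample (n−1)
standard deviations are used throughout; CV uses the signed mean (negative
means yield negative CV, as for strike angles), SI takes the absolute
left−right difference over the signed mean, and both carry NaN flags at
near-zero denominators.  Constant comparison data, all-zero paired
differences, all-flagged imputation inputs and constant regression
predictors raise errors rather than returning numbers.

## Statistics

Between groups: Shapiro-Wilk per group (α = 0.05) and a 1.5·IQR box-plot
outlier check send the comparison to the asymptotic two-tailed
Mann-Whitney U (continuity correction off by default, configurable);
otherwise Levene's test chooses Welch's vs Student's t.  Within group,
the same checks on the paired differences choose Wilcoxon signed-rank
(asymptotic) vs the paired t-test.  Discrimination uses a single-predictor
maximum-likelihood logistic fit (which preserves ranking, so the AUC
equals that of the oriented raw metric), the Hanley-McNeil nonparametric
SE with a normal two-tailed p against 0.5, an exhaustive cut-point search
minimising (1−sens)² + (1−spec)², and the conventional discrimination
bins (0.7 ≤ AUC < 0.8 acceptable, etc.).  Associations with MoCA use OLS
with standardised betas; stepwise forward selection enters the smallest-p
candidate below 0.05 (ties: larger |β|, then column order), removes
entered variables whose p rises above 0.1, skips candidates already
spanned by the design, and can force covariates.  MoCA scores gain one
point for ≤ 12 education years (capped at 30); groups are stratified at
< 24.  No multiple-testing correction is applied — per-metric p-values
are reported as-is, mirroring standard practice for exploratory
pilot-scale analyses (a reproduction choice, not an endorsement).

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: group-level
means/spreads, dual-task shifts, stride-to-stride variability, left/right
asymmetry, an MoCA–speed-DTE link, arbitrary sensor mounting, sensor noise
and bias, and impact transients at the gait events.  It does **not**
emulate turning at the path ends (each walk is one straight pass; the
analysis excludes boundary strides anyway), soft-tissue artefacts,
non-rigid shoe–sensor coupling, magnetic disturbance (no magnetometer is
used), slopes or uneven ground, inter-metric physiological correlations
beyond those induced by shared stride parameters, or the verbal counting
task itself (only its motor consequences).  Passing recovery tests
therefore demonstrates the correctness of the algorithms under the model's
assumptions, not clinical validity on real recordings.

## Problem sizes

Default checks use 10-stride walks (two feet), 20 mounting rotations for
the invariance study, 30 replicates at n = 200/group for power, 1000
replicates for the type-I rate (parameter mode), n = 200 for slope
recovery, and a 13 + 16 signal-mode cohort with 12 strides/walk for the
end-to-end demonstration — sizes chosen so the full reproduction runs in
about a minute on one CPU while keeping Monte-Carlo error well inside the
decision margins.

## Known limitations

Vertical position between stance anchors carries a residual bow of a few
millimetres (the 100 Hz trapezoid cannot fully capture swing-phase
acceleration content), which is the dominant term in the ~0.1–0.3 cm toe-
clearance recovery error.  The angular-rate energy detector cannot separate
loading from rest for strike angles much shallower than ~6°, a genuine
identifiability limit of gyro-only stationarity detection.  The stepwise
procedure admits a chance noise variable in a minority of runs at
p_enter = 0.05 — a property of stepwise selection itself.  Double-support
metrics are out of reach because the two feet are not temporally synced.
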