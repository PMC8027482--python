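# Methods

This note records the models behind `skimass`, the defaults and why they
were chosen, and what the synthetic-data tests do and do not demonstrate.

## Protocol model

The simulated mass-start is a deterministic schedule: seven 3-min laps of
four segments, then an incremental sprint (start 20 km/h, +1 km/h per 15 s).
Segment speeds of the high-intensity part (S1 18, S2 24, S3 14 km/h) are
fixed by the protocol. Segment *inclines and within-lap durations* are not
published as numbers, only as a track profile; the defaults — S1 5 %/60 s,
S2 2 %/35 s, S3 12 %/45 s, S4 −3 %/40 s — were chosen so that each segment's
incline matches the incline at which its natural gear is used in the
efficiency protocol (G3 at 5 %, G4 at 2 %, G2 at 12 %). They are explicitly
configuration values, not ground truth, and sum to the required 180-s lap.
The S4 belt speed (26 km/h) is likewise a configuration choice for a fast
downhill. Breaks are 30-s windows in which the belt keeps running but the
skier produces no locomotor signal; ranking sorts by breaks ascending, then
TTE descending, with exact ties flagged and broken by input order.

## Work rate, metabolic rate, efficiency

Work rate is P = m·g·v·(sin α + μ·cos α) with α = arctan(grade/100) and
μ = 0.016. The arctan convention matters only at the steepest grade (12 %),
where sin(arctan(0.12)) differs from 0.12 by < 1 %. The oxygen energy
equivalent is looked up from the classical nonprotein-RQ table
(19.61 kJ/L at RER 0.70 to 21.12 kJ/L at 1.00, linear interpolation
between rows); RER is clamped to [0.70, 1.00] because values above 1.0
reflect non-metabolic CO2, and values below 0.70 are rejected as
implausible. Gross efficiency is the ratio of the two rates in percent; the
overall GE is the unweighted mean across the 11–12 submaximal bouts, since
no weighting is specified for the "average" and the bouts are balanced by
design. Because the trial generator inverts exactly this chain
(`vo2_for_power`), efficiency recovery is an identity on noiseless data —
the round trip is tested to 1e-9, and recovery through the 10-s binning and
first-order kinetics to 0.1 pp.

VO2Max is the maximum 30-s moving average of the 10-s values. The property
"VO2Max lies between the series mean and maximum" holds for the
ramp-to-exhaustion series an incremental test produces (for a monotone
series the last window already beats the mean); it is *not* an identity for
arbitrary sequences, so the property tests use ramp-shaped series.

## Synthetic trials

The generator emulates the statistical structure the pipeline consumes, not
human biomechanics:

- **IMU (256 Hz).** Each skiing bout is quasi-periodic with a gear-specific
  cycle period (G2 1.6 s, G3 1.9 s, G4 2.2 s — chosen so G3 cycle rates in
  the sprint fall in the observed 29–36 cycles/min band). The mediolateral
  axis is a cosine with one minimum per cycle at the leftmost position
  (leftward acceleration negative by convention); forward/vertical axes
  carry distinct harmonic mixes per gear. Non-skiing spans (downhill tuck,
  breaks, rest) are aperiodic Gaussian wobble smoothed to ~0.35 s, which
  yields irregular detected "cycles" that train the Other class.
- **Metabolic demand.** Per-second oxygen demand is work rate divided by the
  gear's efficiency and the oxygen equivalent; fixed demands stand in for
  non-propulsive states (tuck 20, break 15, rest 6 mL·min⁻¹·kg⁻¹). Measured
  VO2 follows first-order kinetics dV/dt = (D − V)/τ (τ = 25 s; the source
  data document a delayed response but no model, and a mono-exponential is
  the standard minimal choice), binned to 10-s values. HR uses the same
  kinetics on the heart-rate reserve (τ = 20 s) plus a linear drift
  calibrated so the lap-7 minus lap-2 mean difference equals the configured
  total (default 7.9 pp of HRmax). The HR *demand* is soft-capped at 85 % of
  the reserve so the injected drift is not truncated by the personal maximum
  during the steep uphill — without this the drift statistic would be
  unidentifiable near the ceiling. Measured values are clipped at the
  profile maxima.
- **NIRS (10 Hz).** Baseline minus an intensity-proportional desaturation
  (smoothed, τ = 8 s), slow sinusoidal fluctuation, arm-specific linear
  drift (default −3.0 pp lap 7 − lap 2), and injected 1-s dropouts
  (default one per minute) to exercise the gap rule.
- **Markers (200 Hz) and pole force (100 Hz).** Body markers are rigidly
  attached to a CoM trajectory whose forward position integrates belt speed
  (the treadmill belt "un-rolled" into a ground frame), so the
  segment-weighted CoM is an exact translate of the truth and CoM velocity
  is recovered exactly. Pole axial force is a half-sine impulse confined to
  ground contact (15–50 % of the cycle; the swing is exactly zero, so the
  10-N touchdown rule is well defined). Each cycle's impulses are scaled so
  that the cycle-average of F·V_CoM equals the profile's pole fraction of
  the cycle work rate, split by the left/right asymmetry parameter — power
  recovery is therefore exact up to filtering and alignment error. The
  shaft angle ramps 14°→22° from vertical during contact and eases back
  during the swing, making the pole-tip height a V per cycle whose minimum
  is the touchdown; the force clock is skewed by 0.12 s for the alignment
  stage to recover.
- **Determinism.** All randomness flows from `numpy.random.default_rng`
  seeded from the profile; identical inputs give identical bundles.

Physiological noise magnitudes are free parameters (none are published):
defaults are 0.3 m/s² (IMU), 2 N (force), 2 mm (markers), 1 bpm (HR),
1 mL·min⁻¹·kg⁻¹ per 10-s bin (VO2), 0.5 pp (TSI).

What passing recovery tests shows: the *pipeline's* detection,
classification, decomposition, fusion and statistics are internally
consistent and recover known parameters under realistic rates, offsets and
noise. What it does not show: performance on real recordings — real sway is
not sinusoidal, real gear transitions are gradual, classifier accuracy on
real data (the >99 % reported for the study's own recordings) cannot be
established from synthetic separable classes, and real drift p-values or
TSI segment means depend on between-skier variability this generator does
not attempt to reproduce.

## Cycle detection and classification

The mediolateral channel is Gaussian-smoothed (σ = 0.1 s) and cycle starts
are prominent local minima (prominence ≥ 0.5 m/s², value < 0) at least
0.8 s apart — the period floor corresponds to 75 cycles/min, well above the
observed 29–36 band. Neither constant is published; both were set from the
printed cycle-rate range with headroom. A stream's first and last samples
cannot host a local minimum, so the boundary-recovery guarantee (≤ 1 sample
at zero noise) applies to interior boundaries of a bout.

Features per cycle: each accelerometer axis time-normalized to 30 points
and scaled by its in-window SD (shape is amplitude-invariant), plus the
cycle duration and the three raw variances (94 values). The classifier is
an RBF-kernel SVM (C = 10) behind a standard scaler; training rows are
canonically sorted first so the fit is invariant to input order. The exact
feature set and kernel of the original study are unpublished ("a similar
method" to prior work); any separating choice satisfying the accuracy
targets is acceptable, and the ≥ 99 % train / ≥ 95 % held-out targets are
met with margin. G5 is never generated; it exists only inside Other.
Manual video correction is replaced by the ability to pass explicit labels.

## Power decomposition

Markers and force are low-pass filtered with a zero-phase (forward–
backward) 8th-order Butterworth at 15 Hz, implemented in second-order
sections for numerical stability; the source specifies order and cut-off
but not the phase convention, and zero phase is the norm for kinematics.
The CoM uses adjusted male segment inertial parameters with the head and
trunk as one segment bounded by the shoulder and hip midpoints and the hand
folded into the forearm (no hand marker); fractions are renormalized, so a
custom segment table is equally valid. Alignment matches the first 10-N
force up-crossing to the first kinematic touchdown, defined as the first
local minimum of pole-tip height within 1 cm of the global minimum — plant
depths repeat each poling action, so this picks the first plant while
ignoring zero-phase filter transients at the stream edges (the first
0.25 s are excluded). Negative instantaneous pole power is retained in
cycle averages: whether the original analysis clipped it is unstated, and
clipping would break P_Cycle = P_Pole + P_Ski accounting. Cycles with
non-positive work rate (downhill misclassifications) get flagged missing
percentages; skiers without force streams propagate missing power fields
and drop out pairwise in correlations.

## Fusion

1-Hz reduction is the mean of samples per second; 10-s oxygen values are
step-held across their bin so every second carries a value. NIRS 1-s gaps
are filled with the mean of the two neighbouring valid samples, then the
1-Hz values are centred 3-s means (centred was chosen; trailing is equally
defensible and shifts nothing but a 1-s phase). Longer gaps stay missing —
missing propagates as NaN, never zero. Stream offsets come from
configuration; the pole-force offset is the one estimated from touchdown.

## Statistics

Drift is lap 7 − lap 2 for physiological variables (lap 1 excluded from the
baseline because the response is still rising from rest) and lap 7 − lap 1
for kinematic ones, paired t-test across skiers. Segment contrasts exclude
lap 1 and use one-way ANOVA with Tukey HSD. Spearman uses mid-ranks for
ties (verified against a brute-force rank oracle for all small-n cases);
Pearson applies within the no-break subgroup with pairwise deletion.
Magnitudes are labelled on the conventional bands (0.1/0.3/0.5/0.7/0.9);
p < 0.05 is significant and 0.05–0.10 a trend.

The sprint "reserve" variables are the raw differences between the sprint
peak and the initial-part peak (bpm for HR; mL·min⁻¹·kg⁻¹ for VO2). The
normalized variant (difference as % of personal max) is also computed and
reported with a caveat: the two orderings differ, and the raw difference is
the one whose rank correlation matches the published value; for HR no
per-skier maximum is printed at all, so only the raw difference is
available there.

Two battery values are tie-precision-sensitive: the rounded tables contain
exact ties (e.g. three skiers at GE 15.0 %) that full-precision data would
break, so the recomputed coefficients (0.88, 0.68) sit within 0.01–0.02 of
the published 0.89 and 0.70. They are computed and flagged, never forced.
Correlations whose inputs exist only as figure panels (gear share in the
steep uphill vs rank, and the figure-only contrast battery) are out of
reach of the embedded tables and are not reported as reproductions.

## Problem sizes

The test suite and the acceptance script run the full seven-lap protocol
for IMU/metabolic streams and two-lap windows for the 200-Hz marker
streams; recovery statistics aggregate ≥ 20 seeded trials (18 efficiency
bouts across 6 profiles, 2 marker trials, 3 classification trials, 8 drift
replicates). These sizes give sub-minute runs while leaving the recovery
margins (GE ≤ 0.1/0.5 pp, pole fraction ≤ 1 pp, accuracy ≥ 95 %, drift CI
covering 7.9 pp) comfortably resolved.

## Known limitations

- The generator's gears are separable by construction; classification
  results do not transfer to real signals.
- Marker geometry is rigid; the CoM recovery test validates the weighting
  arithmetic, not segment-parameter accuracy on deforming bodies.
- The pole-force direction convention (tip tilted forward of the handle in
  the un-rolled ground frame) is a generator/processor contract, not a
  biomechanical claim.
- Break timing within the initial part is configured, not modelled;
  fatigue does not feed back into the schedule.
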