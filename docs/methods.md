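# Methods

## Pipeline overview

Each recording passes through: quality control → R-peak detection → beat
segmentation → (averaged beat, random beat) → per-beat SVD decomposition →
energy-series landmarking → TCRT/TMD morphology markers → V5 tangent-method
intervals → cohort statistics.  The decomposition is computed **per analysed
beat**, not on the whole tracing: beat-level parameters are what the
morphology markers consume, and a per-beat fit is insensitive to slow
baseline drift between beats.

## The decomposition and its markers

The 8×N beat matrix (leads I, II, V1–V6; window baseline = per-lead median
of the first 80 ms, subtracted) is factorised with an SVD.  The loop-space
series `s3` is the first three right singular vectors scaled by their
singular values; component signs are fixed so each component is
non-negative at the R peak (a pure reporting convention — every angle
computed downstream is invariant to it).  `energy_fraction_3 =
(σ₁²+σ₂²+σ₃²)/Σσᵢ²` is reported per beat and a warning is logged below
0.95; the ~99% compaction expected of clean recordings is treated as an
empirical property to report, never a hard gate.

The energy series is the squared norm `E₃d = s₁²+s₂²+s₃²` (read as the
squared norm; cosine-based markers and argmax landmarks are identical
either way).  Landmarks on `E₃d`:

| landmark | rule | window |
|---|---|---|
| R peak | argmax | ±60 ms around the detector's hint |
| QRS onset / offset | max up- / down-slope | 100 ms before / after R |
| T peak | argmax | QRS offset + [80, 450] ms |
| T start / end | 5% of T-peak energy, sustained ≥ 20 ms | between QRS offset and window end |

All window constants are operational choices exposed as module constants;
a T-peak candidate below 1% of the R-peak energy raises a flat-T error.

**TCRT** averages cos ∠(`s3(t)`, `s3(t_Tpeak)`) over QRS samples whose
energy reaches 70% of the QRS peak energy.  The threshold exists because
low-energy QRS tail vectors have noisy directions; setting it to 0
reproduces the literal onset-to-offset reading, and a config flag allows
averaging over several T vectors instead of the single T-peak vector (a
variant found in the morphology literature).

**TMD** re-decomposes the T-window segment with its own SVD and takes each
lead's loadings on the first two components (rows of `U S` restricted to two
columns) as its reconstruction vector; TMD is the mean pairwise angle in
[0°, 180°] over all 28 lead pairs, with near-zero-norm vectors (< 10⁻⁶ of
the largest) excluded under a logged warning and more than four exclusions
an error.  Two dimensions follow the originating convention; a flag enables
the 3-D variant.

A deliberate asymmetry: TCRT is an angle *inside* the rank-3 loop space and
is therefore invariant to any global rotation of the underlying dipole,
while TMD lives in *lead space* (per-lead loadings) and is not.  This is a
property of the markers themselves, and the synthetic cohort design exploits
it (below).

## Beat processing

R detection maximises the summed squared cross-lead signal after per-lead
smoothing (12 ms boxcar) and differentiation — the derivative step favours
the steep QRS over tall T waves, and the peak is then refined to the raw
energy maximum within ±30 ms.  Peaks are ≥ 200 ms apart; fewer than two is
an error.  Beats are cut 300 ms pre-R to 500 ms post-R (covering P-on to
T-end at ≥ 45 bpm); if that exceeds the shortest RR the window is shrunk
proportionally with a warning, and beats overrunning the recording edges
are dropped.  The averaged beat is the sample-wise mean aligned on R; the
random beat is a seeded uniform choice among interior beats (edges excluded
when ≥ 3 beats exist, to avoid truncation artefacts).

Quality control flags a lead as *displaced* when its RMS falls below 5% of
the median lead RMS or its rectified waveform correlates with the
cross-lead energy template below 0.2, and as *high interference* when more
than 30% of its (DC-excluded) spectral power lies above 40 Hz.  The
exclusion rule is principled but the thresholds are operational defaults,
exposed as parameters; a recording is usable only with no flags on the
eight analysed leads.

## Intervals (lead V5)

The isoelectric level is the mean of a 40 ms window placed 40 ms before the
energy-landmark QRS onset — that landmark marks the maximal upslope, i.e. a
point already inside the complex, so the window is backed off by its own
width to sit on the PR segment.  The tangent is taken at the steepest
post-peak slope (10 ms least-squares fit, searched 300 ms past the T peak),
inverted T waves handled symmetrically; the T end is the tangent's
intersection with the isoelectric level, rounded to the nearest sample.
QT runs from the QRS onset, Tp-e from the T peak; QTc = QT/√RR with RR the
mean RR of the recording (standard device behaviour).  Intervals are kept
to 0.1 ms internally and ratios reported to two decimals.  For a Gaussian
T wave the construction has a closed form — steepest descent at μ+σ, baseline
crossing at exactly μ+2σ — which the tests use as the oracle.  Intervals are
measured on the averaged beat (mode-consistent with morphology); failures
(e.g. a near-zero V5 T projection) leave missing cells rather than failing
the subject.

## Synthetic data

Each beat is a sum of Gaussian bumps attached to fixed 3-D directions
(amplitude mV, centre offset from R in ms, width σ in ms):

| wave | amplitude | centre | width | direction |
|---|---|---|---|---|
| P | 0.12 | −180 | 20 | QRS axis |
| Q | 0.12 | −28 | 9 | QRS axis tilted +spread |
| R | 1.00 | 0 | 13 | QRS axis |
| S | 0.18 | +26 | 10 | QRS axis tilted −spread |
| T | 0.35 | +300 | 60 | T axis (θ from QRS axis) |
| Tw | 0.08 | +330 | 55 | ⊥ QRS–T plane |

Defaults: fs 1000 Hz, 10 s, 60 bpm, QRS loop spread 15°, white noise
5 µV RMS per lead, no baseline wander.  T timing and width scale with √RR
so repolarization shortens at fast rates.  The `Tw` component gives the T
loop a finite, θ-independent width so that T-shape dispersion is not a
deterministic function of θ; with both loop dials at zero the dipole is
exactly rank 2 and pipeline TCRT equals cos θ to ~10⁻⁴.

The dipole is projected through a fixed 8×3 matrix with the classic Dower
image-surface geometry, **polar-orthonormalised** so its columns are exactly
orthonormal: the induced map from dipole space into the SVD loop space is
then a rotation, angles are preserved, and cos θ is the exact TCRT ground
truth rather than an approximation.  Limb leads are derived from the noisy
I and II, so the Einthoven/Goldberger identities hold exactly in the
output.  Noise is added to the 8 independent leads only.

The cohort generator (defaults: 74 controls / 50 cases) draws each
subject's QRS-T angle from a group normal — 64° ± 20° vs 85° ± 20°,
clamped (not resampled) to [0°, 180°] — so the group cos θ means sit near
0.44 and 0.08 with equal dispersion; SDs of 20° were chosen once as the
angular variability that yields cosine-scale spreads (~0.3) typical of
clinical TCRT cohorts while keeping the group contrast detectable at these
sample sizes.  Each subject's dipole frame is randomised: QRS axis uniform
on the sphere, QRS→T sweep axis uniform in its perpendicular plane.  This
emulates anatomical axis variability and has an exact consequence — the
joint law of the T loop's orientation relative to the leads is identical
for every θ, so TMD (and the V5 intervals) carry no group information by
construction, while TCRT still recovers cos θ.  This reproduces the
dissociation the pipeline is designed to detect (group difference in TCRT,
none in TMD) as a property of the simulation, not an accident of seeds.
Covariates (age, sex, body habitus, blood pressure, treatment flags) are
drawn with realistic marginals and identical distributions in both groups
except the treatment prevalences, which mirror a screening-clinic diabetic
population; the true θ is kept in a hidden `theta_true` column.

What the generator does **not** emulate: realistic P/QRS microstructure,
respiration and RR variability, ectopy, electrode-motion artefacts, or any
physiological coupling between θ and the T loop's shape.  Passing tests
therefore demonstrate correctness of the computation and the statistical
machinery on controlled geometry — not clinical validity on real ECGs.

## Statistics

Continuous variables: mean ± SEM (SD/√n, n−1 denominator; a single
observation reports SEM 0 with a warning) compared by the tie-corrected
Kruskal–Wallis test with a χ²(k−1) p-value (all-identical data return
H = 0, p = 1).  Binary variables: percentages compared by Fisher's exact
test, two-sided by the probability-mass rule, computed with exact integer
arithmetic (a config flag selects the tail-doubling convention; a zero
margin returns p = 1 with a warning).  Values more than 2 reference SDs
from a reference mean are flagged abnormal (strict inequality).  The
summary table renders p ≥ 0.05 as "NS" and p < 0.01 as "<0.01".

The confounder model is OLS of a TCRT outcome on group, age, sex, height,
weight and the treatment/comorbidity flags, binary covariates 0/1-coded and
p-values from the t distribution.  BMI is dropped by default: it is a
deterministic function of height and weight up to rounding, and including
all three makes the design numerically fragile (the flag `drop_bmi=False`
restores it).  A rank-deficient design raises an error naming the dependent
columns; the cohort driver additionally drops covariates that are constant
in the analysed subset and skips the model when n < p + 3.

Cohort-level exclusions are declarative filters (column, operator, value)
applied to the covariate table before any ECG is analysed; the default
filter set encodes the pre-ECG clinical screen (age < 18, prior MI,
angiography, CABG, family history of early sudden death, pregnancy,
surgery/malignancy, atrial fibrillation, pacemaker), and filters naming
absent columns are skipped.  Per-subject stage failures are captured in the
result row so one bad record never aborts a cohort; a run is fully
deterministic given (inputs, seed), with the manifest recording the config
hash and version.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts at the study's group
sizes (74/50) at 1000 Hz/10 s, and smaller configurations (250–500 Hz,
2–4 s) where only code paths, not statistical power, are being exercised.
The multi-seed significance-pattern check uses 20 simulated cohorts.
Energy-compaction figures are quoted at beat level: on a whole 10 s tracing
the quiet inter-beat baseline accumulates noise without signal and the
fraction drops to ~98.8% at 1% noise, while the analysed beat carries
~99.0% (single beat) and ~99.9% (averaged beat).

Known limitations: the landmark windows assume adult resting rates
(40–120 bpm); the tangent method needs a measurable V5 T wave and reports
missing values otherwise; TMD magnitudes on the synthetic dipole are larger
than typical clinical reports because a rank-1-plus-width T loop makes
discordant-lead pairs contribute near-180° angles — TMD comparisons between
simulated groups are meaningful, absolute TMD levels are not calibrated to
real data.
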