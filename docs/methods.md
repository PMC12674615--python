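# Methods

This note documents the models and conventions implemented in spckit, the
defaults and why they were chosen, and what the synthetic-data generators
do and do not establish about real recordings.

## Task protocol model

A session is an ordered tiling of half-open epochs `[start, end)` — OFF
(no stimulus), ON (stimulus presentation), ITI (inter-trial interval) —
plus a list of stimulus events (light, tone, simultaneous light+tone,
footshock). Half-open boundaries make every instant belong to exactly one
epoch, so a sample falling on a boundary is deterministically assigned to
the later epoch. Tiling is validated in exact rational arithmetic
(`fractions.Fraction` over the stored binary floats): because consecutive
epochs share their boundary value bit-for-bit, the duration sum telescopes
and equality with the stored total is exact, not approximate.

Builder conventions:

* *Preconditioning* — n trials have n−1 inter-trial intervals. With the
  defaults (3-min initial OFF, five 30-s light+tone presentations, 30-s
  ITIs, 1-min final OFF) this reproduces the canonical 510-s session
  exactly. The same n−1 convention applied to the conditioning defaults
  (five 10-s CS, 1-min ITIs) gives 530 s; since the interval convention
  that would shorten it is not well defined, the conditioning builder
  takes explicit parameters and hard-codes no total.
* *Conditioning* — each footshock starts `cs_duration − shock_duration`
  after its light onset so the two co-terminate; the no-shock group gets
  the identical light schedule with no shock events.
* *Probe tests* — one OFF epoch then one ON epoch carrying a single
  continuous stimulus; tone reads out mediated learning, light direct
  learning.
* *Unpaired sessions* — a single modality per session; the across-session
  light/tone order is an explicit caller-supplied sequence, with a seeded
  balanced generator (`unpaired_session_modalities`) as the default.
* *Habituation* — one 20-min OFF epoch.

## Freezing from pose tracks

The reference position defaults to the centroid of all bodyparts. Each
bodypart's low-likelihood detections (below `min_confidence`, default
0.9 — standard pose-estimation practice) are bridged first by linear
interpolation along that bodypart's own trajectory (nearest-valid fill at
the edges); the centroid then averages the repaired parts. Interpolating
per part before averaging matters: dropping a single off-center bodypart
from a plain confident-subset centroid shifts the centroid by the
bodypart's offset and manufactures a spurious movement spike. Bodyparts
confident in fewer than half the frames are excluded entirely.

Speed for frame pair *i* is the Euclidean displacement between
consecutive positions times the frame rate; a pair is freezing when its
displacement is strictly below `displacement_threshold_cm` (default
0.02 cm, i.e. strictly below 0.5 cm/s at 25 fps — `0.02 * 25 == 0.5` is
exact in binary floating point). Classification is per frame pair with no
bout smoothing by default; an optional `min_bout_s` suppresses freezing
runs shorter than a minimum duration for users who want bout-level
readouts. A track of n frames yields n−1 pairs; epoch membership uses the
pair midpoint time. Pixel→cm calibration (`px_per_cm`) is supplied by the
user, e.g. arena width in cm over arena width in px.

Per-epoch summaries report `100 × freezing pairs / pairs` within the
epoch; an epoch containing no pair midpoint is an error rather than 0%.
Binned time courses use half-open bins (default 10 s); empty bins are
missing (NaN), never zero, and a trailing partial bin is kept and
flagged. `compare_with_reference` reports both frame-pair agreement and
the Pearson correlation of binned percentages against an external scorer,
since validation against manual counts can be quoted at either level.

## Photometry pipeline

Stages, in order:

1. **Trim** the first 60 s, where the fast component of photobleaching
   dominates. TTLs in the removed segment are dropped with a logged
   warning, never silently.
2. **Despike** both channels with a Hampel filter: a sample deviating
   from its window median by more than `n_mad × 1.4826 × MAD` (window 11
   samples, 5 scaled MADs by default) is replaced by that median. The
   1.4826 factor makes the MAD a consistent Gaussian scale estimate, so
   the default threshold sits near 5σ. On locally monotone traces the
   window median equals the center sample and the filter is an exact
   no-op. On heavy white noise the windowed MAD is itself noisy, so a
   small fraction of clean samples (≈0.4% at the defaults) is replaced by
   a nearby median; each such replacement is bounded by the local noise
   scale and is harmless downstream. A literal "no clean sample is ever
   touched" guarantee is unattainable for any threshold rule applied to
   tens of thousands of Gaussian samples.
3. **Isosbestic fit**: ordinary least squares of the 405-nm control onto
   the 470-nm signal, `fitted = a·F405 + b`. The coefficients scale the
   control to best predict the signal — the convention consistent with a
   ΔF/F denominator called "F405 (fitted)". The fit is per session.
4. **ΔF/F** = (F470 − fitted)/fitted, with strictly positive fitted
   values enforced (violations reported with sample indices). A global
   rescaling of both channels leaves ΔF/F unchanged.
5. **Z-scoring** against the whole trimmed trace (session mode) or, in
   trial-wise mode, each PETH row against its own pre-onset window
   (default −5 to 0 s). Both are exposed; session mode is the default.
6. **PETH**: trials are resampled onto a common grid at the trace's own
   sampling interval by linear interpolation, window −5 to +10 s. Onsets
   without full window coverage are dropped with a logged warning; the
   trial count always equals the usable onsets.
7. **Peak statistics**: the per-trial response is the maximum over the
   first post-onset second; the baseline statistic is the same maximum
   over the mirrored pre-onset second, so the two are directly
   comparable. The suprathreshold count uses a strict `z > 2` criterion.
   The threshold is interpreted in z-score units (a raw ΔF/F of 2, i.e.
   200%, is implausible for these sensors) and is configurable.

An optional boxcar smoothing (`smooth_s`, default off) can be applied to
PETH rows after z-scoring. Reading a maximum off an unsmoothed noisy
trace is upward-biased by the sample-level noise maximum; a 0.1-s boxcar
suppresses that bias while attenuating the default transient peak by
only ~1.5%. The recovery analyses in the test suite and acceptance
script use it.

Clock synchronization between video and photometry uses paired TTL
trains: a pure offset for a single pair, otherwise the least-squares
affine map (offset plus drift).

## Statistical workflow

Freezing percentages are positive and right-skewed, so the multivariable
model is a gamma GLM with log link — multiplicative group/epoch effects
on a strictly positive mean. Planned comparisons are Wald t-contrasts on
the linear predictor (dispersion estimated by Pearson χ²; t reference
with the residual degrees of freedom), and the family of planned
p-values is adjusted jointly by Benjamini–Hochberg. Exact zeros are
outside the gamma domain; a configurable small offset shifts them, and
the shift is logged. Empirically the null rejection rate of the ON–OFF
contrast at n = 12/group is ≈0.06 — the mild anti-conservatism expected
from plugging an estimated gamma dispersion into Wald inference at this
sample size.

The cohort workflow fits `value ~ C(group) * C(epoch)` by default and
tests ON vs OFF within each group. Animal identity can be added as a
fixed blocking factor (`C(animal_id)`), but the default leaves it out:
with one observation per animal × epoch, a 12-animal block absorbs 11 of
22 residual degrees of freedom and destabilizes the dispersion estimate;
a gamma likelihood on signed paired differences is not an option since
differences can be negative.

Univariate tools wrap the standard implementations: Kruskal–Wallis with
tie correction, Mann–Whitney with exact small-sample p-values (no ties,
n ≤ 8) and tie-corrected normal approximation otherwise, Levene's test
median-centred (Brown–Forsythe). The Kolmogorov–Smirnov normality check
uses estimated moments, as commonly practiced; this is anti-conservative
(the estimate adapts to the sample) and the implementation logs that
caveat and offers the Lilliefors small-sample correction as an
alternative. Family selection for the GLM fits each candidate
(gamma, gaussian, inverse-gaussian) as an intercept-only model and picks
the lowest AIC.

## Synthetic data: what it emulates, what it does not

**Pose tracks.** Outside immobility bouts the animal performs a
correlated random walk (log-normal step lengths around 4 cm/s median,
heading diffusion 0.5 rad/frame, reflected at the walls of a 30×30-cm
arena). During bouts the per-frame displacement is half-normal with sd
0.004 cm — five standard deviations under the 0.02-cm criterion, so
bout interiors are essentially never misclassified. Bouts are placed by
a Dirichlet split around a mean bout length of 8 s and snapped to the
frame grid, so the realized immobile fraction matches the request to
within a frame or two per bout. Bodyparts sit at fixed offsets around
the center with 0.002-cm jitter; detections drop out (likelihood < 0.5,
position corrupted by ±5-cm noise) with probability 0.005 per frame and
bodypart, exercising the confidence filtering and interpolation.

Not emulated: grooming and rearing (movements that are neither
locomotion nor freezing), partial-occlusion likelihood profiles, camera
distortion, multi-animal interactions. Recovery of the immobile fraction
to ±2 percentage points on these tracks therefore validates the
criterion arithmetic, the trajectory repair, and the epoch bookkeeping —
not robustness to every failure mode of real pose estimation.

**Photometry.** Both channels share a double-exponential bleach (fast
τ = 20 s — mostly gone after the 60-s trim, which is why the pipeline
trims — and slow τ = 3000 s) scaled by per-channel gains (2.0 signal,
1.0 control), with white Gaussian noise (signal sd 0.02; control noise
30% of that). Transients are peak-normalized difference-of-exponentials
kernels (rise 50 ms, decay 600 ms, approximating fast calcium-sensor
kinetics) added as *fractional* modulations of the signal baseline, i.e.
directly in ΔF/F units. Amplitudes stated "in noise-sd units" are
converted by the analytic post-pipeline ΔF/F noise sd (both channel
noises propagated through the isosbestic fit, averaged over the trimmed
bleach trajectory), which makes z-scored peak recovery well defined even
though the ΔF/F noise level drifts as the bleach decays. Point artifacts
are single-sample spikes on both channels.

Not emulated: hemodynamic contamination, motion artifacts correlated
between channels with wavelength-dependent gain, sensor saturation,
slow drift unrelated to bleaching. The recovery guarantees (null ΔF/F on
bleach-only recordings to 10⁻⁶, mean PETH peaks within 10% of injected
amplitudes at 1–4× noise sd, exact suprathreshold counts at 4×)
validate the correction algebra and the peri-event bookkeeping, not
artifact rejection on pathological recordings.

**Cohorts.** Freezing percentages are drawn independently per
animal × epoch from a gamma with shape 3 (CV ≈ 0.58, typical of
freezing data), OFF mean 15%, and a multiplicative ON effect per group
(2.5 for the paired group by default, 1.0 otherwise — the mediated- and
direct-learning pattern at a realistic effect size). No within-animal
correlation is simulated, matching the default unblocked GLM.

## Problem sizes and numerical choices

The recovery suites use the task's own scale: 510-s or 360-s sessions at
25 fps (pose) and 100 samples/s (photometry); PETH recovery pools 5
pairings × 6 sessions × 3 subjects per amplitude. GLM calibration uses
1000 null replicates and 300 at the 2.5× effect. Ties in ranks are
handled by the standard corrections; PETH resampling is linear
interpolation; all random generation flows through
`numpy.random.default_rng` seeds, and every generator is a pure function
of (parameters, seed) — the basis for the byte-identical rerun
guarantee of the pipeline runners, which also fix the CSV float format.

## Known limitations

* The freezing criterion is a pure speed threshold; it cannot separate
  freezing from motionless non-fear states (sleep, quiet rest).
* The isosbestic fit is per session; slow gain drift within a session is
  absorbed only to first order.
* The gamma GLM treats repeated OFF/ON measures as independent unless
  animal blocking is enabled; strong within-animal correlation in real
  cohorts would make the default contrasts anti-conservative.
* The Hampel despiker replaces a small fraction of clean samples on
  noise-dominated traces (see above); window and threshold are
  configurable where this matters.
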