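# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the package. Nothing here states an empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Study design being emulated

Three expertise groups (19 non-musicians, 20 amateur and 20 expert pianists)
hear string-quartet pieces ending regularly (R), with a subtle in-key
transgression (T^sub: tonic in first inversion) or an apparent one (T^app:
subdominant in first inversion), and appraise each ending YES/NO. EEG: 204
retained channels, 1,000 Hz acquisition, 250 Hz analysis rate, ≤90
trials/condition (~70 artifact-free), epochs −200…750 ms around the closure
chord.

Time conventions: the axis is sample-based with origin at stimulus onset and
step 1/sfreq; windows given in ms are half-open [start, end) and a sample
belongs to a window iff its time stamp lies inside. Epoch *cutting* spans
−200…750 ms inclusive where representable (951 samples at 1,000 Hz, 238 at
250 Hz). The 295–480 ms analysis window at 250 Hz therefore contains 46
frames (296…476 ms), i.e. 184 ms — duration tables must sum to exactly that.

## Synthetic-data generator

The generator is the package's study stand-in; its defaults are the study
conditions above.

* **Templates.** Seven scalp maps obtained by forward-projecting random pairs
  of superficial dipoles through the 3-shell head model, average-referenced
  and scaled to unit GFP. Pairwise |spatial correlation| is capped at 0.8
  (every pairwise GMD > 0.63).
* **ERP model.** Each design cell's ERP is a piecewise sequence of templates:
  a shared early sequence (maps 1–3 in 0–296 ms, map 3 returning after
  480 ms), and a group/condition-specific split of the 46-frame analysis
  window among maps 4–7. The "naïve" map dominates non-musicians
  (26−shift frames), the "expert" maps dominate experts, and each
  transgression level shifts 1–2 frames from the naïve to the first expert
  map — reproducing the qualitative duration ordering of the study. A smooth
  positive envelope 1 + 0.8·sin(πt/750) modulates amplitude (peak GFP scale
  3 µV); the envelope is strictly positive so no post-stimulus frame has zero
  GFP.
* **Noise and variability.** Independent Gaussian channel noise; the default
  sd is set so the single-trial RMS SNR is 0.5 (≈8 µV here), and subject
  amplitudes carry log-normal jitter (sd 20%). A per-condition ERP amplitude
  scale is not published; these values were chosen once to make the effects
  detectable at n≈20 and are free parameters. The evoked-level shortcut
  (`simulate_study_evoked`) draws subject ERPs with noise sd/√n_trials —
  statistically equivalent to averaging the trial-level output and far
  cheaper; trial-level simulation remains available for the preprocessing
  stages.
* **Behavior.** Equal-variance signal detection. A subject has one shared
  response criterion for R: the false-alarm rate is Φ(−d̄/2 − c) with d̄ the
  subject's mean sensitivity, and each transgression's hit rate is chosen so
  z(H) − z(FA) equals the cell's d′ exactly. Cell means follow the published
  group means (Non-musicians 0.49/1.60, Amateurs 1.54/3.68); expert means are
  only described as "at ceiling" and default to 3.8/4.2, picked so the
  expertise ordering holds for T^app with margin while the 1/(2N)-rule
  estimator bias at n=90 (checked by binomial enumeration) stays within the
  recovery tolerance. Between-subject spread of true sensitivity is 0.45,
  consistent with the published cell standard deviations.

What the generator does **not** emulate: ocular/muscle artifacts (rejection is
tested with injected threshold crossings), 1/f noise spectra, inter-subject
topographic variability (all subjects share the template maps), or volume
conduction differences between heads. Passing recovery tests therefore shows
the chain is correct under its own assumptions, not that it would recover
identical numbers from real recordings.

## Preprocessing

Stage order is fixed: average reference → band-pass → downsample →
interpolate → reject → average → baseline. Filtering is zero-phase
(forward–backward `sosfiltfilt`): phase handling is not published, and ERP
latency claims require zero phase; the effective magnitude response is the
square of the single-pass response. The −12 dB/octave roll-off is a property
of the 2nd-order Butterworth *design*; `bandpass_response` therefore reports
the analog design response by default, since the bilinear digital realisation
warps frequencies far above the band (the passband, 0.25–30 Hz at fs ≥ 250 Hz,
is unaffected). Decimation keeps every 4th sample with no extra anti-alias
filter — legitimate only because the 30 Hz low-pass precedes it. Spherical
splines use the Perrin basis g(x) = (1/4π)Σ (2n+1)/(n(n+1))^m P_n(x) with
m = 4, 50 terms, ridge 1e-5 on the interpolation system. The ±100 µV
rejection uses strict inequality (a peak of exactly 100 µV is kept) over the
whole epoch window.

## Microstate analysis

Clustering is polarity-**sensitive** by default: evoked components have fixed
polarity, so a map and its sign-flip are distinct states; the
polarity-invariant variant (first principal direction per cluster, |r|
assignment) is retained for spontaneous-EEG-style use. Details that matter:

* Initialisation is farthest-point seeding in correlation space (a random
  first frame, then repeatedly the frame least correlated with the chosen
  seeds); best of `n_restarts` by explained variance. Plain random seeding
  leaves the dispersion curve non-monotone in k, which breaks model-order
  selection.
* Ties in assignment break toward the lowest map index. Zero-GFP frames stay
  unlabeled everywhere.
* Segments shorter than 7 frames (28 ms) are removed at segmentation by
  reassigning their frames to the higher-correlating neighbouring segment;
  back-fitting applies **no** smoothing, so individual durations may fragment.
* The selection criteria are computed from the raw (pre-smoothing) assignment
  of all usable frames: CV = σ̂²((C−1)/(C−1−k))² with σ̂² the mean residual
  per frame and C the channel count, and the Krzanowski–Lai index
  KL(k) = DIFF(k)/DIFF(k+1), DIFF(k) = W(k−1)^{2/C} − W(k)^{2/C} on the
  dispersion W (zero at the k-range endpoints; exponent configurable).
  k_opt maximises KL among k whose CV lies within 5% of the CV minimum.
  The CV criterion alone keeps decreasing on structureless data whenever the
  frame count is small relative to C — the KL gate is what stops overfitting.
* Default k search range 2–12; the analysis drivers use 250 Hz throughout.

## Source model and inverse

The head is three concentric spheres fitted to the montage (electrodes are
radially projected onto the scalp sphere). Conductivities 0.33/0.0042/0.33 S/m
and radius ratios 0.87/0.92/1.00 are the classical defaults; the study names
the model but no parameters. The lead field solves the per-degree radial
boundary-value problem exactly (4×4 system per degree, radii scaled by the
scalp radius for conditioning) and sums 60 Legendre terms; eccentricities
above 0.95 of the brain radius are flagged for slow convergence. Gray matter
is replaced by a spherical shell (0.45–0.95 of an effective radius) whose
scale is adjusted so the 6 mm lattice holds ≈3005 nodes — a template-anatomy
stand-in, so node coordinates are nominal.

The inverse is the depth-weighted minimum norm K = W Lᵀ (L W Lᵀ + λH)⁺ with
per-node weights ‖L_node‖⁻¹ (exponent configurable), λ = 0.05 × mean
eigenvalue of L W Lᵀ on the average-reference subspace, and H the centring
matrix; λ = 0 is rejected because the average-referenced system is singular.
Current density is the norm of the node moment after averaging the ERP over
the analysis window (linear, so order is immaterial; the norm is taken after
averaging). Absolute µA/mm³ calibration is not reproducible from the
published description; CD is treated as relative, and every downstream
statistic is scale-invariant.

**Known limitation (documented expectation gap).** A weighted minimum norm
does not localize noiseless point sources to the exact node: the peak falls
within the immediate lattice neighbourhood (≤ √3·6 mm) in ≈96% of
sensor-covered superficial draws, but within one 6 mm spacing only ≈60% even
at λ→0 (≈30% at the default λ). An sLORETA-style resolution standardisation
of the same operator would localize exactly, but that is a different
estimator. The acceptance-level test asserting 95%-within-6 mm is therefore
expected to fail and is kept as documentation of the idealized expectation;
the unit suite asserts the neighbourhood property the method actually has.

## Source statistics

The node-wise mixed ANOVA uses unweighted-means sums of squares (harmonic
mean group size) for the unequal groups; between effect tested against
subjects-within-groups (df 2, 56), within and interaction against the
subject × condition residual (df 2/4, 112); no sphericity correction (3
levels; published df are uncorrected). Degenerate inputs (zero error sum of
squares with zero effect) report F = 0, p = 1. The cluster criterion is
p < 0.005 with ≥10 contiguous nodes under 10 mm connectivity; the Monte-Carlo
calibration smooths i.i.d. Gaussian node noise with a 7 mm-FWHM Gaussian
kernel over node distances (rows renormalised, variance re-standardised
analytically), thresholds two-sidedly and searches components — the real CD
maps are never smoothed (AlphaSim convention). Fisher-LSD post-hocs reuse the
omnibus error term and df, are uncorrected, and are only released when the
omnibus p < 0.05; with 3 groups this gatekeeping bounds the family-wise error
near the nominal level (verified by a 10,000-replication null in the suite).

**Second documented expectation gap.** The ≤0.5%-of-seeds bound for surviving
clusters under a full-pipeline null presumes the 7 mm calibration describes
the smoothness of the CD maps. It does not: the inverse operator's point
spread is several cm wide, node F-values are strongly correlated, and ≈half of
null runs show a ≥10-node cluster. The identical ANOVA → cluster chain on
spatially independent node noise yields none, isolating the cause as
calibration non-transfer rather than a defect in the statistics. The
acceptance-level test keeps the full-pipeline reading and is expected red.

## Behavior

Percent correct per condition plus d′ per transgression with false alarms
from the shared R trials. Extreme rates use the 1/(2N) rule (log-linear
offered); interior rates are never altered, so d′ equals the closed form
exactly away from ceiling. Partial η² = SS_effect/(SS_effect + SS_error),
matching the published effect-size label. Degenerate contrasts (zero
variance) report p = 1 with a warning rather than failing.

## Problem sizes used by tests and drivers

The suite runs the full study scale (59 subjects × 3 conditions × 204
channels) through the evoked-level generator; trial-level simulation appears
at reduced scale in the preprocessing and CLI tests. The Monte-Carlo
calibration runs its full 10,000 iterations (sparse smoothing kernel; a few
seconds); the seed-quantile properties use 10–20 seeds for generator recovery
and 200 seeds for the null-pipeline rate. These sizes are the package's
defaults for a desk-scale reproduction and are stated here so results can be
regenerated exactly.
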