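# Methods

This note documents the models and estimators in `flairqc`, the
parameters that matter, the choices made where the design was open, and
what the synthetic experiments can and cannot show about real data.

## The synthetic head phantom

The phantom is a nested-ellipsoid head in a FLAIR-like contrast regime
(GM brightest, then WM, CSF suppressed, air at zero; defaults 300 / 200 /
50 / 0 signal units): an outer CSF shell, a cortical GM ribbon, a WM
core, and two ventricle ellipsoids. Geometry scales with the field of
view (head semi-axes 0.36 / 0.40 / 0.33 of the FOV along FH / AP / RL).
The array axis convention is fixed throughout: axis 0 = FH (frequency
encoding), axis 1 = AP (phase encoding), axis 2 = RL (slice encoding).

Rasterization happens on a supersampled grid (default 2×, 4× for
resolution experiments) that is block-averaged to the target matrix.
This matters twice: tissue interfaces acquire continuously distributed
sub-voxel phases, which the pooled-ESF MTF estimator requires, and the
block average is exactly the box aperture of an idealized voxel.
Degradations are applied in a fixed order:

1. tissue means on the label map;
2. multiplicative bias field — a product of per-axis polynomials of
   degree ≤ 2, normalized to mean 1, rescaled so the peak fractional
   modulation equals `bias_amplitude`;
3. anisotropic Gaussian blur of per-axis FWHM, applied **on the
   supersampled grid**. Blurring after downsampling would hand the
   super-resolution MTF estimator a periodized (aliased) version of the
   blur spectrum instead of the blur itself; the PSF physically acts on
   the continuous object, so the simulation does too;
4. ghosting: a copy of the blurred head signal rolled along AP by
   `ghost_shift_fraction` of the FOV (default 0.25), scaled by
   `ghost_amplitude` — the phase-encoding-direction artefact of motion
   or system instability;
5. Rician noise: the magnitude of (signal + g1, g2) with i.i.d. Gaussian
   quadrature channels of sd `noise_sd`; the air background is then
   Rayleigh, as in magnitude MRI.

Tissue masks mark **pure** voxels only (all subvoxels one tissue), so a
degradation-free phantom carries the exact tissue mean on every masked
voxel, and mask-based statistics avoid partial-volume rims. The GM
ribbon is 7 voxels and the CSF shell 8 voxels thick by default: the edge
extractor requires 5 clean samples on each side of a cortical crossing
plus partial-volume voxels at both boundaries, which a thinner ribbon
cannot supply.

### Cohorts and the latent-quality coupling

`default_cohort_spec` builds a fleet of devices with latent quality q
spread evenly over [−1.5, 1.5]. q drives, per device: Michelson contrast
(mean 0.20 + 0.04 q), WM SNR (25 · e^{0.3 q}), blur FWHM (2.8 − 0.4 q mm,
15% worse along AP), and ghost amplitude (0.12 − 0.05 q, clipped at 0).
Each device also draws an arbitrary global intensity **gain**
(log-normal, sd 0.6), as real scanners have arbitrary signal scales.
Per-study parameters are truncated-normal draws around the device means,
with a per-study latent quality q_study = q + N(0, 0.25) that the
simulated observer sees. Per-study seeds are a stable hash of (cohort
seed, device id, study index), so any study can be regenerated in
isolation.

The gain is the mechanism behind the expected correlation pattern:
scale-free parameters (contrast, CNR, QI, MTF) remain comparable across
devices, while noise in raw signal units is scrambled by the gain and
correlates only weakly with observed quality. The blur draw has a
deliberately large study-level sd (0.35 mm) relative to its device-level
range, emulating motion-like study-to-study resolution variability.

This generator emulates: device-level quality differences expressed in
several physically distinct degradations, study-level variability,
magnitude-MRI noise statistics, phase-encode ghosting, and smooth
intensity inhomogeneity. It does **not** emulate: realistic anatomy,
k-space or parallel-imaging physics, motion blur with structured PSFs,
vendor-specific filters, or segmentation error (masks are ground truth).
Passing tests therefore demonstrate estimator correctness under
controlled conditions, not clinical performance; with real data the
segmentation and the artefact spectrum become additional error sources.

## Technical QC parameters

All tissue statistics run on the bias-corrected volume; the QI runs on
the raw volume (its background must not be touched by a brain-driven
correction).

**Bias field.** The volume is flattened tissue-wise (each class divided
by its median), leaving ≈ the bias field on brain voxels; a normalized
Gaussian convolution (FWHM 60 mm; anything ≳ 40 mm works) smooths and
extrapolates it, and the field is normalized to mean 1 over the brain.
Correction is guaranteed non-harmful: if dividing by the estimated field
would raise the WM coefficient of variation (e.g. on an already-clean
volume), the input is returned unchanged.

**Tissue levels** are medians over 1-voxel-eroded pure masks (≥ 100
voxels required). Medians, not means: robust to Rician floor and
residual bias.

**Contrast** is Michelson, (μGM − μWM)/(μGM + μWM): bounded, unitless,
comparable across field strengths and gains. A negative value (inverted
ordering) is flagged, not raised.

**Noise** is estimated from the residual of a 3×3×3 median filter inside
eroded WM: 1.4826 · MAD(residual) / 0.9536, where 0.9536 is the
calibrated ratio between the robust residual SD and the true voxel SD
for this filter on Gaussian noise (measured once on pure noise and
fixed). The local-median residual makes the estimate insensitive to slow
anatomy and leftover bias; a constant offset changes nothing.

**CNR** = (μGM − μWM)/σ, the literal contrast-to-noise ratio of the two
tissues that carry FLAIR's diagnostic contrast. Sign is preserved;
noise-free volumes are flagged rather than divided by zero.

**QI** = 1 − N_artefact/N_background on the air region (outside the head
mask dilated by 3 voxels, inside a 2-voxel frame, ≥ 10⁴ voxels).
Artefact voxels exceed median + 4 · (1.4826 · MAD) of the background and
belong to connected components of ≥ 5 voxels: isolated Rayleigh-tail
voxels do not count, coherent ghost signal does. Higher is better,
QI ∈ [0, 1].

## Edge-based MTF estimation

Spatial resolution is measured from anatomy, slanted-edge style, with
the cortical GM→CSF surface as the edge.

**Profile extraction.** Along one array axis, a candidate is a line
segment with ≥ 5 consecutive pure-GM voxels, a gap of ≤ 3 partial
voxels, then ≥ 5 pure-CSF voxels (either orientation). Candidates are
rejected if their plateau contrast (median of each side) is below 20% of
the global GM–CSF difference, if the plateaus invert, or if the crossing
is oblique to the surface: the local normal comes from the gradient of a
smoothed inside-cortex indicator, and |cos| ≥ 0.9 between the normal and
the scan axis is required. Accepted profiles are normalized to [0, 1] by
their own plateau medians (adapting the calculation to local base signal
levels) and their sample offsets are projected onto the normal, which
removes the 1/cos θ stretch of oblique sampling exactly for a locally
planar edge.

**Sub-voxel registration.** Each profile's edge position is initialized
as the centroid of its absolute gradient. The centroid of a coarsely
sampled edge carries a sampling-phase-dependent bias that can reach a
large fraction of a voxel when the blur is at or below the voxel pitch,
which would wreck the pooled ESF; two passes of template re-registration
(least-squares shift of each profile against the pooled ESF, parabolic
sub-grid refinement) remove it. On a synthetic tilted plane the
registered positions recover the true sub-voxel boundary heights with
RMSE < 0.05 voxel.

**ESF → LSF → MTF.** Offsets are pooled into ¼-voxel bins over ±5.5
voxels. Each bin's value is a local linear regression evaluated at the
bin center (a plain bin mean is biased by any clustering of sample
phases within the bin). The binned ESF is monotone-smoothed by isotonic
regression, extended with its asymptotic plateaus to ±12 voxels (so the
apodization window is much wider than the LSF — windowing a narrow
support biases the MTF upward), differentiated by central differences,
Hann-apodized, Fourier-transformed, and normalized to 1 at zero
frequency. Frequencies are in cycles/mm via the voxel spacing.

**Known-chain correction.** The measured curve is divided by the
analytic transfer functions of the discretization chain — voxel box
aperture sinc(f·a), bin aperture sinc(f·w), central-difference response
sinc(2 f w) — and truncated where that correction falls below 0.15.
Without it, the estimator reports the *system* MTF (blur × aperture)
rather than the blur MTF, and the Gaussian oracle is unreachable for
sub-voxel blurs. The usable band therefore extends beyond the voxel
Nyquist (the pooled ESF is super-sampled); MTF50/MTF10 are the first
downward crossings of 0.5/0.1, linearly interpolated, with an `inf`
sentinel (flagged, excluded from correlations) when a threshold lies
beyond the measurable band — which can happen for the sharpest studies
at coarse demo resolutions.

On noise-free Gaussian-blurred phantoms (σ = 0.5–2.0 mm, voxel pitch
2σ, 4× rasterization) the estimated MTF50/MTF10 sit within ~3% of the
closed forms f50 = √(ln 2 / 2π²σ²), f10 = √(ln 10 / 2π²σ²) on all three
axes; the errors are identical across σ because the problem is exactly
scale-equivariant in voxel units.

## Forced choice and ratings

Pairs are drawn uniformly with replacement over unordered pairs of the
full study pool, sides randomized, self-comparison forbidden — the only
scheduling rule. The simulated observer picks the left volume with
probability 1/(1 + e^{−(q_left − q_right)/τ}): a logistic
(Bradley–Terry-type) choice model whose single noise knob τ (default
0.35 on the latent-quality scale) spans quality oracle (τ→0) to coin
flip (τ→∞). The logistic-vs-probit choice is arbitrary at this level of
abstraction. One observer by default; the vote schema carries observer
ids so multi-rater extensions need no format change. Ratings are the
exact binomial formulas per study; studies never drawn (N_t = 0) are
flagged unrated and excluded downstream.

## Cohort statistics

Shapiro–Wilk per device (≥ 3 rated studies; zero-variance samples
flagged), classical one-way fixed-effects ANOVA of P across devices,
Tukey HSD via the studentized range (Tukey–Kramer harmonic form for
unequal groups, as in `scipy.stats.tukey_hsd`), significance at 0.05.
R² is the squared Pearson correlation of a simple linear fit — "based on
linear correlation" admits exactly this reading — computed per study and
on within-device medians of both variables (standard even-n midpoint
medians, rated studies only, non-finite parameter values dropped
pairwise).

One calibration subtlety: under a null simulated as a single shared vote
log, the P values are negatively coupled (every win is another study's
loss; the participation-weighted mean of P is exactly ½), which deflates
the ANOVA type-I rate to ≈ 0.035–0.04 at the 5-device scale — the test
is conservative on real sessions, not broken. The calibration
experiments therefore draw i.i.d. binomial P at scheduler-realistic N_t
(the proper null of the *statistics*), where ANOVA and Tukey's
family-wise rate both sit within Monte-Carlo error of the nominal 0.05;
the vote-coupled rate is computed alongside as its own quantity.

## Problem sizes of the standing experiments

Chosen so a full evaluation remains in the minutes range on one CPU:
MTF oracle phantoms at 96³ with 4× rasterization; the 3×3 (noise, blur)
recovery grid at 72³ / 2 mm with 20 replicates per cell (180 phantoms);
statistical calibration with 1000 null sessions of 5 devices × 10
studies; ranking recovery over 20 sessions of 150 studies × 2000 votes;
the coupled-quality cohort at 15 devices × 3 studies, 72³. The full
reference-scale pipeline run (15 × 10 at 128³, 2000 votes) is the
default of the CLI and the analysis scripts.

## Known limitations

- Masks are consumed, not estimated; segmentation error on real data is
  out of scope and would propagate into every mask-based statistic.
- The MTF estimator assumes a locally planar, two-plateau edge; heavy
  cortical curvature at very coarse resolution, or blur well above the
  clean-plateau width, biases the plateau normalization low and the
  thresholds accordingly (rank orderings are far more robust than
  absolute values there).
- The aperture correction presumes an ideal box voxel; a scanner's true
  sampling aperture (k-space apodization, interpolation filters) differs,
  so absolute MTF values on real data inherit that model error.
- The QI detects artefact only above the robust background threshold;
  ghosting below ~3σ of the air noise is invisible to it by design.
- The observer model is unbiased and stationary; real raters drift, have
  criteria, and disagree — the multi-rater bias adjustment is carried in
  the schema but not implemented.
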