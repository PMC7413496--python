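# Methods

## The measurement model

A two-photon focal volume is treated as an anisotropic 3D Gaussian whose
lateral and axial full widths at half maximum (FWHM) are the quantities of
interest.  What a microscope records of a fluorescent bead is the bead
convolved with that focal volume; for 200-nm beads the bead's contribution
to the measured width is below 0.15% axially and a few percent laterally,
so measured widths are reported as *effective* widths without bead-size
deconvolution.  All analysis is 1D, matching common practice: a
single-voxel-wide profile through the bead peak along x gives the lateral
width and along z the axial width; profiles are never averaged over y.

The Gaussian-plus-offset model `A·exp(−(u−μ)²/2σ²) + b` is fitted by
unweighted nonlinear least squares (scipy `curve_fit`, moment-based
initial values, bounded σ ∈ [0.1·step, 5·span], 10⁴ evaluation cap).
`FWHM = 2√(2 ln 2)·σ`.  Two centre conventions exist because in vivo bead
images are blurred by heartbeat/breathing motion: `free_center` (μ free,
the in vitro protocol) and `fixed_center` (μ pinned to the centre pixel).
The mode is always explicit, never auto-selected.  A fit whose RMS
residual exceeds 20% of the fitted amplitude is flagged unreliable and
excluded from condition summaries; the minimum profile length is 7
samples.  Both thresholds are package choices.

### Peak refinement

Taking the profile through the raw intensity argmax biases fitted widths
low in two ways: shot noise inflates the selected centre sample, and with
per-plane lateral motion the argmax prefers a column where the motion
happened to align at one plane, which makes the axial profile decay
artificially fast.  Detection therefore runs on a 1-voxel-Gaussian
smoothed copy, and the measurement column is re-centred on the intensity
centroid of the axial sum projection (motion averages out in the
projection); the axial centre is the smoothed argmax of that column.
With this refinement the recovered mean axial FWHM is unbiased to within
about 1% under the default noise and jitter; without it the bias reaches
−3% to −7%.

## Condition presets and the RI-mismatch model

The shipped table `data/psf_presets.tsv` anchors mean effective widths for
two pupil-fill modes at depths of 100, 200 and 300 μm (water immersion);
intermediate depths interpolate linearly and extrapolation beyond the
anchors must be requested explicitly (`extrapolate=True`), because beads
become too dim to follow much past 300 μm and extrapolated values are a
guess.

The immersion-RI response is deliberately phenomenological: each axis of
the preset is multiplied by `1 + gain · depth · (n − n_opt)²` with
`n_opt = 1.355` (the midpoint of the RI range that minimises focal
volumes in cortical tissue).  The axial gain (1.6 μm⁻¹ RI⁻²) gives a 1.3×
axial inflation at |Δn| = 0.025 and 300 μm depth; the lateral gain is set
to one third of that, reflecting that spherical aberration elongates the
focus mostly axially.  These gains are simulator knobs, not physical
constants; no claim is made that modelled absolute widths at n ≠ 1.33
match any measurement.  When the *generator* needs ground truth for a
condition at arbitrary RI, the model is applied as a ratio relative to
the reference RI (1.33) at which the preset table was measured, so the
preset is reproduced exactly at the reference and widths contract toward
`n_opt`.

Pupil geometry uses the standard infinity-corrected relation
`D_pupil = 2·NA·f_tube/M` with `f_tube = 180 mm` (Olympus convention) by
default.

## The synthetic generators

**Bead stacks** default to 0.05 μm lateral pixels and 0.25 μm z-steps
(56×80×80 voxels, 14×4×4 μm), one bead per stack when used for
metrology so each fit is an independent sample.  Rendering treats the
requested PSF as the target effective width: sub-resolution beads
(≤ 0.4 μm) are anisotropic Gaussians at exactly the requested FWHMs,
while resolution-scale beads (e.g. 1.0 μm) are rendered by the exact
uniform-ball × Gaussian convolution, computed by slicing the ball into
disks (Gauss–Legendre quadrature along z) and using the closed form
disk ⊗ 2D-Gaussian = noncentral-χ² CDF.  A 1.0-μm bead therefore renders
axially wider than the nominal focal volume, as real microbead images do,
and such measurements are labelled "relative" in outputs.  Noise is
Poisson on expected photons (default peak 200, baseline 5) plus Gaussian
read noise (SD 2 counts), clipped at zero.  Motion is a rigid per-plane
lateral translation ~N(0, 0.05 μm) standing in for heartbeat and
breathing; bead-to-bead width scatter is multiplicative with 5% CV
(in vivo preparations show 5–15%).  Placement is rejection sampling with
10·n_beads retries and margins that keep every measurement window inside
the stack.

**Structure stacks** render randomly oriented ~1-μm filaments with 0.5-μm
spine-like stubs on a 21-plane grid (0.25/0.5 μm sampling), blurred by a
supplied PSF, with the blur-free reference returned alongside.  In the
quality pipeline each condition's brightness is scaled by the ratio of
the reference condition's effective focal volume (lateral² × axial) to
its own, emulating the inverse dependence of two-photon excitation
efficiency on focal volume; without this coupling the Brenner sums of
different conditions differ only through blur and are dominated by the
constant noise contribution.

**Calcium movies** place disjoint disk-shaped cells (2-px halo so
8-connectivity cannot merge neighbours) beside a dark vessel band
(default 15% of the frame), with transient events — one-frame rise, 3-
frame exponential decay — confined to contiguous within-cell regions
grown to an exact pixel count: true events 25–60 px, sub-threshold
distractors 10–20 px placed in the tissue between cells so they can never
merge with a true event.  Defaults: 96×96 frames, 60 frames at 1 s, 6
cells, 8 events/cell/100 frames, amplitude ΔF/F = 2 over a 50-count
baseline, Gaussian read noise SD 2.

What the generators do *not* emulate: optical sectioning physics and
scattering, depth-dependent attenuation inside one stack, non-rigid
motion, astrocyte morphology, bleaching, and vessel pulsation.  Passing
tests therefore demonstrate the correctness of the measurement chain and
its statistics, not robustness to every artifact of real recordings.

## Image-quality and activity conventions

"The k lowest pixels per plane" (k = 100) is the reading of the
background rule consistent with its pooled count (21 × 100 = 2100); ties
are broken by scan order, which cannot change the pooled mean.  The
Brenner gradient uses horizontal differences at step 2 and is reported as
a raw sum — consumers normalise explicitly, and the published contrast
quantity is a ratio between conditions, where any per-pixel normalisation
cancels.

ΔF is reported in raw counts (not ΔF/F).  Otsu binarization is applied
per frame (events are transient) with 256 bins over the frame's range,
ties resolved toward the lowest threshold; ROIs from different frames
merge when their pixel sets overlap, keeping the union and the earliest
frame.  "Larger than 20 pixels" is strict (area ≥ 21), 8-connectivity by
default; both are recorded in output metadata and configurable.  Two
degenerate-frame guards exist: a constant frame (Otsu undefined) is
skipped with a warning, and a frame whose Otsu foreground exceeds 30% of
the pixels is likewise skipped — Otsu applied to an activity-free noise
frame splits the noise distribution and floods the foreground, and no
sparse-activity interpretation survives that.  An explicit threshold
override bypasses Otsu entirely for calibration experiments.

A consequence of the minimum-projection baseline is a noise pedestal:
each pixel's ΔF carries ≈ +2.3 noise SD on average (the negative of the
expected minimum of ~60 noise samples).  The pedestal is common to both
conditions of a comparison, so a 4:1 planted amplitude ratio yields a
measured fold change of ≈ 3.6–3.7 rather than 4.0 at the default noise
level; this is a property of the method being modelled, not an estimator
defect.

## Statistics

Welch's t-test (unequal variances, Welch–Satterthwaite df, two-sided)
backs pairwise FWHM comparisons, Bonferroni-corrected within each
fill × depth family against the reference RI.  The Friedman statistic is
the tie-corrected chi-square over within-block ranks; an all-tied design
returns statistic 0, p = 1.  DSCF compares each pair with a two-sample
rank statistic computed on that pair alone (average ranks for ties,
tie-corrected variance), standardised and referred to the studentized
range with k groups and infinite df: `p = P(Q ≥ √2·|W*|)`.  The
studentized-range tail is computed in-package by numerical integration of
`1 − k∫φ(u)[Φ(u) − Φ(u−q)]^{k−1} du` (absolute tolerance 10⁻⁸) and
cross-checked against an independent implementation and, at k = 3, n = 4,
against exhaustive enumeration of the joint permutation null.  At such
small samples the asymptotic p is accurate to ~0.02 only for
well-separated data; mid-range p values can deviate by 0.1 from the exact
familywise null, a known small-sample property of the asymptotic
reference, so small-n DSCF p values should be read qualitatively.

## Numerical and design notes

- All randomness flows from one integer seed; per-stage and per-condition
  streams are spawned via `SeedSequence`, with the imaging condition
  folded into the entropy so different conditions draw independent bead
  populations under the same top-level seed.  Fixed seed ⇒ bit-identical
  outputs.
- Problem sizes in the test suite and acceptance script (single-bead
  stacks of 56×80×80 voxels; 15/11/12 beads per condition; 21-plane
  quality stacks; 60-frame movies) match the condition sample sizes the
  preset table was built from and keep a full run to a few minutes.
- Local-maximum detection uses a compact neighbourhood by default but
  should be given a neighbourhood covering one (elongated) bead image via
  `peak_window_um` when widths are large relative to the stack — a too
  small window surfaces duplicate maxima from a single noisy blob.
- TIFF I/O uses the ImageJ metadata dialect (`spacing` for the z-step,
  a `lateral_step_um` key for pixel size); physical steps must come from
  metadata or be given explicitly — there are no silent defaults, since a
  wrong step rescales every FWHM downstream.
- The printed beam-diameter pair (10.8 mm, 17.4 mm) is not mutually
  consistent with a single pupil percentage pair under the standard pupil
  relation; the geometry here reproduces 115.1% for 17.4 mm and yields
  71.4% for 10.8 mm.

## Known limitations

- The RI-mismatch response is quadratic by construction; real aberration
  growth with depth and mismatch is more complex and asymmetric.
- Expansion ratios and summaries assume enough reliable beads; a single
  bead yields a summary without an s.e.m.
- The ΔF pipeline targets sparse, transient events; dense or sustained
  activity breaks the per-frame Otsu assumption (the aggregate-projection
  mode is provided but secondary).
- Lateral FWHM of resolution-scale beads is dominated by the bead size
  and is only useful as a relative quantity.
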