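# Methods

## Problem and model

A micropillar trap array immobilizes monodisperse antibody-coated microbeads
(nominally 15 µm) one per trap; the assay readout is the mean fluorescence
of each bead.  Quantification must include *every* captured bead: if beads
are found by thresholding the fluorescence channel, dark and dim beads are
silently excluded and the per-bead mean is biased upward — most severely for
low-expression samples, where accuracy matters most.  The pipeline therefore
decouples identification from signal: beads are detected on the bright-field
channel, where their appearance (a high-contrast dark ring) is independent
of fluorescence, and only then are their coordinates transferred to the
fluorescence image for readout.

Coordinate convention, used everywhere: 0-based pixel indices, origin at the
image top-left, x rightward (columns), y downward (rows); positions are
`(x, y)` floats at sub-pixel precision.

## Array geometry

`ArrayLayout` models the trap grid: `n_rows` rows of `pillars_per_row`
pillars; a trap is the gap between adjacent pillars, so a row holds
`pillars_per_row − 1` beads and the reference 10 × 60 layout holds 590.
The published chip geometry gives pillar/trap counts but not pitches, so the
defaults are chosen so a 15 µm bead fits exactly one trap at a 20× objective:
trap pitch 25 µm, row pitch 40 µm, pillar diameter 10 µm, pixel size
0.65 µm/px (bead radius ≈ 11.5 px).  Only the pixel-space ratios matter to
the algorithms; all values are configurable.  Outlet interception pillars
(which give the physical chip its ~100% capture efficiency) are not modeled;
capture efficiency enters only as the `fill_fraction` of `random_occupancy`.

## Synthetic imaging

`render_pair` produces a matched bright-field/fluorescence pair plus exact
ground truth.  Both channels share identical geometry — the chip is imaged
in place — which is the assumption positional migration relies on, and which
the generator enforces by construction.

Bright-field: background level 30 000 (16-bit scale), pillars as mid-gray
anti-aliased disks (30% darkening), beads as dark rims (rim width
max(2 px, 0.18 r), darkening `ring_contrast` = 0.55) with a slightly dark
interior; the field is blurred by a Gaussian PSF (σ = 1 px default).

Fluorescence: background 8 000 plus one rendered disk per bead.  Per-bead
amplitudes follow a two-component mixture: `positive_fraction` of beads draw
a lognormal amplitude (mean `mean_signal` = 20 000, CV `signal_cv` = 0.25 by
default, truncated at zero by construction); the rest are exactly zero.  The
exact point mass at zero is deliberate — it is the case that makes
fluorescence-gated analysis biased.

**Photometric convention.**  A bead's amplitude is defined as its expected
ROI-mean signal: each bead's kernel (anti-aliased disk convolved with the
PSF) is normalized so that its mean over the bead's own pixel-footprint disk
(pixel centers within one radius of the true center) equals 1.  In the
noiseless limit a centered circular ROI therefore reads exactly
`background_level + amplitude`, for any blur width.  Without this
normalization the PSF leaks a radius-dependent few percent of the signal out
of the rim, and every downstream truth comparison would need a
blur-attenuation factor; defining amplitude photometrically keeps the
oracles exact and changes nothing about the detection problem.

Both channels receive the same acquisition noise: a zero-mean planar
background tilt of relative span `background_gradient` (default 0.05, random
direction per image) and pixelwise additive Gaussian noise
(`noise_sd` = 1500 ≈ 5% of the bright-field dynamic range).  Images are
quantized to uint16.  Not modeled (known limitations): Poisson shot noise,
Airy-disk PSF structure, vignetting beyond the planar tilt, spectral
cross-talk, debris/aggregates, and focus drift.  Passing tests on this
imagery therefore demonstrate the correctness of the algorithms under the
stated appearance model, not robustness to every real-microscope artifact;
the detection contract (boxes in, quantification out) is the part designed
to carry over unchanged, since real detections can be supplied as annotation
files.

`render_dilution_series` emulates a serial-dilution calibration: the mean
amplitude at concentration c follows a configurable response, by default
linear in log10(c) at 2 500 gray levels per decade from a zero floor — the
linear regime of a saturating binding curve over 10–10⁷ particles/µL, chosen
so the top of the series stays well below the 16-bit ceiling.  A blank
condition (occupied beads, zero specific signal — medium only) is always
rendered.  Per-pair seeds are spawned deterministically from the experiment
seed.

## Detection

The reference detector replaces a trained network with a classical,
fully-deterministic equivalent honoring the same contract:

1. standardize the image (zero mean, unit variance);
2. normalized cross-correlation against a synthetic dark-ring template of
   the configured radius (FFT-based, via scikit-image);
3. local maxima above `score_threshold`, separated by `min_separation_px`
   (default 1.5 radii), with sub-pixel refinement by a 1-D quadratic fit of
   the correlation peak along each axis;
4. square boxes of side 2 r centered on each peak, confidence
   `(ncc + 1)/2`, clipped to the frame;
5. greedy non-maximum suppression at IoU > 0.3, ties broken by (y, x).

`score_threshold` defaults to 0.7: bead peaks score ≈ 0.9 on this imagery
while local maxima of the correlation field on pure noise sit near 0.5
(correlation ≈ 0), so 0.5 would admit noise peaks on a blank image; 0.7
separates the two populations with wide margins on both sides.  The
threshold is per-source configuration — an external network's confidences
have different semantics and its operating point must be chosen by its user.

Detection reads only the bright-field image; the function signature does not
accept a fluorescence channel.  That interface restriction *is* the
unbiasedness guarantee.

## Positional migration and readout

Each box becomes its inscribed circle: center `(x + w/2, y + h/2)` plus an
optional rigid registration offset (identity by default), radius
`min(w, h)/2`.  "Mean grayscale within the round boundary" is implemented as
the full-disk mean: a pixel belongs to the ROI when its center lies within
one radius of the ROI center (no partial-area weighting; at r ≈ 11 px the
sub-pixel boundary contribution is immaterial, and the rule is exactly
checkable against a brute-force loop).  An annulus-only variant would also
be defensible reading of "round boundaries"; the disk was chosen because the
bead's fluorescence fills its footprint.  Pixels of a clipped circle outside
the frame are excluded and flagged; an ROI entirely outside the frame is
dropped with a logged warning, never silently.  No background subtraction
happens at this stage — raw means are reported, and background handling
belongs to the statistics layer.

`gated_quantify_pair` implements the biased counterfactual (discard beads
below a fluorescence gate) solely so the bias can be demonstrated and
regression-tested; it is not a production path.

## Statistics

Per-condition mean/SD/SEM pool per-bead intensities directly across images
(no per-image weighting); SD uses the n−1 denominator, and a single-bead
condition reports SD 0 with a degenerate flag.  The calibration is an
unweighted ordinary least squares of condition means against
log10(concentration) — the only plausible axis for a series spanning six
decades.  Blank statistics are computed over per-bead intensities pooled
across blank replicates, because per-bead variability is what a single-bead
platform actually measures.  LOD threshold = blank mean + 3 blank SD; LOD
concentration inverts the fitted line at the threshold.  When the slope is
non-positive or the threshold lies outside the fitted intensity range, the
LOD is reported as not determinable with a reason code
(`nonpositive_slope`, `below_fitted_range`, `above_fitted_range`);
`allow_extrapolation=True` yields the extrapolated value, flagged.  Under
the generator's defaults the synthetic blank SD is small (camera noise
averaged over ~380 ROI pixels plus the background tilt), so the simulated
LOD falls *below* the lowest simulated concentration and is reported as an
explicit extrapolation — a property of the idealized noise model, not of
the method.  Group comparison is descriptive (means with 95%
normal-approximation CIs and optional blank subtraction); no hypothesis
testing machinery is attached.

## Problem sizes and determinism

Unit tests run on reduced arrays (2–4 rows, 8–16 pillars) where a render
takes ~50 ms; the validation suite and `scripts/acceptance.py` use the full
590-trap layout for detection/unbiasedness and a 24-pair dilution series
(7 concentrations × 3 replicates + 3 blanks), sizes at which the whole
acceptance run completes in well under a minute.  Every random draw flows
from a single integer seed through `numpy` `SeedSequence` spawning; a fixed
seed reproduces images, CSVs and JSON byte-identically (no timestamps are
written), which the test suite asserts at the byte level across two full
CLI runs.
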