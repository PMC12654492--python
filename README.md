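# beadquant

Automated quantification for single-bead microarray immunoassays.

Bead-based fluorescence immunoassays read out one antibody-functionalized
microbead per trap of a micropillar array: a bright-field micrograph shows
every bead as a high-contrast dark ring, and a pixel-aligned fluorescence
micrograph carries the signal of interest.  Detecting beads on the
*fluorescence* channel is biased — dim and dark beads are missed, so the
per-bead mean is inflated, which matters exactly when target expression is
low.  `beadquant` implements the unbiased alternative:

1. **detect** every bead on the bright-field channel (template
   cross-correlation against a dark-ring model, peak extraction, greedy
   non-maximum suppression), yielding bounding boxes `(x, y, w, h)` with
   confidences;
2. **migrate** each box onto the fluorescence image and replace it with its
   inscribed circle;
3. **measure** the mean grayscale intensity over each circular ROI — every
   bead, including non-fluorescent ones;
4. **aggregate** per-condition statistics, fit the dilution calibration
   line, and compute the limit of detection.

External detector output (e.g. a trained network) can be substituted for the
built-in detector via normalized-bounding-box annotation files
(`class x_center y_center width height [confidence]`).

A synthetic image generator renders matched bright-field/fluorescence pairs
of a populated micropillar array with exact ground truth (bead centers,
radii, per-bead true signal), so the whole pipeline is testable end to end
without a microscope.

## The statistics

For a dilution series with concentrations $c_1 < \dots < c_k$ (particles/µL)
the per-condition mean bead intensities $\bar{y}_i$ are fit by ordinary least
squares on a log abscissa,

$$\bar{y} = a \cdot \log_{10} c + b,$$

and the limit of detection uses the standard blank rule: with blank mean
$\mu_B$ and standard deviation $\sigma_B$ over per-bead intensities pooled
across blank replicates,

$$y_{\mathrm{LOD}} = \mu_B + 3\sigma_B, \qquad
  c_{\mathrm{LOD}} = 10^{(y_{\mathrm{LOD}} - b)/a}.$$

If the slope is non-positive or the threshold falls outside the fitted
range, the LOD concentration is reported as not determinable with a reason
code; extrapolation must be requested explicitly and is flagged in the
result.

The reference trap array is 10 rows × 60 pillars; a trap is the gap between
adjacent pillars, so the array holds 59 beads per row, 590 in total.

## Worked example

```python
import numpy as np
from beadquant import *

layout = ArrayLayout(n_rows=4, pillars_per_row=16)      # 60 traps
optics = OpticsParams()
signal = SignalModel(positive_fraction=0.5)             # half the beads are dark
occ = random_occupancy(layout, fill_fraction=1.0, seed=8)
bf, fl, truth = render_pair(layout, occ, optics, signal, seed=8)

params = DetectionParams(template_radius_px=optics.bead_radius_px)
boxes = detect_beads(bf, params)
print(f"detected {len(boxes)} beads "
      f"(mean confidence {np.mean([b.confidence for b in boxes]):.3f})")

measurements = quantify_pair(bf, fl, params)
vals = np.array([m.mean_intensity for m in measurements])
print(f"all-bead mean intensity: {vals.mean():.1f} gray levels")
print(f"expected mixture mean:   {signal.background_level + 0.5*signal.mean_signal:.1f}")

gate = signal.background_level + signal.mean_signal / 2
gated = gated_quantify_pair(bf, fl, params, gate)
print(f"fluorescence-gated mean: "
      f"{np.mean([m.mean_intensity for m in gated]):.1f}  ({len(gated)} beads kept)")

result = run_dilution_experiment(
    layout, OpticsParams(noise_sd=300.0), SignalModel(signal_cv=0.1),
    concentrations=[10.0**k for k in range(1, 8)], replicates=3, seed=8,
    allow_extrapolation=True,
)
cal = result.calibration
print(f"calibration: slope {cal.slope:.0f} gray/decade, R^2 = {cal.r_squared:.4f}")
print(f"LOD threshold = blank mean + 3 SD = {cal.lod_threshold:.0f} gray levels")
print(f"LOD concentration = {cal.lod_concentration:.2f} particles/uL "
      f"(extrapolated: {cal.lod_extrapolated})")
```

Output:

```
detected 60 beads (mean confidence 0.895)
all-bead mean intensity: 17932.5 gray levels
expected mixture mean:   18000.0
fluorescence-gated mean: 27888.7  (30 beads kept)
calibration: slope 2461 gray/decade, R^2 = 0.9998
LOD threshold = blank mean + 3 SD = 8337 gray levels
LOD concentration = 1.27 particles/uL (extrapolated: True)
```

All 60 beads are found with sub-pixel accuracy on the bright-field channel
alone.  The all-bead mean (17933) agrees with the true mixture mean (18000:
background 8000 plus half the beads at 20000 signal) within sampling error,
while gating on fluorescence keeps only the 30 bright beads and inflates the
mean by ~55%.  The dilution fit recovers the programmed response slope
(2500 gray levels per decade) within 2% at R² > 0.999; the LOD falls below
the lowest simulated concentration, so it is reported as an explicit
extrapolation.

## Command line

```bash
beadquant simulate  --config config.yaml --out sim/ --series   # render + manifest
beadquant detect    --image sim/pair_bright_field.tiff --out boxes.txt
beadquant quantify  --bright-field bf.tiff --fluorescence fl.tiff --out beads.csv
beadquant calibrate --manifest sim/manifest.csv --measurements meas/ --out cal.json
```

`quantify --detections boxes.txt` substitutes external detector output;
`--gate-threshold` enables the (biased) fluorescence-gated counterfactual
for demonstration.  Exit codes: 0 success, 1 validation error, 2 I/O error.
Every output is stamped with the configuration hash and package version.

## Layout

- `beadquant.geometry` — trap-array model, trap positions, occupancy
- `beadquant.simulate` — synthetic image pairs, ground truth, dilution series
- `beadquant.detect` — bright-field detector, NMS, IoU, annotation I/O
- `beadquant.migrate` — box→circle migration, disk-mean intensity, pair quantification
- `beadquant.stats` — condition summaries, calibration fit, LOD, comparisons
- `beadquant.cli` — `simulate` / `detect` / `quantify` / `calibrate` commands

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
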