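"""Synthetic micropillar-array micrograph generator with exact ground truth.

Renders matched bright-field / fluorescence image pairs of a bead-loaded
micropillar array so that every downstream stage (detection, positional
migration, intensity readout, calibration) can be exercised and validated
without a microscope.

Appearance model
----------------
Bright-field: bright background, pillars as mid-gray anti-aliased disks at the
layout's pillar positions, and each trapped bead as a dark rim (annulus) with
a slightly darkened interior — the high-contrast ring appearance transmitted
light gives a transparent sphere.  The whole field is blurred by a Gaussian
PSF, then a planar background gradient and pixelwise Gaussian noise are added.

Fluorescence: flat background (plus the same planar gradient) with one blurred
disk per bead.  Per-bead amplitudes follow a two-component mixture: a fraction
``positive_fraction`` of beads draw a lognormal amplitude with mean
``mean_signal`` and coefficient of variation ``signal_cv``; the rest carry
exactly zero signal.  The point mass at zero is the scenario in which
fluorescence-gated analysis is biased and bright-field-based detection is not.

Photometric convention: a bead's *amplitude* is its expected ROI-mean signal.
Each bead's rendered kernel (anti-aliased disk convolved with the PSF) is
normalized so that the mean over the bead's own pixel-footprint disk equals
the drawn amplitude exactly.  In the noiseless limit a perfectly centered
circular ROI therefore reads ``background_level + amplitude`` for any blur.

Both channels share identical geometry (the chip is not moved between
exposures), which is the assumption the positional-migration step relies on.
Images are 16-bit grayscale; all arithmetic is floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ImageSizeError, ValidationError
from .geometry import ArrayLayout, OccupancyMap, pillar_positions, trap_positions, random_occupancy

__all__ = [
    "OpticsParams",
    "SignalModel",
    "GroundTruth",
    "SimulatedPair",
    "LogLinearResponse",
    "render_pair",
    "write_ground_truth",
    "render_dilution_series",
    "default_image_shape",
]

DTYPE_MAX = 65535.0  # 16-bit grayscale

# fixed bright-field styling (relative to background level)
_PILLAR_CONTRAST = 0.30
_INTERIOR_CONTRAST = 0.25  # bead interior darkening as a fraction of ring_contrast


@dataclass(frozen=True)
class OpticsParams:
    """Acquisition model shared by both channels.

    ``noise_sd`` and the background levels are in raw gray levels of the
    16-bit image; ``background_gradient`` is the maximum relative tilt of the
    background plane across the field (0 = flat).
    """

    bead_radius_px: float = 11.5
    ring_contrast: float = 0.55
    blur_sigma_px: float = 1.0
    bf_background_level: float = 30000.0
    noise_sd: float = 1500.0
    background_gradient: float = 0.05

    def __post_init__(self):
        if not self.bead_radius_px > 0:
            raise ValidationError(f"bead_radius_px must be > 0 (got {self.bead_radius_px})")
        if self.blur_sigma_px < 0:
            raise ValidationError(f"blur_sigma_px must be >= 0 (got {self.blur_sigma_px})")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0 (got {self.noise_sd})")
        if not (0.0 <= self.ring_contrast <= 1.0):
            raise ValidationError(f"ring_contrast must lie in [0, 1] (got {self.ring_contrast})")
        if not (0.0 <= self.background_gradient <= 1.0):
            raise ValidationError(
                f"background_gradient must lie in [0, 1] (got {self.background_gradient})"
            )
        if not (0 <= self.bf_background_level <= DTYPE_MAX):
            raise ValidationError(
                f"bf_background_level must lie in [0, {DTYPE_MAX:.0f}] "
                f"(got {self.bf_background_level})"
            )


@dataclass(frozen=True)
class SignalModel:
    """Per-bead fluorescence amplitude mixture.

    ``positive_fraction`` of the beads carry signal; amplitudes are lognormal
    with mean ``mean_signal`` (gray levels) and CV ``signal_cv``; the
    remaining beads carry exactly zero.  ``background_level`` is the
    fluorescence-channel background (gray levels).
    """

    positive_fraction: float = 1.0
    mean_signal: float = 20000.0
    signal_cv: float = 0.25
    background_level: float = 8000.0

    def __post_init__(self):
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValidationError(
                f"positive_fraction must lie in [0, 1] (got {self.positive_fraction})"
            )
        if self.mean_signal < 0:
            raise ValidationError(f"mean_signal must be >= 0 (got {self.mean_signal})")
        if self.signal_cv < 0:
            raise ValidationError(f"signal_cv must be >= 0 (got {self.signal_cv})")
        if not (0 <= self.background_level <= DTYPE_MAX):
            raise ValidationError(
                f"background_level must lie in [0, {DTYPE_MAX:.0f}] "
                f"(got {self.background_level})"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-bead truth for a rendered pair (the synthetic stand-in for
    manual bounding-box annotation)."""

    centers: np.ndarray  # (n_beads, 2) float (x, y) pixels
    radius_px: float
    true_signal: np.ndarray  # (n_beads,) gray levels, >= 0
    occupancy: OccupancyMap

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if centers.size == 0:
            centers = centers.reshape(0, 2)
        sig = np.asarray(self.true_signal, dtype=float)
        if centers.shape[0] != self.occupancy.n_occupied:
            raise ValidationError(
                f"one center per occupied trap required (got {centers.shape[0]} centers, "
                f"{self.occupancy.n_occupied} occupied traps)"
            )
        if sig.shape != (centers.shape[0],):
            raise ValidationError("true_signal length must equal the number of centers")
        if np.any(sig < 0):
            raise ValidationError("true_signal entries must be >= 0")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "true_signal", sig)

    @property
    def n_beads(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class SimulatedPair:
    """One labeled bright-field/fluorescence pair from a simulated experiment."""

    condition: str
    concentration: float  # particles/µL; 0.0 for the blank control
    replicate: int
    seed: int
    bright_field: np.ndarray
    fluorescence: np.ndarray
    ground_truth: GroundTruth


def _array_extent_px(layout: ArrayLayout) -> tuple[float, float]:
    """(width, height) of the pillar grid bounding box, in pixels."""
    w = (layout.pillars_per_row - 1) * layout.trap_pitch_px
    h = (layout.n_rows - 1) * layout.row_pitch_px
    return w, h


def _margin_px(layout: ArrayLayout, optics: OpticsParams) -> int:
    # margin covers two bead radii, the PSF tail and the pillar bodies
    return int(
        math.ceil(
            max(2 * optics.bead_radius_px, optics.bead_radius_px + layout.pillar_radius_px)
            + 3 * optics.blur_sigma_px
            + 2
        )
    )


def default_image_shape(layout: ArrayLayout, optics: OpticsParams) -> tuple[int, int]:
    """Smallest (height, width) that holds the full array with the default margin."""
    w, h = _array_extent_px(layout)
    m = _margin_px(layout, optics)
    return (int(math.ceil(h)) + 2 * m, int(math.ceil(w)) + 2 * m)


def _aa_disk(dist: np.ndarray, radius: float) -> np.ndarray:
    """Anti-aliased disk indicator: 1 inside, 0 outside, linear 1-px edge ramp."""
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _paint(canvas: np.ndarray, patch: np.ndarray, x0: int, y0: int, op) -> None:
    """Apply ``op(region, patch_crop)`` where the patch overlaps the canvas."""
    h, w = canvas.shape
    ph, pw = patch.shape
    ax0, ay0 = max(x0, 0), max(y0, 0)
    ax1, ay1 = min(x0 + pw, w), min(y0 + ph, h)
    if ax0 >= ax1 or ay0 >= ay1:
        return
    sub = canvas[ay0:ay1, ax0:ax1]
    sub[...] = op(sub, patch[ay0 - y0 : ay1 - y0, ax0 - x0 : ax1 - x0])


def _bead_patches(
    cx: float, cy: float, radius: float, sigma: float
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Bright-field ring profile and normalized fluorescence kernel for one bead.

    Returns ``(ring, kernel, x0, y0)`` where both patches share the top-left
    canvas coordinate ``(x0, y0)``.  ``kernel`` integrates the PSF and is
    scaled so its mean over the bead's pixel-footprint disk (pixel centers at
    distance <= radius from the true center) is exactly 1.
    """
    pad = int(math.ceil(radius + 3 * sigma + 2))
    x0, y0 = int(math.floor(cx)) - pad, int(math.floor(cy)) - pad
    n = 2 * pad + 1
    xs = np.arange(x0, x0 + n, dtype=float)
    ys = np.arange(y0, y0 + n, dtype=float)
    dist = np.hypot(xs[None, :] - cx, ys[:, None] - cy)

    rim_w = max(2.0, 0.18 * radius)
    outer = _aa_disk(dist, radius)
    inner = _aa_disk(dist, radius - rim_w)
    ring = (outer - inner) + _INTERIOR_CONTRAST * inner  # rim 1, interior fraction

    disk = outer.copy()
    if sigma > 0:
        disk = gaussian_filter(disk, sigma, mode="constant")
    footprint = dist <= radius  # pixel-center inclusion rule (matches measurement)
    m = disk[footprint].mean()
    if m <= 0:
        raise ValidationError("degenerate bead kernel; radius too small for the PSF")
    return ring, disk / m, x0, y0


def _gradient_plane(shape: tuple[int, int], strength: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean planar tilt with total relative span ``strength``, random direction."""
    h, w = shape
    theta = rng.uniform(0, 2 * np.pi)
    u = (np.arange(w) / max(w - 1, 1) - 0.5) * np.cos(theta)
    v = (np.arange(h) / max(h - 1, 1) - 0.5) * np.sin(theta)
    return strength * (u[None, :] + v[:, None])


def _draw_amplitudes(signal: SignalModel, n_beads: int, rng: np.random.Generator) -> np.ndarray:
    """Two-component mixture: exact count of positives, lognormal amplitudes."""
    amps = np.zeros(n_beads)
    n_pos = int(round(signal.positive_fraction * n_beads))
    if n_pos > 0 and signal.mean_signal > 0:
        pos_idx = rng.choice(n_beads, size=n_pos, replace=False)
        if signal.signal_cv > 0:
            s2 = math.log1p(signal.signal_cv**2)
            mu = math.log(signal.mean_signal) - s2 / 2
            amps[pos_idx] = rng.lognormal(mean=mu, sigma=math.sqrt(s2), size=n_pos)
        else:
            amps[pos_idx] = signal.mean_signal
    elif n_pos > 0:
        # mean_signal == 0: positives exist but carry no amplitude (blank condition)
        pass
    return amps


def render_pair(
    layout: ArrayLayout,
    occupancy: OccupancyMap,
    optics: OpticsParams,
    signal: SignalModel,
    seed: int,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render one matched bright-field/fluorescence pair with ground truth.

    Returns ``(bright_field, fluorescence, GroundTruth)``; images are uint16
    arrays of identical shape, pixel-aligned across channels.  A fixed seed
    reproduces the pair bit-identically.
    """
    min_shape = default_image_shape(layout, optics)
    if shape is None:
        shape = min_shape
    elif shape[0] < min_shape[0] or shape[1] < min_shape[1]:
        raise ImageSizeError(
            f"image shape {shape} too small for the layout; requires at least "
            f"{min_shape[0]} x {min_shape[1]} (rows x cols)"
        )
    h, w = shape
    m = _margin_px(layout, optics)
    origin = (float(m), float(m))

    rng = np.random.default_rng(seed)
    traps = trap_positions(layout, origin)
    pillars = pillar_positions(layout, origin)
    centers = traps[occupancy.occupied]
    n_beads = centers.shape[0]
    amps = _draw_amplitudes(signal, n_beads, rng)

    # --- bright-field: multiplicative attenuation on a bright background ---
    atten = np.ones(shape)
    pr = layout.pillar_radius_px
    ppad = int(math.ceil(pr + 2))
    for px, py in pillars:
        x0, y0 = int(math.floor(px)) - ppad, int(math.floor(py)) - ppad
        n = 2 * ppad + 1
        xs = np.arange(x0, x0 + n, dtype=float)
        ys = np.arange(y0, y0 + n, dtype=float)
        dist = np.hypot(xs[None, :] - px, ys[:, None] - py)
        disk = _aa_disk(dist, pr)
        _paint(atten, _PILLAR_CONTRAST * disk, x0, y0, lambda s, p: s * (1.0 - p))

    fluor_signal = np.zeros(shape)
    for (cx, cy), amp in zip(centers, amps):
        ring, kernel, x0, y0 = _bead_patches(cx, cy, optics.bead_radius_px, optics.blur_sigma_px)
        _paint(atten, optics.ring_contrast * ring, x0, y0, lambda s, p: s * (1.0 - p))
        if amp > 0:
            _paint(fluor_signal, amp * kernel, x0, y0, lambda s, p: s + p)

    bf = optics.bf_background_level * atten
    if optics.blur_sigma_px > 0:
        bf = gaussian_filter(bf, optics.blur_sigma_px, mode="nearest")

    grad = _gradient_plane(shape, optics.background_gradient, rng)
    bf = bf + optics.bf_background_level * grad
    fl = signal.background_level * (1.0 + grad) + fluor_signal

    if optics.noise_sd > 0:
        bf = bf + rng.normal(0.0, optics.noise_sd, shape)
        fl = fl + rng.normal(0.0, optics.noise_sd, shape)

    bf16 = np.clip(np.rint(bf), 0, DTYPE_MAX).astype(np.uint16)
    fl16 = np.clip(np.rint(fl), 0, DTYPE_MAX).astype(np.uint16)
    gt = GroundTruth(
        centers=centers,
        radius_px=optics.bead_radius_px,
        true_signal=amps,
        occupancy=occupancy,
    )
    return bf16, fl16, gt


def write_ground_truth(gt: GroundTruth, image_shape: tuple[int, int], path) -> None:
    """Write ground truth as normalized bounding-box annotation text.

    One line per bead: ``class x_center y_center width height`` with the four
    geometry values normalized to [0, 1] by image width/height; class 0 =
    bead.  Round-trips with :func:`beadquant.detect.read_detections`.
    """
    h, w = image_shape
    r = gt.radius_px
    lines = []
    for cx, cy in gt.centers:
        if cx - r < 0 or cy - r < 0 or cx + r > w or cy + r > h:
            raise ValidationError(
                f"bead at ({cx:.1f}, {cy:.1f}) with radius {r:.1f} extends out of frame"
            )
        lines.append(f"0 {cx / w:.6f} {cy / h:.6f} {2 * r / w:.6f} {2 * r / h:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


@dataclass(frozen=True)
class LogLinearResponse:
    """Dose-response: amplitude linear in log10(concentration), clipped.

    ``amplitude(c) = clip(slope_per_decade * (log10(c) - log10_c0), floor, ceiling)``.
    The defaults give a response that is strictly linear over the 10–10^7
    particles/µL dilution range without reaching the camera ceiling.
    """

    slope_per_decade: float = 2500.0
    log10_c0: float = 0.0
    floor: float = 0.0
    ceiling: float = 60000.0

    def __call__(self, concentration: float) -> float:
        a = self.slope_per_decade * (math.log10(concentration) - self.log10_c0)
        return float(np.clip(a, self.floor, self.ceiling))


def render_dilution_series(
    layout: ArrayLayout,
    optics: OpticsParams,
    base_signal: SignalModel,
    concentrations,
    response=None,
    replicates: int = 3,
    seed: int = 0,
    fill_fraction: float = 1.0,
) -> list[SimulatedPair]:
    """Simulate a serial-dilution experiment, blank control included.

    For each concentration the mean per-bead amplitude follows ``response``
    (default :class:`LogLinearResponse`); the blank condition (label ``0``)
    is always rendered first with zero specific signal, sharing the same bead
    occupancy statistics.  Per-pair seeds derive deterministically from
    ``seed`` and the (condition, replicate) index.
    """
    conc = [float(c) for c in concentrations]
    if any(c <= 0 for c in conc):
        raise ValidationError(f"concentrations must be strictly positive (got {conc})")
    if conc != sorted(conc) or len(set(conc)) != len(conc):
        raise ValidationError(f"concentrations must be strictly increasing (got {conc})")
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1 (got {replicates})")
    if response is None:
        response = LogLinearResponse()

    pairs: list[SimulatedPair] = []
    conditions = [("blank", 0.0, 0.0)] + [
        (f"c{i + 1}", c, response(c)) for i, c in enumerate(conc)
    ]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(conditions) * replicates)
    k = 0
    for label, c, amp in conditions:
        for rep in range(replicates):
            occ_seed, pair_seed = (int(s % (2**31)) for s in children[k].generate_state(2))
            k += 1
            occ = random_occupancy(layout, fill_fraction, occ_seed)
            sig = replace(base_signal, mean_signal=amp, positive_fraction=1.0 if amp > 0 else 0.0)
            bf, fl, gt = render_pair(layout, occ, optics, sig, seed=pair_seed)
            pairs.append(
                SimulatedPair(
                    condition=label,
                    concentration=c,
                    replicate=rep,
                    seed=pair_seed,
                    bright_field=bf,
                    fluorescence=fl,
                    ground_truth=gt,
                )
            )
    return pairs
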