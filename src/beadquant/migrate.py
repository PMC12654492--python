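"""Positional migration of bright-field boxes onto the fluorescence channel.

The quantification step of the workflow: every bead box found in bright-field
is transferred ("migrated") to the pixel-aligned fluorescence image, replaced
by its inscribed circle, and the mean grayscale intensity inside that round
boundary is computed.  Because detection never looks at fluorescence, beads
with zero signal are measured like any other — the property that removes the
bias a fluorescence-gated analysis would introduce.  The gated counterfactual
is provided explicitly (:func:`gated_quantify_pair`) so the bias can be
demonstrated and tested.

No background subtraction happens here; raw means are reported and background
handling is deferred to the statistics layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import BeadBox, DetectionParams, detect_beads
from .errors import ImageSizeError, MeasurementError, ValidationError

__all__ = [
    "CircularROI",
    "BeadMeasurement",
    "Registration",
    "migrate",
    "measure_intensity",
    "quantify_pair",
    "gated_quantify_pair",
    "measurements_to_dataframe",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Registration:
    """Rigid translation between channels, in pixels.  Identity by default:
    the chip is imaged in place, so the channels are pixel-aligned."""

    dx: float = 0.0
    dy: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.dx) and np.isfinite(self.dy)):
            raise ValidationError(f"registration offsets must be finite (got {self.dx}, {self.dy})")


@dataclass(frozen=True)
class CircularROI:
    """Circular readout region for one bead on the fluorescence channel."""

    cx: float
    cy: float
    r: float
    bead_id: int = 0

    def __post_init__(self):
        if not self.r > 0:
            raise ValidationError(f"ROI radius must be > 0 (got {self.r})")


@dataclass(frozen=True)
class BeadMeasurement:
    bead_id: int
    roi: CircularROI
    mean_intensity: float
    n_pixels: int
    clipped: bool = False


def migrate(
    boxes: list[BeadBox],
    registration: Registration = Registration(),
    image_shape: tuple[int, int] | None = None,
) -> list[CircularROI]:
    """Convert bead boxes to circular ROIs on the fluorescence channel.

    Each ROI is the circle inscribed in its box (radius = min(w, h)/2),
    centered at the box center shifted by the registration offset.  Order and
    identity are preserved (``bead_id`` = index of the box in the input).
    ROIs that fall entirely outside ``image_shape`` are dropped and logged,
    never silently discarded.
    """
    rois: list[CircularROI] = []
    for i, b in enumerate(boxes):
        cx = b.x + b.w / 2.0 + registration.dx
        cy = b.y + b.h / 2.0 + registration.dy
        r = min(b.w, b.h) / 2.0
        if image_shape is not None:
            h, w = image_shape
            if cx + r < 0 or cy + r < 0 or cx - r > w - 1 or cy - r > h - 1:
                logger.warning(
                    "dropping bead %d: migrated ROI center (%.1f, %.1f) r=%.1f is outside "
                    "the %dx%d fluorescence frame", i, cx, cy, r, w, h,
                )
                continue
        rois.append(CircularROI(cx=cx, cy=cy, r=r, bead_id=i))
    return rois


def measure_intensity(fluorescence: np.ndarray, roi: CircularROI) -> BeadMeasurement:
    """Mean grayscale intensity within a bead's round boundary.

    A pixel ``(ix, iy)`` belongs to the ROI when ``(ix - cx)^2 + (iy - cy)^2
    <= r^2`` (pixel-center rule, no partial-area weighting).  In-circle pixels
    outside the frame are excluded from the mean and flagged via ``clipped``.
    """
    img = np.asarray(fluorescence)
    if img.ndim != 2:
        raise ImageSizeError(f"fluorescence image must be single-channel 2-D (got ndim={img.ndim})")
    h, w = img.shape
    cx, cy, r = roi.cx, roi.cy, roi.r

    ix = np.arange(int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1)
    iy = np.arange(int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1)
    in_circle = (ix[None, :] - cx) ** 2 + (iy[:, None] - cy) ** 2 <= r * r
    in_frame = (
        (ix[None, :] >= 0) & (ix[None, :] < w) & (iy[:, None] >= 0) & (iy[:, None] < h)
    )
    usable = in_circle & in_frame
    n = int(usable.sum())
    if n == 0:
        raise MeasurementError(
            f"no pixel inside ROI (cx={cx}, cy={cy}, r={r}) lies within the image"
        )
    yy, xx = np.nonzero(usable)
    mean = float(img[iy[yy], ix[xx]].astype(float).mean())
    clipped = bool((in_circle & ~in_frame).any())
    return BeadMeasurement(
        bead_id=roi.bead_id, roi=roi, mean_intensity=mean, n_pixels=n, clipped=clipped
    )


def quantify_pair(
    bright_field: np.ndarray,
    fluorescence: np.ndarray,
    detection_params: DetectionParams = DetectionParams(),
    registration: Registration = Registration(),
    image_id: str = "",
    boxes: list[BeadBox] | None = None,
) -> list[BeadMeasurement]:
    """Full per-pair quantification: detect -> migrate -> measure.

    Beads are detected on the bright-field channel (or taken from ``boxes``
    when an external detector's output is supplied), their boxes migrated to
    the fluorescence channel, and each bead's disk-mean intensity measured.
    Every retained bead is measured, including non-fluorescent ones.
    """
    bf = np.asarray(bright_field)
    fl = np.asarray(fluorescence)
    if bf.shape != fl.shape:
        raise ImageSizeError(
            f"bright-field {bf.shape} and fluorescence {fl.shape} shapes differ"
        )
    if boxes is None:
        boxes = detect_beads(bf, detection_params, image_id=image_id)
    rois = migrate(boxes, registration, image_shape=fl.shape)
    measurements = []
    for roi in rois:
        try:
            measurements.append(measure_intensity(fl, roi))
        except MeasurementError:
            logger.warning("dropping bead %d: ROI has no measurable pixel", roi.bead_id)
    return measurements


def gated_quantify_pair(
    bright_field: np.ndarray,
    fluorescence: np.ndarray,
    detection_params: DetectionParams = DetectionParams(),
    gate_threshold: float = 0.0,
    registration: Registration = Registration(),
    image_id: str = "",
    boxes: list[BeadBox] | None = None,
) -> list[BeadMeasurement]:
    """Biased counterfactual: measure only beads above a fluorescence gate.

    Identical to :func:`quantify_pair` but discards beads whose mean
    intensity falls below ``gate_threshold`` — the selection a
    fluorescence-only detector would apply implicitly.  Exists to demonstrate
    and test the resulting upward bias; not for production quantification.
    """
    all_measurements = quantify_pair(
        bright_field, fluorescence, detection_params, registration, image_id, boxes
    )
    return [m for m in all_measurements if m.mean_intensity >= gate_threshold]


def measurements_to_dataframe(
    measurements: list[BeadMeasurement], image_id: str = ""
) -> pd.DataFrame:
    """Measurement table: image_id, bead_id, cx, cy, r, n_pixels, mean_intensity, clipped."""
    return pd.DataFrame(
        [
            {
                "image_id": image_id,
                "bead_id": m.bead_id,
                "cx": m.roi.cx,
                "cy": m.roi.cy,
                "r": m.roi.r,
                "n_pixels": m.n_pixels,
                "mean_intensity": m.mean_intensity,
                "clipped": m.clipped,
            }
            for m in measurements
        ],
        columns=["image_id", "bead_id", "cx", "cy", "r", "n_pixels", "mean_intensity", "clipped"],
    )
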