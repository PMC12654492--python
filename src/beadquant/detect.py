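"""Bright-field bead detection and detection-file I/O.

Beads are located on the *bright-field* channel only — never the fluorescence
channel — so that zero-signal beads are found exactly as reliably as bright
ones.  The reference detector is classical: normalized cross-correlation
against a synthetic dark-ring template, local-maximum extraction, and greedy
non-maximum suppression.  Predictions from an external detector (e.g. a
trained network) can be slotted in through :func:`read_detections`, which
reads the normalized center-format annotation dialect
(``class x_center y_center width height [confidence]``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import match_template, peak_local_max

from .errors import ImageSizeError, ParseError, ValidationError

__all__ = [
    "BeadBox",
    "DetectionParams",
    "detect_beads",
    "nms",
    "iou",
    "read_detections",
    "write_detections",
    "boxes_to_dataframe",
]


@dataclass(frozen=True)
class BeadBox:
    """Axis-aligned bounding box of one detected bead.

    ``(x, y)`` is the top-left corner in 0-based pixel coordinates; the box
    covers the half-open region ``[x, x+w) x [y, y+h)``.
    """

    x: float
    y: float
    w: float
    h: float
    confidence: float = 1.0
    image_id: str = ""

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"box width/height must be > 0 (got w={self.w}, h={self.h})")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence must lie in [0, 1] (got {self.confidence})")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class DetectionParams:
    """Operating point of the reference template-correlation detector.

    ``score_threshold`` applies to the confidence score ``(ncc + 1) / 2``;
    the default 0.7 keeps bead peaks (score ~0.9 on the synthetic imagery)
    while rejecting correlation noise (score ~0.5) and pillar responses.
    ``min_separation_px`` defaults to 1.5x the template radius.
    """

    template_radius_px: float = 11.5
    score_threshold: float = 0.7
    nms_iou_threshold: float = 0.3
    min_separation_px: float | None = None

    def __post_init__(self):
        if self.template_radius_px <= 0:
            raise ValidationError(
                f"template_radius_px must be > 0 (got {self.template_radius_px})"
            )
        for name in ("score_threshold", "nms_iou_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1] (got {v})")
        if self.min_separation_px is None:
            object.__setattr__(self, "min_separation_px", 1.5 * self.template_radius_px)
        elif self.min_separation_px <= 0:
            raise ValidationError(f"min_separation_px must be > 0 (got {self.min_separation_px})")


def iou(a: BeadBox, b: BeadBox) -> float:
    """Intersection-over-union of two boxes (half-open pixel intervals)."""
    ix = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    iy = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _rank_key(box: BeadBox):
    # confidence descending, ties by (y, x) ascending
    return (-box.confidence, box.y, box.x)


def nms(boxes: list[BeadBox], iou_threshold: float) -> list[BeadBox]:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-confidence remaining box (ties broken by
    (y, x) ascending) and removes every box overlapping it with
    IoU > ``iou_threshold``.  Output order is the kept order.
    """
    if len({b.image_id for b in boxes}) > 1:
        raise ValidationError("nms requires boxes from a single image_id")
    remaining = sorted(boxes, key=_rank_key)
    kept: list[BeadBox] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining if iou(best, b) <= iou_threshold]
    return kept


def _ring_template(radius: float, blur_sigma: float = 1.0) -> np.ndarray:
    """Synthetic dark-ring bead template: dark rim, slightly dark interior,
    neutral surround — mirrors the bright-field appearance of a trapped bead."""
    pad = int(math.ceil(radius + 3))
    n = 2 * pad + 1
    ax = np.arange(n, dtype=float) - pad
    dist = np.hypot(ax[None, :], ax[:, None])
    rim_w = max(2.0, 0.18 * radius)
    outer = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    inner = np.clip(radius - rim_w + 0.5 - dist, 0.0, 1.0)
    tpl = -1.0 * (outer - inner) - 0.25 * inner
    if blur_sigma > 0:
        tpl = gaussian_filter(tpl, blur_sigma, mode="constant")
    return tpl


def _refine_peak(corr: np.ndarray, py: int, px: int) -> tuple[float, float]:
    """Sub-pixel peak via 1D quadratic fits along each axis."""

    def offset(m1, c, p1):
        denom = m1 - 2 * c + p1
        if denom >= 0:  # not a proper local max; keep integer location
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    h, w = corr.shape
    dx = offset(corr[py, px - 1], corr[py, px], corr[py, px + 1]) if 0 < px < w - 1 else 0.0
    dy = offset(corr[py - 1, px], corr[py, px], corr[py + 1, px]) if 0 < py < h - 1 else 0.0
    return px + dx, py + dy


def detect_beads(
    bright_field: np.ndarray, params: DetectionParams, image_id: str = ""
) -> list[BeadBox]:
    """Detect beads in a single-channel bright-field image.

    Pipeline: standardize the image to zero mean / unit variance; correlate
    with a dark-ring template of ``template_radius_px`` (normalized
    cross-correlation); take local maxima above ``score_threshold`` separated
    by at least ``min_separation_px``; emit square boxes of side
    ``2 * template_radius_px`` centered on each (sub-pixel refined) maximum
    with confidence ``(ncc + 1) / 2``; apply greedy NMS.  Output is sorted by
    confidence descending, ties by (y, x) ascending.
    """
    img = np.asarray(bright_field)
    if img.ndim != 2:
        raise ImageSizeError(f"bright-field image must be single-channel 2-D (got ndim={img.ndim})")
    if params.template_radius_px < 2:
        raise ValidationError("template_radius_px must be >= 2 for detection")
    tpl = _ring_template(params.template_radius_px)
    if tpl.shape[0] > img.shape[0] or tpl.shape[1] > img.shape[1]:
        raise ImageSizeError(
            f"template {tpl.shape} larger than image {img.shape}; radius too large"
        )

    img = img.astype(float)
    sd = img.std()
    if sd == 0:
        return []
    img = (img - img.mean()) / sd

    corr = match_template(img, tpl, pad_input=True)  # peak at template center
    corr_threshold = 2.0 * params.score_threshold - 1.0
    peaks = peak_local_max(
        corr,
        min_distance=max(1, int(round(params.min_separation_px))),
        threshold_abs=corr_threshold,
        exclude_border=False,
    )

    r = params.template_radius_px
    side = 2.0 * r
    h, w = img.shape
    boxes = []
    for py, px in peaks:
        conf = float(np.clip((corr[py, px] + 1.0) / 2.0, 0.0, 1.0))
        cx, cy = _refine_peak(corr, py, px)
        x0, y0 = cx - r, cy - r
        # clip to image bounds
        x1, y1 = min(x0 + side, float(w)), min(y0 + side, float(h))
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            continue
        boxes.append(
            BeadBox(x=x0, y=y0, w=x1 - x0, h=y1 - y0, confidence=conf, image_id=image_id)
        )
    boxes.sort(key=_rank_key)
    return nms(boxes, params.nms_iou_threshold)


def read_detections(path, image_shape: tuple[int, int], image_id: str = "") -> list[BeadBox]:
    """Read normalized center-format detections/annotations into pixel boxes.

    Each non-empty line is ``class x_center y_center width height
    [confidence]`` with all five trailing values in [0, 1]; a missing
    confidence defaults to 1.0.  Inverse of :func:`write_detections`.
    """
    h, w = image_shape
    boxes: list[BeadBox] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) not in (5, 6):
                raise ParseError(
                    f"expected 5 or 6 whitespace-separated fields, got {len(fields)}", lineno
                )
            try:
                int(fields[0])
                vals = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"non-numeric field ({exc})", lineno) from None
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ParseError(
                    f"normalized values must lie in [0, 1] (got {vals})", lineno
                )
            xc, yc, bw, bh = vals[0] * w, vals[1] * h, vals[2] * w, vals[3] * h
            conf = vals[4] if len(vals) == 5 else 1.0
            boxes.append(
                BeadBox(x=xc - bw / 2, y=yc - bh / 2, w=bw, h=bh, confidence=conf, image_id=image_id)
            )
    return boxes


def write_detections(
    boxes: list[BeadBox], image_shape: tuple[int, int], path, with_confidence: bool = True
) -> None:
    """Write boxes in normalized center format (class 0 = bead)."""
    h, w = image_shape
    lines = []
    for b in boxes:
        xc, yc = b.center
        vals = [xc / w, yc / h, b.w / w, b.h / h]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValidationError(f"box {b} does not normalize into [0, 1] for shape {image_shape}")
        line = "0 " + " ".join(f"{v:.6f}" for v in vals)
        if with_confidence:
            line += f" {b.confidence:.6f}"
        lines.append(line)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def boxes_to_dataframe(boxes: list[BeadBox]) -> pd.DataFrame:
    """Detection table with columns image_id, x, y, w, h, confidence."""
    return pd.DataFrame(
        [
            {"image_id": b.image_id, "x": b.x, "y": b.y, "w": b.w, "h": b.h,
             "confidence": b.confidence}
            for b in boxes
        ],
        columns=["image_id", "x", "y", "w", "h", "confidence"],
    )
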