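"""Geometric model of the micropillar trap array.

The analysis region of the chip is a regular grid of micropillars: ``n_rows``
parallel rows of ``pillars_per_row`` pillars each.  A *trap* is the gap between
two adjacent pillars within a row, sized so that exactly one monodisperse bead
(nominally 15 µm) is retained per trap; a row of ``P`` pillars therefore holds
``P - 1`` beads, and the reference layout (10 rows x 60 pillars) has a
theoretical capacity of 590 beads.

Coordinate convention (used package-wide): 0-based pixel indices, origin at
the image top-left, x rightward (columns), y downward (rows).  Positions are
``(x, y)`` pairs of floats at sub-pixel precision.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ValidationError

__all__ = ["ArrayLayout", "OccupancyMap", "trap_positions", "pillar_positions", "random_occupancy"]


@dataclass(frozen=True)
class ArrayLayout:
    """Micropillar trap-array geometry.

    Defaults describe the reference chip: 10 rows of 60 pillars (590 traps)
    holding 15 µm beads, imaged with a 20x objective (0.65 µm/pixel).  Pitches
    are configurable; only their ratios to the pixel size matter downstream.
    """

    n_rows: int = 10
    pillars_per_row: int = 60
    pillar_diameter_um: float = 10.0
    trap_pitch_um: float = 25.0
    row_pitch_um: float = 40.0
    bead_diameter_um: float = 15.0
    pixel_size_um: float = 0.65

    def __post_init__(self):
        if int(self.n_rows) != self.n_rows or self.n_rows < 1:
            raise ValidationError(f"n_rows must be an integer >= 1 (got {self.n_rows})")
        if int(self.pillars_per_row) != self.pillars_per_row or self.pillars_per_row < 2:
            raise ValidationError(
                f"pillars_per_row must be an integer >= 2 (got {self.pillars_per_row})"
            )
        for name in (
            "pillar_diameter_um",
            "trap_pitch_um",
            "row_pitch_um",
            "bead_diameter_um",
            "pixel_size_um",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be strictly positive (got {v})")
        if self.bead_diameter_um > self.trap_pitch_um:
            raise ValidationError(
                "bead_diameter_um must not exceed trap_pitch_um for single-bead trapping "
                f"(got bead {self.bead_diameter_um} > pitch {self.trap_pitch_um})"
            )

    @property
    def traps_per_row(self) -> int:
        return self.pillars_per_row - 1

    @property
    def total_traps(self) -> int:
        return self.n_rows * (self.pillars_per_row - 1)

    @property
    def trap_pitch_px(self) -> float:
        return self.trap_pitch_um / self.pixel_size_um

    @property
    def row_pitch_px(self) -> float:
        return self.row_pitch_um / self.pixel_size_um

    @property
    def bead_radius_px(self) -> float:
        return self.bead_diameter_um / 2.0 / self.pixel_size_um

    @property
    def pillar_radius_px(self) -> float:
        return self.pillar_diameter_um / 2.0 / self.pixel_size_um

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayLayout":
        return cls(**d)


@dataclass(frozen=True)
class OccupancyMap:
    """Per-trap bead occupancy, indexed (row, trap) in row-major order."""

    layout: ArrayLayout
    occupied: np.ndarray  # bool, shape (total_traps,)

    def __post_init__(self):
        occ = np.asarray(self.occupied, dtype=bool)
        if occ.shape != (self.layout.total_traps,):
            raise ValidationError(
                f"occupied must have length total_traps={self.layout.total_traps} "
                f"(got shape {occ.shape})"
            )
        object.__setattr__(self, "occupied", occ)

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())


def trap_positions(layout: ArrayLayout, origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Return all trap centers as an ``(total_traps, 2)`` array of ``(x, y)`` pixels.

    Traps are enumerated row-major: row 0 left-to-right, then row 1, ...  The
    trap between pillars ``j`` and ``j+1`` sits midway between their centers.
    ``origin`` is the pixel position of the first pillar of the first row.
    """
    xs = (np.arange(layout.traps_per_row) + 0.5) * layout.trap_pitch_px + origin[0]
    ys = np.arange(layout.n_rows) * layout.row_pitch_px + origin[1]
    gx, gy = np.meshgrid(xs, ys)  # rows x traps
    return np.column_stack([gx.ravel(), gy.ravel()])


def pillar_positions(layout: ArrayLayout, origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Pillar centers, ``(n_rows * pillars_per_row, 2)``, row-major ``(x, y)``."""
    xs = np.arange(layout.pillars_per_row) * layout.trap_pitch_px + origin[0]
    ys = np.arange(layout.n_rows) * layout.row_pitch_px + origin[1]
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def random_occupancy(
    layout: ArrayLayout, fill_fraction: float, seed: int | np.random.Generator
) -> OccupancyMap:
    """Occupy ``round(fill_fraction * total_traps)`` traps chosen uniformly.

    Reproducible for a fixed integer seed.
    """
    if not (0.0 <= fill_fraction <= 1.0):
        raise ValidationError(f"fill_fraction must lie in [0, 1] (got {fill_fraction})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = layout.total_traps
    n_occ = int(round(fill_fraction * n))
    occupied = np.zeros(n, dtype=bool)
    if n_occ > 0:
        occupied[rng.choice(n, size=n_occ, replace=False)] = True
    return OccupancyMap(layout=layout, occupied=occupied)
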