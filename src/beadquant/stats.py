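"""Assay statistics: condition summaries, dilution calibration, and LOD.

Per-bead disk-mean intensities are pooled per condition (no per-image
weighting), the dilution series is fit by ordinary least squares of condition
mean intensity against log10(concentration), and the limit of detection is
computed by the standard blank rule

    LOD threshold   = blank_mean + 3 * blank_sd
    LOD concentration = 10 ** ((threshold - intercept) / slope)

with blank statistics taken over per-bead intensities pooled across blank
replicates.  When the threshold falls outside the fitted range, or the slope
is non-positive, the LOD concentration is reported as not determinable with a
reason code instead of being extrapolated silently; extrapolation can be
requested explicitly and is then flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .migrate import BeadMeasurement

__all__ = [
    "ConditionSummary",
    "CalibrationResult",
    "summarize_condition",
    "fit_calibration",
    "compare_conditions",
    "plot_calibration",
]

BLANK_SD_MULTIPLIER = 3.0  # LOD threshold = blank mean + 3 SD


@dataclass(frozen=True)
class ConditionSummary:
    """Pooled per-bead intensity statistics for one assay condition."""

    condition: str
    concentration: float  # particles/µL; 0.0 denotes the blank control
    n_beads: int
    mean: float
    sd: float  # sample SD (n-1 denominator); 0 with sd_degenerate for n=1
    sem: float
    n_images: int = 1
    sd_degenerate: bool = False

    def __post_init__(self):
        if self.n_beads < 1:
            raise ValidationError(f"n_beads must be >= 1 (got {self.n_beads})")
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0 (got {self.sd})")


@dataclass(frozen=True)
class CalibrationResult:
    """Log-linear dilution calibration with blank-based LOD.

    ``slope`` is in gray levels per decade of concentration.  When
    ``lod_concentration`` is None, ``lod_reason`` explains why
    (``nonpositive_slope``, ``below_fitted_range`` or ``above_fitted_range``);
    ``lod_extrapolated`` marks a value obtained by explicit extrapolation
    beyond the fitted concentration range.
    """

    slope: float
    intercept: float
    r_squared: float
    blank_mean: float
    blank_sd: float
    lod_threshold: float
    lod_concentration: float | None
    concentrations_used: list[float] = field(default_factory=list)
    lod_reason: str | None = None
    lod_extrapolated: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_condition(
    measurements: list[BeadMeasurement],
    label: str,
    concentration: float = 0.0,
    n_images: int = 1,
) -> ConditionSummary:
    """Pool per-bead intensities of one condition into mean/SD/SEM.

    All beads are pooled directly (summarizing a concatenation of several
    images' measurements is identical to summarizing them jointly).  SD uses
    the n-1 denominator; a single-bead condition reports sd=0 with the
    ``sd_degenerate`` flag set.
    """
    if not measurements:
        raise ValidationError(f"condition {label!r}: no measurements to summarize")
    vals = np.array([m.mean_intensity for m in measurements], dtype=float)
    n = vals.size
    degenerate = n == 1
    sd = 0.0 if degenerate else float(vals.std(ddof=1))
    return ConditionSummary(
        condition=label,
        concentration=float(concentration),
        n_beads=n,
        mean=float(vals.mean()),
        sd=sd,
        sem=sd / math.sqrt(n),
        n_images=n_images,
        sd_degenerate=degenerate,
    )


def fit_calibration(
    summaries: list[ConditionSummary],
    blank: ConditionSummary,
    allow_extrapolation: bool = False,
) -> CalibrationResult:
    """Fit the dilution calibration line and derive the LOD.

    Ordinary least squares of condition mean intensity on
    log10(concentration) over the (unweighted) condition means; requires at
    least three non-blank concentrations, all strictly positive.
    """
    if len(summaries) < 3:
        raise ValidationError(
            f"calibration requires >= 3 non-blank concentrations (got {len(summaries)})"
        )
    conc = np.array([s.concentration for s in summaries], dtype=float)
    if np.any(conc <= 0):
        raise ValidationError(f"calibration concentrations must be > 0 (got {conc.tolist()})")
    x = np.log10(conc)
    y = np.array([s.mean for s in summaries], dtype=float)

    fit = sps.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    # guard against tiny negative round-off on perfectly collinear input
    r_squared = float(min(1.0, fit.rvalue**2))

    lod_threshold = blank.mean + BLANK_SD_MULTIPLIER * blank.sd
    lod_concentration: float | None = None
    reason: str | None = None
    extrapolated = False
    if slope <= 0:
        reason = "nonpositive_slope"
    else:
        lod_log = (lod_threshold - intercept) / slope
        if lod_log < x.min():
            reason = "below_fitted_range"
        elif lod_log > x.max():
            reason = "above_fitted_range"
        if reason is None:
            lod_concentration = 10.0**lod_log
        elif allow_extrapolation:
            lod_concentration = 10.0**lod_log
            extrapolated = True
            reason = None
    return CalibrationResult(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        blank_mean=blank.mean,
        blank_sd=blank.sd,
        lod_threshold=lod_threshold,
        lod_concentration=lod_concentration,
        concentrations_used=conc.tolist(),
        lod_reason=reason,
        lod_extrapolated=extrapolated,
    )


def compare_conditions(
    summaries: list[ConditionSummary], blank: ConditionSummary | None = None
) -> pd.DataFrame:
    """Descriptive per-condition report with 95% normal-approximation CIs.

    Conditions appear in input order; when a blank is supplied a
    background-subtracted mean column is added.  No hypothesis testing — the
    comparison is descriptive (bar-chart style means with error bars).
    """
    if len(summaries) < 2:
        raise ValidationError(f"need >= 2 conditions to compare (got {len(summaries)})")
    rows = []
    for s in summaries:
        half = 1.96 * s.sem
        row = {
            "condition": s.condition,
            "concentration": s.concentration,
            "n_beads": s.n_beads,
            "mean": s.mean,
            "sd": s.sd,
            "sem": s.sem,
            "ci_low": s.mean - half,
            "ci_high": s.mean + half,
        }
        if blank is not None:
            row["mean_minus_blank"] = s.mean - blank.mean
        rows.append(row)
    return pd.DataFrame(rows)


def plot_calibration(result: CalibrationResult, summaries: list[ConditionSummary], path) -> None:
    """Calibration line, condition means with SEM bars, and the LOD threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.log10([s.concentration for s in summaries])
    y = [s.mean for s in summaries]
    err = [s.sem for s in summaries]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(x, y, yerr=err, fmt="o", color="k", capsize=3, label="condition means")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.slope * xs + result.intercept, "b-", label="linear fit")
    ax.axhline(result.lod_threshold, color="r", ls="--", label="blank mean + 3 SD")
    if result.lod_concentration is not None:
        ax.axvline(np.log10(result.lod_concentration), color="r", ls=":", alpha=0.6)
    ax.set_xlabel("log10 concentration (particles/µL)")
    ax.set_ylabel("mean fluorescence intensity (gray levels)")
    ax.set_title(f"R² = {result.r_squared:.4f}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
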