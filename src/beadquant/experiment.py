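"""End-to-end simulated experiments: render, quantify, summarize, calibrate."""

from __future__ import annotations

from dataclasses import dataclass, field

from .detect import DetectionParams
from .geometry import ArrayLayout
from .migrate import BeadMeasurement, quantify_pair
from .simulate import (
    LogLinearResponse,
    OpticsParams,
    SignalModel,
    render_dilution_series,
)
from .stats import CalibrationResult, ConditionSummary, fit_calibration, summarize_condition

__all__ = ["DilutionExperimentResult", "run_dilution_experiment"]


@dataclass(frozen=True)
class DilutionExperimentResult:
    blank: ConditionSummary
    summaries: list[ConditionSummary]
    calibration: CalibrationResult
    measurements: dict[str, list[BeadMeasurement]] = field(default_factory=dict)


def run_dilution_experiment(
    layout: ArrayLayout,
    optics: OpticsParams,
    signal: SignalModel,
    concentrations,
    replicates: int = 3,
    seed: int = 0,
    detection_params: DetectionParams | None = None,
    response: LogLinearResponse | None = None,
    fill_fraction: float = 1.0,
    allow_extrapolation: bool = False,
) -> DilutionExperimentResult:
    """Simulate a full dilution series and run it through the pipeline.

    Per condition, per-bead intensities are pooled across replicates (blank
    replicates included), then the calibration line and LOD are fit.  The
    per-condition measurement lists are returned for inspection.
    """
    if detection_params is None:
        detection_params = DetectionParams(template_radius_px=optics.bead_radius_px)
    pairs = render_dilution_series(
        layout, optics, signal, concentrations,
        response=response, replicates=replicates, seed=seed, fill_fraction=fill_fraction,
    )
    by_condition: dict[str, list[BeadMeasurement]] = {}
    meta: dict[str, tuple[float, int]] = {}
    for p in pairs:
        ms = quantify_pair(
            p.bright_field, p.fluorescence, detection_params,
            image_id=f"{p.condition}_r{p.replicate}",
        )
        by_condition.setdefault(p.condition, []).extend(ms)
        conc, n_img = meta.get(p.condition, (p.concentration, 0))
        meta[p.condition] = (conc, n_img + 1)

    summaries = []
    blank = None
    for label, ms in by_condition.items():
        conc, n_img = meta[label]
        s = summarize_condition(ms, label, conc, n_images=n_img)
        if label == "blank":
            blank = s
        else:
            summaries.append(s)
    calibration = fit_calibration(summaries, blank, allow_extrapolation=allow_extrapolation)
    return DilutionExperimentResult(
        blank=blank, summaries=summaries, calibration=calibration, measurements=by_condition
    )
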