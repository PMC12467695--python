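"""Frame-by-frame video processing: quality gating and sequence aggregation.

Every frame of a sequence is processed independently (detection,
measurement, quality assessment); only frames passing all diagnostic
gates contribute to the per-sequence alpha aggregate. Gates mirror what a
sonographer checks on a Graf standard-plane image: both landmarks visible
with adequate confidence, iliac margin near-vertical, and clean line fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .detect import LOWER_LIMB, RIM, LandmarkDetection, detect_landmarks
from .geometry import (
    AlphaMeasurement,
    MeasureParams,
    MeasurementFailure,
    measure_alpha,
)
from .io import UltrasoundFrame

Detector = Callable[[UltrasoundFrame], list[LandmarkDetection]]


@dataclass(frozen=True)
class GateParams:
    """Diagnostic-quality gates (applied in order, reasons accumulated)."""

    min_confidence: float = 0.3  # per landmark
    max_inclination_deg: float = 5.0
    max_iliac_rms_px: float = 2.0
    max_roof_rms_px: float = 3.0


@dataclass(frozen=True)
class FrameQualityReport:
    frame_index: int
    detections_present: dict[str, bool]
    confidences: dict[str, float]
    inclination_deg: float | None
    iliac_rms_residual: float | None
    roof_rms_residual: float | None
    is_diagnostic: bool
    reject_reasons: tuple[str, ...]


def assess_frame(
    frame: UltrasoundFrame,
    detections: list[LandmarkDetection],
    measurement: AlphaMeasurement | MeasurementFailure,
    gates: GateParams = GateParams(),
    frame_index: int = 0,
) -> FrameQualityReport:
    """Apply the diagnostic gates to one frame's detections and measurement.

    Gate order: both-landmarks, per-landmark confidence, inclination,
    iliac/roof fit residuals. Reasons accumulate (no short-circuit among
    applicable gates); fit-dependent gates are skipped when the measurement
    itself failed. Every frame yields a report.
    """
    dets = {d.label: d for d in detections}
    present = {RIM: RIM in dets, LOWER_LIMB: LOWER_LIMB in dets}
    confidences = {label: dets[label].confidence for label in dets}
    reasons: list[str] = []

    for label in (RIM, LOWER_LIMB):
        if not present[label]:
            reasons.append(f"{label}_not_detected")
    for label in (RIM, LOWER_LIMB):
        if present[label] and dets[label].confidence < gates.min_confidence:
            reasons.append(f"low_confidence_{label}")

    inclination = iliac_rms = roof_rms = None
    if measurement.ok:
        inclination = measurement.inclination_deg
        iliac_rms = measurement.iliac_line.rms_residual
        roof_rms = measurement.roof_line.rms_residual
        if abs(inclination) > gates.max_inclination_deg:
            reasons.append("inclination_exceeded")
        if iliac_rms > gates.max_iliac_rms_px:
            reasons.append("iliac_residual_exceeded")
        if roof_rms > gates.max_roof_rms_px:
            reasons.append("roof_residual_exceeded")
    else:
        reasons.append(f"measurement_failed:{measurement.reason}")

    return FrameQualityReport(
        frame_index=frame_index,
        detections_present=present,
        confidences=confidences,
        inclination_deg=inclination,
        iliac_rms_residual=iliac_rms,
        roof_rms_residual=roof_rms,
        is_diagnostic=not reasons,
        reject_reasons=tuple(reasons),
    )


@dataclass
class SequenceResult:
    """Per-sequence aggregate over diagnostic-quality frames only."""

    measurements: list[AlphaMeasurement | MeasurementFailure]
    reports: list[FrameQualityReport]
    diagnostic_frame_indices: list[int]
    alpha_mean: float | None
    alpha_sd: float | None
    n_diagnostic: int

    def per_frame_rows(self) -> list[dict]:
        rows = []
        for m, rep in zip(self.measurements, self.reports):
            rows.append(
                {
                    "frame_index": rep.frame_index,
                    "alpha_deg": m.alpha_deg if m.ok else None,
                    "inclination_deg": m.inclination_deg if m.ok else None,
                    "is_diagnostic": rep.is_diagnostic,
                    "reject_reasons": ";".join(rep.reject_reasons),
                }
            )
        return rows


def run_sequence(
    frames: Sequence[UltrasoundFrame],
    detector: Detector = detect_landmarks,
    gates: GateParams = GateParams(),
    params: MeasureParams = MeasureParams(),
    mode: str = "dynamic",
) -> SequenceResult:
    """Process a frame sequence and aggregate diagnostic-quality frames.

    Frames are processed independently (no temporal smoothing). A sequence
    with zero diagnostic frames yields an explicit empty aggregate
    (mean/sd ``None``), never an exception.
    """
    if len(frames) < 1:
        raise ValueError("run_sequence needs at least one frame")
    measurements, reports = [], []
    for k, frame in enumerate(frames):
        detections = detector(frame)
        m = measure_alpha(frame, detections, mode=mode, params=params, frame_index=k)
        measurements.append(m)
        reports.append(assess_frame(frame, detections, m, gates, frame_index=k))

    diag = [k for k, rep in enumerate(reports) if rep.is_diagnostic and measurements[k].ok]
    alphas = np.array([measurements[k].alpha_deg for k in diag])
    if len(alphas) == 0:
        mean = sd = None
    else:
        mean = float(alphas.mean())
        sd = float(alphas.std(ddof=1)) if len(alphas) > 1 else 0.0
    return SequenceResult(
        measurements=measurements,
        reports=reports,
        diagnostic_frame_indices=diag,
        alpha_mean=mean,
        alpha_sd=sd,
        n_diagnostic=len(diag),
    )
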