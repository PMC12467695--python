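"""Anatomical landmark detection: acetabular rim and lower limb of ilium.

The downstream geometry only needs approximate bounding boxes for the two
Graf landmarks, so the detector is a pluggable contract: any callable
mapping a frame to at most one detection per label can stand in (e.g. a
learned single-shot detector). The reference implementation here is
classical and fully deterministic: it extracts the bone-surface ridge map,
follows the dominant near-vertical ridge chain (the iliac outer margin) to
its caudal terminus or first sharp direction change — the acetabular rim
(osseous beak) — and takes the screened ridge point farthest from the
iliac line on the medial side as the lower limb of the ilium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    PointSet,
    ScreenParams,
    extract_local_maxima,
    fit_line_tls,
    preprocess,
    ridge_chains,
    screen_peaks,
)
from .io import UltrasoundFrame

log = logging.getLogger(__name__)

RIM = "acetabular_rim"
LOWER_LIMB = "ilium_lower_limb"


@dataclass(frozen=True)
class LandmarkDetection:
    """A labelled landmark bounding box with a confidence score.

    The box is (row_min, col_min, row_max, col_max) in pixels, half-open on
    the max edges; confidence lies in [0, 1] and is monotone in the local
    ridge-to-background contrast.
    """

    label: str
    box: tuple[int, int, int, int]
    confidence: float

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        if not (r0 < r1 and c0 < c1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


def box_center(det: LandmarkDetection) -> tuple[float, float]:
    """Center of a detection box, the anchor for baseline construction."""
    r0, c0, r1, c1 = det.box
    return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


@dataclass(frozen=True)
class DetectorParams:
    box_size: int = 24
    confidence_floor: float = 0.1  # no detection emitted below this contrast
    min_separation_px: int = 5
    screen: ScreenParams = field(default_factory=ScreenParams)
    min_chain_rows: int = 15
    corner_tolerance_px: float = 1.5  # ridge deviation marking the rim corner
    min_limb_distance_px: float = 15.0  # lower limb must clear the iliac line


def detect_landmarks(
    frame: UltrasoundFrame, params: DetectorParams = DetectorParams()
) -> list[LandmarkDetection]:
    """Detect the two Graf landmarks on a frame (rim first, then lower limb).

    Returns at most one detection per label and an empty list — never a
    fabricated box — when no ridge candidate exceeds the contrast floor.
    Degenerate frames (non-grayscale, all-constant) yield an empty result
    with a logged warning rather than an exception.
    """
    if frame.pixels.ndim != 2:
        log.warning("detect_landmarks: non-grayscale frame, returning no detections")
        return []
    if frame.pixels.min() == frame.pixels.max():
        log.warning("detect_landmarks: constant frame, returning no detections")
        return []

    pre = preprocess(frame)
    row_pts = extract_local_maxima(pre, "rows", params.min_separation_px)
    row_scr = screen_peaks(row_pts, params.screen, scan_axis="rows")
    if len(row_scr) < params.min_chain_rows:
        log.warning("detect_landmarks: too few screened ridge points")
        return []

    chains = ridge_chains(row_scr, scan_axis="rows", max_step_px=params.screen.max_step_px)
    chains = [c for c in chains if len(c) >= params.min_chain_rows]
    if not chains:
        log.warning("detect_landmarks: no near-vertical ridge chain found")
        return []
    iliac_idx = max(chains, key=len)
    chain_pts = row_scr.points[iliac_idx]
    chain_pts = chain_pts[np.argsort(chain_pts[:, 0])]

    rim_point = _rim_from_chain(chain_pts, params.corner_tolerance_px)
    iliac_line = fit_line_tls(chain_pts[: max(2, int(0.6 * len(chain_pts)))])

    detections = []
    rim_det = _make_detection(RIM, rim_point, pre, params)
    if rim_det is not None:
        detections.append(rim_det)

    limb_point = _lower_limb(pre, iliac_line, params)
    if limb_point is not None:
        limb_det = _make_detection(LOWER_LIMB, limb_point, pre, params)
        if limb_det is not None:
            detections.append(limb_det)
    return detections


def _rim_from_chain(chain_pts: np.ndarray, tol_px: float) -> tuple[float, float]:
    """Caudal terminus of the iliac ridge chain, or the corner where the
    chain bends away from the upper-chain line (shallow-roof scenes where
    the roof ridge stays chain-connected to the iliac margin).

    Candidate termini tie-break toward the greater row (the rim is the
    caudal end of the margin in this orientation).
    """
    upper = chain_pts[: max(2, int(0.6 * len(chain_pts)))]
    line = fit_line_tls(upper)
    dist = line.distance(chain_pts)
    on_line = np.flatnonzero(dist <= tol_px)
    j = int(on_line.max()) if len(on_line) else len(chain_pts) - 1
    return (float(chain_pts[j, 0]), float(chain_pts[j, 1]))


def _lower_limb(pre: UltrasoundFrame, iliac_line, params: DetectorParams):
    """Screened column-scan ridge point farthest from the iliac line.

    The bony roof is shallow relative to the rows, so a column scan samples
    it cleanly; the lower limb of the ilium is its far (medial) terminus,
    i.e. the bright ridge point with maximal perpendicular clearance from
    the iliac margin. Ties break toward the greater row.
    """
    col_pts = extract_local_maxima(pre, "cols", params.min_separation_px)
    col_scr = screen_peaks(col_pts, params.screen, scan_axis="cols")
    if len(col_scr) == 0:
        return None
    dist = iliac_line.distance(col_scr.points)
    far = dist >= params.min_limb_distance_px
    if not far.any():
        return None
    cand = col_scr.points[far]
    d = dist[far]
    best = np.lexsort((cand[:, 0], d))[-1]  # max distance, then max row
    return (float(cand[best, 0]), float(cand[best, 1]))


def _make_detection(
    label: str, point: tuple[float, float], pre: UltrasoundFrame, params: DetectorParams
) -> LandmarkDetection | None:
    shape = pre.pixels.shape
    size = params.box_size
    r0 = int(np.clip(round(point[0]) - size // 2, 0, shape[0] - size))
    c0 = int(np.clip(round(point[1]) - size // 2, 0, shape[1] - size))
    box = (r0, c0, r0 + size, c0 + size)
    conf = _confidence(pre.pixels, box, caudal_half=(label == RIM))
    if conf < params.confidence_floor:
        return None
    return LandmarkDetection(label=label, box=box, confidence=conf)


def _confidence(
    pixels: np.ndarray, box: tuple[int, int, int, int], caudal_half: bool = False
) -> float:
    """Normalized local ridge contrast on a [0, 1] scale.

    The 95th percentile of the box window minus the frame's background
    floor (20th percentile), over the full 8-bit range — monotone in the
    ridge-to-background contrast of the landmark's supporting structure.
    For the rim, only the caudal half of the box is scored: a true
    acetabular rim is validated by the bony roof actually departing
    caudally from it, whereas a mere ridge fade-out (an off-plane frame)
    leaves that half dark.
    """
    r0, c0, r1, c1 = box
    if caudal_half:
        r0 = (r0 + r1) // 2
    window = pixels[r0:r1, c0:c1].astype(np.float64)
    background = float(np.percentile(pixels, 20))
    contrast = float(np.percentile(window, 95)) - background
    return float(np.clip(contrast / 255.0, 0.0, 1.0))
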