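"""Core Graf alpha-angle measurement geometry.

The measurement chain on one frame is: preprocess, extract per-scanline
local intensity maxima (bone surfaces are intensity ridges), screen the
maxima by intensity and ridge-run length, fit the iliac outer margin line
(Hough-seeded total least squares in static mode, chain-based total least
squares in dynamic mode), construct the baseline parallel to the iliac
margin through the detected acetabular rim, fit the bony-roof line in the
region spanned by the two landmark boxes, and report the angle between
baseline and roof line as alpha together with the iliac inclination.

Line convention: ``theta`` in [0, 180) degrees is the line direction
measured from the image column (vertical) axis, positive clockwise toward
+col; ``offset`` is the signed perpendicular distance of the line from the
image origin, with normal ``n = (-sin theta, cos theta)`` in (row, col)
coordinates. A perfectly vertical iliac margin has theta = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .io import UltrasoundFrame


class MeasurementError(Exception):
    """A measurement-stage failure with a machine-readable reason code."""

    def __init__(self, reason: str, detail: str = ""):
        super().__init__(detail or reason)
        self.reason = reason
        self.detail = detail


# ---------------------------------------------------------------------------
# line model and angle arithmetic


@dataclass(frozen=True)
class LineModel:
    """A 2-D line in angle-offset form.

    theta: direction in degrees in [0, 180) from the vertical (+row) axis,
    positive clockwise. offset: signed perpendicular distance (px) from the
    origin along the normal (-sin theta, cos theta).
    """

    theta: float
    offset: float
    rms_residual: float = 0.0
    n_points: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 180.0:
            raise ValueError(f"theta must lie in [0, 180), got {self.theta}")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")
        if self.n_points < 2:
            raise ValueError("a line needs at least 2 supporting points")

    def normal(self) -> np.ndarray:
        a = math.radians(self.theta)
        return np.array([-math.sin(a), math.cos(a)])

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Absolute perpendicular distance of (row, col) points to the line."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.abs(pts @ self.normal() - self.offset)


def _fold_theta(theta_deg: float) -> float:
    t = theta_deg % 180.0
    return 0.0 if t == 180.0 else t


def angle_between(l1: LineModel, l2: LineModel) -> float:
    """Inter-line angle in degrees, folded into [0, 90].

    The Graf alpha-angle opens caudally from the baseline toward the bony
    roof; with the near-vertical baseline convention used here the folded
    (acute) angle between the two directions is the reported alpha. The
    result is symmetric in its arguments.
    """
    d = abs(l1.theta - l2.theta) % 180.0
    return min(d, 180.0 - d)


def iliac_inclination(iliac_line: LineModel) -> float:
    """Signed tilt of the iliac margin from the vertical axis, in [-90, 90].

    0 for a perfectly vertical margin; positive = clockwise.
    """
    t = iliac_line.theta
    return t if t <= 90.0 else t - 180.0


def construct_baseline(iliac_line: LineModel, rim_anchor: tuple[float, float]) -> LineModel:
    """Baseline parallel to the iliac outer margin through the rim anchor."""
    offset = float(np.asarray(rim_anchor, dtype=float) @ iliac_line.normal())
    return LineModel(
        theta=iliac_line.theta,
        offset=offset,
        rms_residual=iliac_line.rms_residual,
        n_points=iliac_line.n_points,
    )


# ---------------------------------------------------------------------------
# point sets: extraction, screening, chain analysis


@dataclass
class PointSet:
    """Bone-surface candidate points with their source-pixel intensities."""

    points: np.ndarray  # (N, 2) float (row, col)
    intensities: np.ndarray  # (N,) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if len(self.points) != len(self.intensities):
            raise ValueError("points and intensities must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, mask: np.ndarray) -> "PointSet":
        return PointSet(self.points[mask], self.intensities[mask])


def preprocess(frame: UltrasoundFrame) -> UltrasoundFrame:
    """Smooth a frame before ridge extraction.

    A light Gaussian (sigma 0.8 px) suppresses pixel-level noise while
    keeping every bone ridge a clean local intensity maximum regardless of
    its orientation (median footprints were rejected: any footprint erodes
    1-px ridges at some orientation). Residual impulse noise that survives
    as an isolated peak is removed downstream by the run-length screening
    rule. Output range stays within [0, 255] and repeated application
    changes the image only marginally.
    """
    img = frame.pixels.astype(np.float64)
    img = ndimage.gaussian_filter(img, 0.8)
    out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return UltrasoundFrame(out, frame.pixel_spacing_mm, dict(frame.metadata))


def extract_local_maxima(
    frame: UltrasoundFrame,
    scan_axis: str = "rows",
    min_separation_px: int = 5,
    subpixel: bool = False,
) -> PointSet:
    """Strict per-scanline local intensity maxima.

    ``scan_axis='rows'`` scans each row along the columns (suited to the
    near-vertical iliac margin, which crosses every row once);
    ``scan_axis='cols'`` scans each column along the rows (suited to the
    shallower bony-roof line). Peaks on one scanline are separated by at
    least ``min_separation_px``; plateau interiors are never returned.
    With ``subpixel`` a three-point parabolic interpolation refines the
    along-scanline coordinate; intensities are always taken at the source
    pixel.
    """
    if scan_axis not in {"rows", "cols"}:
        raise ValueError(f"scan_axis must be 'rows' or 'cols', got {scan_axis!r}")
    img = frame.pixels.astype(np.float64)
    lines = img if scan_axis == "rows" else img.T

    pts, vals = [], []
    for idx in range(lines.shape[0]):
        x = lines[idx]
        peaks, _ = find_peaks(x, distance=max(1, min_separation_px), plateau_size=(1, 1))
        for p in peaks:
            pos = float(p)
            if subpixel and 0 < p < len(x) - 1:
                denom = x[p - 1] - 2.0 * x[p] + x[p + 1]
                if denom < 0:
                    pos += 0.5 * (x[p - 1] - x[p + 1]) / denom
            if scan_axis == "rows":
                pts.append((float(idx), pos))
            else:
                pts.append((pos, float(idx)))
            vals.append(x[p])
    if not pts:
        return PointSet(np.empty((0, 2)), np.empty(0))
    return PointSet(np.array(pts), np.array(vals))


@dataclass(frozen=True)
class ScreenParams:
    """Peak-screening rule: keep peaks with intensity >= mu + k*sigma of the
    candidate-peak population (sample SD), optionally an absolute floor, and
    drop ridge runs shorter than ``min_run`` consecutive scanlines.

    The mu + k*sigma threshold is capped at the midpoint of the peak
    intensity range: when the candidate population is narrow and unimodal
    (e.g. a clean frame where nearly every peak already lies on bone) the
    uncapped rule would sit above almost the entire population and discard
    valid bone surfaces. The cap scales with intensity, so screening stays
    invariant under global intensity scaling.
    """

    k_sigma: float | None = 2.0
    absolute_threshold: float | None = None
    min_run: int = 5
    max_step_px: float = 2.0


def screen_peaks(
    points: PointSet, params: ScreenParams = ScreenParams(), scan_axis: str = "rows"
) -> PointSet:
    """Intensity- and run-length-based screening of candidate bone peaks.

    Returns a subset of the input; every retained intensity meets every
    stated threshold, and raising any threshold never enlarges the result.
    An empty result is legitimate (downstream stages must handle it).
    """
    if len(points) == 0:
        return points
    inten = points.intensities
    thr = -np.inf
    if params.k_sigma is not None and len(inten) > 1:
        thr = float(np.mean(inten) + params.k_sigma * np.std(inten, ddof=1))
        thr = min(thr, float(inten.min() + inten.max()) / 2.0)
    if params.absolute_threshold is not None:
        thr = max(thr, params.absolute_threshold)
    kept = points.subset(inten >= thr)
    if params.min_run > 1 and len(kept) > 0:
        runs = ridge_chains(kept, scan_axis=scan_axis, max_step_px=params.max_step_px)
        keep_idx = np.concatenate(
            [r for r in runs if len(r) >= params.min_run] or [np.empty(0, dtype=int)]
        )
        mask = np.zeros(len(kept), dtype=bool)
        mask[keep_idx.astype(int)] = True
        kept = kept.subset(mask)
    return kept


def ridge_chains(
    points: PointSet, scan_axis: str = "rows", max_step_px: float = 2.0, max_gap: int = 2
) -> list[np.ndarray]:
    """Group points into ridge chains along the scan axis.

    A point on scanline ``s`` extends a chain whose last point lies on a
    scanline within ``max_gap`` earlier and whose cross coordinate differs
    by at most ``max_step_px`` per scanline; near-vertical ridges form one
    long chain under a row scan while steeper structures fragment.
    Returns index arrays into ``points``.
    """
    if len(points) == 0:
        return []
    along = 0 if scan_axis == "rows" else 1  # scanline coordinate
    cross = 1 - along
    order = np.lexsort((points.points[:, cross], points.points[:, along]))
    chains: list[list[int]] = []
    last: list[tuple[float, float]] = []  # (scanline, cross) of each chain tail
    for i in order:
        s, c = points.points[i, along], points.points[i, cross]
        best, best_dc = -1, np.inf
        for j, (ls, lc) in enumerate(last):
            ds = s - ls
            if 1 <= ds <= max_gap and abs(c - lc) <= max_step_px * ds:
                dc = abs(c - lc)
                if dc < best_dc:
                    best, best_dc = j, dc
        if best >= 0:
            chains[best].append(i)
            last[best] = (s, c)
        else:
            chains.append([i])
            last.append((s, c))
    return [np.array(ch, dtype=int) for ch in chains]


# ---------------------------------------------------------------------------
# line fitting


def fit_line_tls(points: PointSet | np.ndarray) -> LineModel:
    """Total-least-squares (orthogonal) line fit via the principal axis.

    Minimizes the summed squared perpendicular distances — the appropriate
    criterion for the near-vertical iliac margin, where ordinary regression
    of col on row would be ill-posed. ``rms_residual`` is the RMS
    perpendicular distance of the supporting points.
    """
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float)
    pts = pts.reshape(-1, 2)
    if len(pts) < 2 or len(np.unique(pts, axis=0)) < 2:
        raise MeasurementError("too_few_points", "TLS fit needs >= 2 distinct points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    theta = _fold_theta(math.degrees(math.atan2(direction[1], direction[0])))
    line = LineModel(theta=theta, offset=0.0, rms_residual=0.0, n_points=len(pts))
    offset = float(centroid @ line.normal())
    rms = float(s[1] / math.sqrt(len(pts))) if len(s) > 1 else 0.0
    return LineModel(theta=theta, offset=offset, rms_residual=rms, n_points=len(pts))


def hough_fit(
    points: PointSet | np.ndarray,
    theta_bin_deg: float = 1.0,
    rho_bin_px: float = 1.0,
    theta_range: tuple[float, float] | None = None,
) -> LineModel:
    """Point Hough transform followed by total-least-squares refinement.

    Every point votes for all (theta, rho) bins it lies on; the
    accumulator-maximal bin (ties broken toward smallest theta, then
    smallest rho) selects inliers within ``2 * rho_bin_px`` of the bin
    line, which are then TLS-refined. Robust to a moderate fraction of
    gross outliers. ``theta_range`` (degrees, folded into [0, 180))
    optionally restricts the direction search, e.g. to near-vertical lines.
    """
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float)
    pts = pts.reshape(-1, 2)
    if len(pts) < 2:
        raise MeasurementError("too_few_points", "Hough fit needs >= 2 points")

    thetas = np.arange(0.0, 180.0, theta_bin_deg)
    if theta_range is not None:
        lo, hi = theta_range
        folded = (thetas - lo) % 180.0
        thetas = thetas[folded <= (hi - lo) % 180.0]
        if len(thetas) == 0:
            raise ValueError("theta_range selects no Hough bins")
    a = np.radians(thetas)
    normals = np.stack([-np.sin(a), np.cos(a)], axis=1)  # (T, 2)
    rho = pts @ normals.T  # (N, T)
    rho_min = rho.min() - rho_bin_px
    bins = np.floor((rho - rho_min) / rho_bin_px).astype(int)
    n_rho = bins.max() + 1

    acc = np.zeros((len(thetas), n_rho), dtype=int)
    for t in range(len(thetas)):
        np.add.at(acc[t], bins[:, t], 1)
    best = np.argwhere(acc == acc.max())
    t_idx, r_idx = min(best, key=lambda br: (thetas[br[0]], br[1]))
    theta0 = float(thetas[t_idx])
    rho0 = rho_min + (r_idx + 0.5) * rho_bin_px

    seed_line = LineModel(theta=_fold_theta(theta0), offset=float(rho0), n_points=len(pts))
    inliers = seed_line.distance(pts) <= 2.0 * rho_bin_px
    if inliers.sum() < 2:
        return seed_line
    return fit_line_tls(pts[inliers])


def fit_roof_line(
    frame: UltrasoundFrame,
    rim_box: tuple[int, int, int, int],
    ilium_box: tuple[int, int, int, int],
    screened_points: PointSet,
    *,
    mode: str = "dynamic",
    margin_px: int = 10,
    baseline: LineModel | None = None,
    baseline_exclusion_px: float = 4.0,
    hough_theta_bin_deg: float = 1.0,
    hough_rho_bin_px: float = 1.0,
) -> LineModel:
    """Fit the bony acetabular roof line between the two landmark boxes.

    Support points are the screened bone-surface maxima inside the bounding
    region spanned by the rim and lower-limb boxes inflated by
    ``margin_px``; points within ``baseline_exclusion_px`` of the baseline
    are removed so the iliac ridge passing through the rim box cannot
    contaminate the roof fit. Static mode seeds with a Hough transform,
    dynamic mode fits total least squares directly. Fewer than 2 usable
    points raises a roof-fit failure (the frame is unusable).
    """
    r0 = min(rim_box[0], ilium_box[0]) - margin_px
    c0 = min(rim_box[1], ilium_box[1]) - margin_px
    r1 = max(rim_box[2], ilium_box[2]) + margin_px
    c1 = max(rim_box[3], ilium_box[3]) + margin_px
    pts = screened_points.points
    mask = (pts[:, 0] >= r0) & (pts[:, 0] < r1) & (pts[:, 1] >= c0) & (pts[:, 1] < c1)
    if baseline is not None:
        mask &= baseline.distance(pts) > baseline_exclusion_px
    region = screened_points.subset(mask)
    if len(region) < 2:
        raise MeasurementError("roof_fit_failed", "fewer than 2 roof support points")
    try:
        if mode == "static":
            return hough_fit(region, hough_theta_bin_deg, hough_rho_bin_px)
        return fit_line_tls(region)
    except MeasurementError as exc:
        raise MeasurementError("roof_fit_failed", exc.detail) from exc


# ---------------------------------------------------------------------------
# full-frame measurement


@dataclass(frozen=True)
class MeasureParams:
    """Tunable thresholds of the measurement chain (all config-exposed)."""

    min_separation_px: int = 5
    screen: ScreenParams = field(default_factory=ScreenParams)
    subpixel: bool = True
    iliac_theta_window_deg: float = 30.0  # Hough search half-width about vertical
    hough_theta_bin_deg: float = 1.0
    hough_rho_bin_px: float = 1.0
    min_chain_rows: int = 10
    roof_margin_px: int = 10
    baseline_exclusion_px: float = 4.0


@dataclass(frozen=True)
class AlphaMeasurement:
    """One frame's alpha-angle result with full fit diagnostics retained."""

    alpha_deg: float
    inclination_deg: float
    baseline: LineModel
    roof_line: LineModel
    iliac_line: LineModel
    method: str  # 'static' | 'dynamic'
    frame_index: int | None = None

    @property
    def ok(self) -> bool:
        return True


@dataclass(frozen=True)
class MeasurementFailure:
    """Reason-coded failure of the measurement chain on one frame."""

    reason: str
    method: str
    detail: str = ""
    frame_index: int | None = None

    @property
    def ok(self) -> bool:
        return False


def measure_alpha(
    frame: UltrasoundFrame,
    detections,
    mode: str = "dynamic",
    params: MeasureParams = MeasureParams(),
    frame_index: int | None = None,
) -> AlphaMeasurement | MeasurementFailure:
    """Measure the Graf alpha-angle on one frame given landmark detections.

    Static mode follows the still-image path (Hough-seeded baseline fit);
    dynamic mode follows the video path (ridge-chain total least squares).
    Any stage failure yields a reason-coded :class:`MeasurementFailure`,
    never a silent number.
    """
    if mode not in {"static", "dynamic"}:
        raise ValueError(f"mode must be 'static' or 'dynamic', got {mode!r}")
    from .detect import box_center  # local import to avoid a cycle

    dets = {d.label: d for d in detections}
    if "acetabular_rim" not in dets:
        return MeasurementFailure("rim_not_detected", mode, frame_index=frame_index)
    if "ilium_lower_limb" not in dets:
        return MeasurementFailure("lower_limb_not_detected", mode, frame_index=frame_index)
    rim_det, limb_det = dets["acetabular_rim"], dets["ilium_lower_limb"]

    try:
        pre = preprocess(frame)
        row_pts = extract_local_maxima(pre, "rows", params.min_separation_px, params.subpixel)
        row_scr = screen_peaks(row_pts, params.screen, scan_axis="rows")
        iliac_line = _fit_iliac(row_scr, mode, params)

        baseline = construct_baseline(iliac_line, box_center(rim_det))

        col_pts = extract_local_maxima(pre, "cols", params.min_separation_px, params.subpixel)
        col_scr = screen_peaks(col_pts, params.screen, scan_axis="cols")
        roof_line = fit_roof_line(
            pre,
            rim_det.box,
            limb_det.box,
            col_scr,
            mode=mode,
            margin_px=params.roof_margin_px,
            baseline=baseline,
            baseline_exclusion_px=params.baseline_exclusion_px,
            hough_theta_bin_deg=params.hough_theta_bin_deg,
            hough_rho_bin_px=params.hough_rho_bin_px,
        )
    except MeasurementError as exc:
        return MeasurementFailure(exc.reason, mode, exc.detail, frame_index)

    return AlphaMeasurement(
        alpha_deg=angle_between(baseline, roof_line),
        inclination_deg=iliac_inclination(baseline),
        baseline=baseline,
        roof_line=roof_line,
        iliac_line=iliac_line,
        method=mode,
        frame_index=frame_index,
    )


def _fit_iliac(screened: PointSet, mode: str, params: MeasureParams) -> LineModel:
    """Iliac outer-margin fit: Hough-seeded TLS (static) or longest
    near-vertical ridge chain + TLS (dynamic)."""
    if len(screened) < 2:
        raise MeasurementError("iliac_fit_failed", "no screened bone-surface points")
    if mode == "static":
        w = params.iliac_theta_window_deg
        line = hough_fit(
            screened,
            params.hough_theta_bin_deg,
            params.hough_rho_bin_px,
            theta_range=(180.0 - w, w),
        )
    else:
        chains = ridge_chains(screened, scan_axis="rows", max_step_px=params.screen.max_step_px)
        chains = [c for c in chains if len(c) >= params.min_chain_rows]
        if not chains:
            raise MeasurementError("iliac_fit_failed", "no sufficiently long ridge chain")
        longest = max(chains, key=len)
        line = fit_line_tls(screened.points[longest])
    if angle_between(line, LineModel(theta=0.0, offset=0.0)) > params.iliac_theta_window_deg:
        raise MeasurementError(
            "iliac_fit_failed",
            f"fitted iliac direction {line.theta:.1f} deg is not near-vertical",
        )
    return line


def round_reported(value: float, decimals: int = 1) -> float:
    """Round half away from zero (reporting convention for angles)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)
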