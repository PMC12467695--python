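"""Frame, sequence, and results I/O.

Images are 8-bit grayscale PNG or TIFF (16-bit accepted and linearly
rescaled); sequences are either a directory of lexicographically ordered
frames or a multi-page TIFF. Results and ground-truth sidecars are JSON;
per-frame tables are CSV. All round-trips are lossless at the stated
precision and every JSON output embeds the effective configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

log = logging.getLogger(__name__)

DEFAULT_PIXEL_SPACING_MM = 0.1
SCHEMA_VERSION = 1


@dataclass
class UltrasoundFrame:
    """One 2-D grayscale intensity grid plus pixel-spacing metadata.

    Pixels are stored as an 8-bit ``(rows, cols)`` array, origin top-left,
    coordinates given as ``(row, col)``.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"frame must be 2-D grayscale, got shape {self.pixels.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_frame(path: str | Path) -> UltrasoundFrame:
    """Read a single-channel PNG/TIFF frame.

    16-bit input is rescaled linearly to 8 bit (65535 -> 255). RGB input is
    rejected with guidance; a missing pixel-spacing sidecar falls back to the
    documented default of 0.1 mm/px with a logged notice.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: expected single-channel grayscale, got shape {arr.shape}; "
            "convert RGB images to grayscale before measurement"
        )
    arr = _to_uint8(arr, str(path))
    spacing, meta = _read_frame_sidecar(path)
    return UltrasoundFrame(arr, pixel_spacing_mm=spacing, metadata=meta)


def _to_uint8(arr: np.ndarray, label: str) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    raise ValueError(f"{label}: unsupported dtype {arr.dtype}; expected uint8 or uint16")


def _read_frame_sidecar(path: Path) -> tuple[float, dict]:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return float(meta.get("pixel_spacing_mm", DEFAULT_PIXEL_SPACING_MM)), meta
    log.info(
        "%s: no sidecar found, using default pixel spacing %.2f mm/px",
        path,
        DEFAULT_PIXEL_SPACING_MM,
    )
    return DEFAULT_PIXEL_SPACING_MM, {"pixel_spacing_mm": DEFAULT_PIXEL_SPACING_MM}


def write_frame(frame: UltrasoundFrame, path: str | Path) -> Path:
    """Write an 8-bit frame as PNG or TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, frame.pixels.astype(np.uint8))
    sidecar = path.with_suffix(".json")
    meta = dict(frame.metadata)
    meta["pixel_spacing_mm"] = frame.pixel_spacing_mm
    sidecar.write_text(json.dumps(_jsonify(meta), indent=1))
    return path


def read_sequence(path: str | Path) -> list[UltrasoundFrame]:
    """Read a frame sequence in acquisition order.

    A directory is read lexicographically (PNG/TIFF members); a multi-page
    TIFF in page order. Mixed frame shapes within one sequence are an error.
    """
    path = Path(path)
    if path.is_dir():
        members = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not members:
            raise ValueError(f"{path}: no PNG/TIFF frames found")
        frames = [read_frame(p) for p in members]
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [
            UltrasoundFrame(_to_uint8(page, f"{path}[{k}]"))
            for k, page in enumerate(stack)
        ]
        spacing, meta = _read_frame_sidecar(path)
        for f in frames:
            f.pixel_spacing_mm = spacing
            f.metadata = dict(meta)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"{path}: mixed frame shapes within one sequence: {shapes}")
    return frames


def write_sequence(
    frames: list[UltrasoundFrame],
    out_dir: str | Path,
    ground_truth: list | None = None,
    config: dict | None = None,
) -> Path:
    """Write frames as zero-padded PNGs plus one JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{k:04d}.png", frame.pixels.astype(np.uint8))
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "pixel_spacing_mm": frames[0].pixel_spacing_mm if frames else None,
        "config": config or {},
    }
    if ground_truth is not None:
        sidecar["frames"] = [_jsonify(_as_dict(gt)) for gt in ground_truth]
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def read_ground_truth(seq_dir: str | Path) -> dict:
    return json.loads((Path(seq_dir) / "ground_truth.json").read_text())


def write_results(result, path: str | Path, format: str = "json", config: dict | None = None) -> Path:
    """Serialize any result object (measurement, sequence, statistics).

    JSON keeps full float precision; CSV flattens per-frame rows (sequence
    results only). The effective config is embedded for provenance.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": SCHEMA_VERSION, "config": config or {}}
    payload["result"] = _jsonify(_as_dict(result))
    payload["result_type"] = type(result).__name__
    if format == "json":
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif format == "csv":
        _write_csv(result, path)
    else:
        raise ValueError(f"unknown results format: {format!r}")
    return path


def _write_csv(result, path: Path) -> None:
    import pandas as pd

    rows = getattr(result, "per_frame_rows", None)
    if callable(rows):
        pd.DataFrame(rows()).to_csv(path, index=False)
    else:
        pd.DataFrame([_flatten(_as_dict(result))]).to_csv(path, index=False)


def _as_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return obj
    if isinstance(obj, (list, tuple)):
        return [_as_dict(o) for o in obj]
    return obj


def _jsonify(obj):
    """Make numpy scalars/arrays and sets JSON-serializable, recursively."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonify(v) for v in obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out
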