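"""Synthetic Graf-standard-plane hip phantom with exact ground truth.

A digital stand-in for a physical infant-hip phantom scanned in the Graf
standard plane: the iliac outer margin is a bright near-vertical ridge, the
bony acetabular roof meets it at the true alpha-angle at the acetabular rim
(osseous beak), and the lower limb of the ilium terminates the roof line.
The scene geometry is constructed analytically (the stored segments satisfy
the alpha-angle to floating-point precision) before any rasterization, so
every rendered frame carries an exact ground truth.

Conventions: coordinates are ``(row, col)``, origin top-left, 0-based;
angles are degrees; line/segment directions are measured from the image
column (vertical) axis, positive clockwise (toward +col). Positive
inclination therefore tilts the iliac margin clockwise on screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .io import UltrasoundFrame

DEFAULT_SHAPE = (256, 256)
DEFAULT_PIXEL_SPACING_MM = 0.1
#: contrast multiplier applied to rim/roof ridges on off-plane frames;
#: low enough that quality gating must reject these frames
OFFPLANE_CONTRAST = 0.3
LANDMARK_BOX_SIZE = 24

Point = tuple[float, float]


def _unit(angle_deg: float) -> np.ndarray:
    """Unit direction at ``angle_deg`` from the vertical (+row) axis."""
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


@dataclass(frozen=True)
class PhantomScene:
    """Parametric ground-truth geometry of a Graf standard-plane hip."""

    alpha_true: float
    inclination_true: float
    rim_point: Point
    ilium_lower_limb_point: Point
    iliac_segment: tuple[Point, Point]  # (cranial end, rim end)
    roof_segment: tuple[Point, Point]  # (rim, lower limb)
    labrum_point: Point
    image_shape: tuple[int, int] = DEFAULT_SHAPE
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def segment_angle(self) -> float:
        """Angle between the stored iliac and roof segments, recomputed
        from endpoint coordinates (consistency check against alpha_true)."""
        u = np.subtract(self.iliac_segment[1], self.iliac_segment[0])
        v = np.subtract(self.roof_segment[1], self.roof_segment[0])
        cosang = abs(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.degrees(math.acos(min(1.0, cosang)))

    def transformed(self, rotation_deg: float = 0.0, translation: Point = (0.0, 0.0)) -> "PhantomScene":
        """Rotate about the rim point (positive clockwise) then translate."""
        a = math.radians(rotation_deg)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        pivot = np.asarray(self.rim_point)
        t = np.asarray(translation)

        def tp(p: Point) -> Point:
            q = pivot + rot @ (np.asarray(p) - pivot) + t
            return (float(q[0]), float(q[1]))

        return replace(
            self,
            inclination_true=self.inclination_true + rotation_deg,
            rim_point=tp(self.rim_point),
            ilium_lower_limb_point=tp(self.ilium_lower_limb_point),
            iliac_segment=(tp(self.iliac_segment[0]), tp(self.iliac_segment[1])),
            roof_segment=(tp(self.roof_segment[0]), tp(self.roof_segment[1])),
            labrum_point=tp(self.labrum_point),
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Acoustic artifact model: multiplicative Rayleigh-like speckle, then
    Gaussian blur, then column-wise shadowing below the first bone surface.

    With ``speckle_scale`` 0 the bone ridge remains the intensity maximum
    along any scanline crossing it (shadow never attenuates bone pixels).
    """

    speckle_scale: float = 0.2
    blur_sigma_px: float = 1.0
    shadow_attenuation: float = 0.4
    background_level: int = 40
    bone_intensity: int = 220

    def __post_init__(self) -> None:
        if self.speckle_scale < 0 or self.blur_sigma_px < 0:
            raise ValueError("speckle_scale and blur_sigma_px must be >= 0")
        if not 0 <= self.shadow_attenuation <= 1:
            raise ValueError("shadow_attenuation must lie in [0, 1]")
        if not 0 <= self.background_level <= 255 or not 0 <= self.bone_intensity <= 255:
            raise ValueError("intensity levels must lie in [0, 255]")
        if self.bone_intensity <= self.background_level:
            raise ValueError("bone_intensity must exceed background_level")


NOISELESS = NoiseConfig(speckle_scale=0.0, blur_sigma_px=0.0, shadow_attenuation=0.0)


@dataclass(frozen=True)
class DriftModel:
    """Probe drift during continuous scanning: a fixed per-frame rotation
    (about the rim) and translation, with selected frames rendered off-plane
    (landmark contrast degraded). Frame 0 is undrifted."""

    rotation_per_frame: float = 0.0
    translation_per_frame: Point = (0.0, 0.0)
    offplane_frames: frozenset[int] = field(default_factory=frozenset)


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame truth sidecar: alpha, inclination, landmark boxes, quality."""

    alpha_true: float
    inclination_true: float
    rim_point: Point
    ilium_lower_limb_point: Point
    rim_box: tuple[int, int, int, int]
    lower_limb_box: tuple[int, int, int, int]
    diagnostic_quality: bool
    frame_index: int = 0


def make_scene(
    alpha_deg: float,
    inclination_deg: float = 0.0,
    image_shape: tuple[int, int] = DEFAULT_SHAPE,
    *,
    rim_point: Point = (170.0, 110.0),
    iliac_length: float = 130.0,
    roof_length: float = 90.0,
    labrum_offset: float = 26.0,
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM,
) -> PhantomScene:
    """Construct the analytic scene for a given true alpha and iliac tilt.

    The iliac outer margin runs caudally into the acetabular rim; the bony
    roof leaves the rim at ``alpha_deg`` to the iliac direction, opening
    medially (toward +col), and ends at the lower limb of the ilium.

    Parameters
    ----------
    alpha_deg : float
        True Graf alpha-angle, in degrees; must lie in (30, 90].
    inclination_deg : float
        Signed tilt of the iliac margin from the vertical image axis,
        positive clockwise; must satisfy ``|inclination_deg| < 30``.
    """
    if not 30.0 < alpha_deg <= 90.0:
        raise ValueError(f"alpha_deg must lie in (30, 90], got {alpha_deg}")
    if not abs(inclination_deg) < 30.0:
        raise ValueError(f"|inclination_deg| must be < 30, got {inclination_deg}")

    rim = np.asarray(rim_point, dtype=float)
    u_iliac = _unit(inclination_deg)
    u_roof = _unit(inclination_deg + alpha_deg)
    cranial = rim - iliac_length * u_iliac
    lower_limb = rim + roof_length * u_roof
    labrum = rim + labrum_offset * _unit(inclination_deg + alpha_deg + 14.0)

    return PhantomScene(
        alpha_true=float(alpha_deg),
        inclination_true=float(inclination_deg),
        rim_point=tuple(rim),
        ilium_lower_limb_point=tuple(lower_limb),
        iliac_segment=(tuple(cranial), tuple(rim)),
        roof_segment=(tuple(rim), tuple(lower_limb)),
        labrum_point=tuple(labrum),
        image_shape=tuple(image_shape),
        pixel_spacing_mm=pixel_spacing_mm,
    )


#: half-width of the rendered bone echo band: real bone surfaces return an
#: echo several pixels thick, and the band keeps the ridge bright enough to
#: survive blurring with a clearly separable contrast
ECHO_HALF_WIDTH_PX = 1


def _raster_segment(
    seg: tuple[Point, Point], shape: tuple[int, int], half_width: int = ECHO_HALF_WIDTH_PX
) -> np.ndarray:
    """Mask of a segment rasterized as a (2*half_width + 1)-px echo band."""
    (r0, c0), (r1, c1) = seg
    rr, cc = draw_line(round(r0), round(c0), round(r1), round(c1))
    mask = np.zeros(shape, dtype=bool)
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    mask[rr[keep], cc[keep]] = True
    if half_width > 0:
        mask = ndimage.binary_dilation(mask, np.ones((2 * half_width + 1,) * 2))
    return mask


def rasterized_bone_pixels(scene: PhantomScene) -> dict[str, set[tuple[int, int]]]:
    """Exact pixel sets of the rendered bone structures (noiseless render)."""
    shape = scene.image_shape
    out = {}
    for name, seg in [("iliac", scene.iliac_segment), ("roof", scene.roof_segment)]:
        rr, cc = np.nonzero(_raster_segment(seg, shape))
        out[name] = set(zip(rr.tolist(), cc.tolist()))
    lab = np.zeros(shape, dtype=bool)
    lr, lc = round(scene.labrum_point[0]), round(scene.labrum_point[1])
    if 0 <= lr < shape[0] and 0 <= lc < shape[1]:
        lab[lr, lc] = True
        lab = ndimage.binary_dilation(lab, np.ones((2 * ECHO_HALF_WIDTH_PX + 1,) * 2))
    rr, cc = np.nonzero(lab)
    out["labrum"] = set(zip(rr.tolist(), cc.tolist()))
    return out


def _landmark_box(point: Point, shape: tuple[int, int], size: int = LANDMARK_BOX_SIZE) -> tuple[int, int, int, int]:
    r, c = point
    half = size // 2
    r0 = int(np.clip(round(r) - half, 0, shape[0] - size))
    c0 = int(np.clip(round(c) - half, 0, shape[1] - size))
    return (r0, c0, r0 + size, c0 + size)


def render_frame(
    scene: PhantomScene,
    noise: NoiseConfig = NoiseConfig(),
    seed: int | np.random.Generator = 0,
    *,
    contrast_factor: float = 1.0,
    frame_index: int = 0,
) -> tuple[UltrasoundFrame, GroundTruth]:
    """Render one 8-bit frame from a scene with a seeded artifact model.

    ``contrast_factor`` < 1 degrades the rim-neighbourhood and roof ridges
    (off-plane emulation); such frames are flagged non-diagnostic in the
    returned ground truth. Identical (scene, noise, seed) inputs yield a
    bit-identical frame.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = scene.image_shape
    img = np.full(shape, float(noise.background_level))
    bone_amp = float(noise.bone_intensity - noise.background_level)

    iliac_mask = _raster_segment(scene.iliac_segment, shape)
    roof_mask = _raster_segment(scene.roof_segment, shape)
    rim = np.asarray(scene.rim_point)

    # off-plane degradation hits the roof and the caudal (rim-adjacent) part
    # of the iliac margin — the structures whose visibility defines the plane
    ir, ic = np.nonzero(iliac_mask)
    iliac_d = np.hypot(ir - rim[0], ic - rim[1])
    iliac_amp = np.where(iliac_d <= 15.0, contrast_factor * bone_amp, bone_amp)
    img[ir, ic] = noise.background_level + iliac_amp
    img[roof_mask] = noise.background_level + contrast_factor * bone_amp
    lr, lc = round(scene.labrum_point[0]), round(scene.labrum_point[1])
    if 0 <= lr < shape[0] and 0 <= lc < shape[1]:
        lab = np.zeros(shape, dtype=bool)
        lab[lr, lc] = True
        lab = ndimage.binary_dilation(lab, np.ones((2 * ECHO_HALF_WIDTH_PX + 1,) * 2))
        img[lab & ~iliac_mask & ~roof_mask] = (
            noise.background_level + 0.6 * contrast_factor * bone_amp
        )

    bone_mask = iliac_mask | roof_mask

    if noise.speckle_scale > 0:
        rayleigh = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=shape)
        img *= 1.0 + noise.speckle_scale * (rayleigh - 1.0)
    if noise.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, noise.blur_sigma_px)
    if noise.shadow_attenuation > 0:
        img = _apply_shadow(img, bone_mask, noise.shadow_attenuation)

    frame = UltrasoundFrame(
        np.clip(np.round(img), 0, 255).astype(np.uint8),
        pixel_spacing_mm=scene.pixel_spacing_mm,
        metadata={"alpha_true": scene.alpha_true, "frame_index": frame_index},
    )
    gt = GroundTruth(
        alpha_true=scene.alpha_true,
        inclination_true=scene.inclination_true,
        rim_point=scene.rim_point,
        ilium_lower_limb_point=scene.ilium_lower_limb_point,
        rim_box=_landmark_box(scene.rim_point, shape),
        lower_limb_box=_landmark_box(scene.ilium_lower_limb_point, shape),
        diagnostic_quality=contrast_factor >= 1.0,
        frame_index=frame_index,
    )
    return frame, gt


def _apply_shadow(img: np.ndarray, bone_mask: np.ndarray, attenuation: float) -> np.ndarray:
    """Attenuate non-bone pixels more than 2 px below the first bone surface
    in each column (acoustic shadowing along the beam axis)."""
    out = img.copy()
    rows = np.arange(img.shape[0])[:, None]
    first_bone = np.where(
        bone_mask.any(axis=0), bone_mask.argmax(axis=0), img.shape[0]
    )
    shade = (rows > first_bone[None, :] + 2) & ~bone_mask
    out[shade] *= 1.0 - attenuation
    return out


def render_sequence(
    scene: PhantomScene,
    n_frames: int,
    drift: DriftModel = DriftModel(),
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
) -> tuple[list[UltrasoundFrame], list[GroundTruth]]:
    """Render a drifting probe sequence with per-frame ground truth.

    Frame ``k`` shows the scene after ``k`` accumulated drift steps
    (rotation about the current rim, then translation); frames listed in
    ``drift.offplane_frames`` are rendered with degraded landmark contrast
    and flagged non-diagnostic.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    bad = [k for k in drift.offplane_frames if not 0 <= k < n_frames]
    if bad:
        raise ValueError(f"offplane frame indices out of range [0, {n_frames}): {bad}")

    children = np.random.SeedSequence(seed).spawn(n_frames)
    frames, truths = [], []
    current = scene
    for k in range(n_frames):
        factor = OFFPLANE_CONTRAST if k in drift.offplane_frames else 1.0
        frame, gt = render_frame(
            current,
            noise,
            np.random.default_rng(children[k]),
            contrast_factor=factor,
            frame_index=k,
        )
        frames.append(frame)
        truths.append(gt)
        current = current.transformed(
            drift.rotation_per_frame, drift.translation_per_frame
        )
    return frames, truths
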