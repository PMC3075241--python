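"""Idealized stereo pipeline: pinhole projection, blob rendering, centroid
detection and triangulation.

The rig is a rectified parallel pair: two identical pinhole cameras
separated horizontally by a baseline, optical axes along the cage depth
(+y) axis, image u along cage +x and image v along cage -z.  For such a
rig the left/right rows of a projected point coincide (epipolar
constraint) and the disparity is ``focal * baseline / depth``, which
:func:`triangulate` inverts back into the cage frame.

The fly appears as a bright disk on a dark background; its image position
is the intensity-weighted centroid of pixels above a threshold (Otsu by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import Position3D, ValidationError

__all__ = [
    "StereoRig",
    "StereoDetection",
    "project_point",
    "triangulate",
    "render_frame",
    "detect_fly",
]


@dataclass
class StereoRig:
    """Rectified parallel stereo rig in front of the cage.

    ``camera_pos`` is the left camera center in cage coordinates (y < 0:
    the rig looks into the cage along +y); the right camera sits
    ``baseline_mm`` further along +x.  Focal length and principal point
    are in pixels.
    """

    focal_px: float = 1200.0
    baseline_mm: float = 120.0
    cx: float = 640.0
    cy: float = 512.0
    image_width: int = 1280
    image_height: int = 1024
    camera_pos: tuple[float, float, float] = (15.0, -400.0, 75.0)

    def __post_init__(self) -> None:
        if self.baseline_mm <= 0:
            raise ValidationError("stereo baseline must be positive")
        if self.focal_px <= 0:
            raise ValidationError("stereo focal length must be positive")


@dataclass(frozen=True)
class StereoDetection:
    """Blob centroids in the left and right image, (u, v) pixels."""

    left: tuple[float, float]
    right: tuple[float, float]

    @property
    def disparity(self) -> float:
        return self.left[0] - self.right[0]


def project_point(p: Position3D, rig: StereoRig) -> StereoDetection:
    """Pinhole projection of a cage point into both cameras.

    Raises on non-positive depth (point behind the rig).
    """
    ox, oy, oz = rig.camera_pos
    depth = p.y - oy
    if depth <= 0:
        raise ValidationError("point is not in front of the cameras (depth <= 0)")
    v = rig.focal_px * (oz - p.z) / depth + rig.cy
    u_left = rig.focal_px * (p.x - ox) / depth + rig.cx
    u_right = rig.focal_px * (p.x - ox - rig.baseline_mm) / depth + rig.cx
    return StereoDetection(left=(u_left, v), right=(u_right, v))


def triangulate(det: StereoDetection, rig: StereoRig) -> Position3D:
    """Invert the parallel-rig model: depth = focal * baseline / disparity."""
    disparity = det.disparity
    if disparity <= 0:
        raise ValidationError("non-positive disparity: degenerate stereo geometry")
    ox, oy, oz = rig.camera_pos
    depth = rig.focal_px * rig.baseline_mm / disparity
    v = 0.5 * (det.left[1] + det.right[1])
    x = ox + (det.left[0] - rig.cx) * depth / rig.focal_px
    z = oz - (v - rig.cy) * depth / rig.focal_px
    return Position3D(x, oy + depth, z)


def _draw_blob(shape: tuple[int, int], center: tuple[float, float],
               radius: float, background: float, level: float) -> np.ndarray:
    h, w = shape
    img = np.full(shape, background, dtype=float)
    u0, v0 = center
    if not (0 <= u0 < w and 0 <= v0 < h):
        return img  # off-frame: no blob drawn
    uu = np.arange(max(0, int(u0 - radius - 2)), min(w, int(u0 + radius + 3)))
    vv = np.arange(max(0, int(v0 - radius - 2)), min(h, int(v0 + radius + 3)))
    if len(uu) == 0 or len(vv) == 0:
        return img
    du = uu[None, :] - u0
    dv = vv[:, None] - v0
    dist = np.hypot(du, dv)
    # sub-pixel edge coverage so the intensity-weighted centroid is unbiased
    cover = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    img[np.ix_(vv, uu)] = background + (level - background) * cover
    return img


def render_frame(
    p: Position3D,
    rig: StereoRig,
    blob_radius_px: float = 3.0,
    background: float = 10.0,
    blob_level: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the fly as one bright anti-aliased disk per camera.

    A centroid projecting outside the image bounds leaves that frame blank.
    """
    det = project_point(p, rig)
    shape = (rig.image_height, rig.image_width)
    left = _draw_blob(shape, det.left, blob_radius_px, background, blob_level)
    right = _draw_blob(shape, det.right, blob_radius_px, background, blob_level)
    return left, right


def detect_fly(image: np.ndarray, threshold: float | None = None) -> tuple[float, float] | None:
    """Intensity-weighted centroid (u, v) of above-threshold pixels, or None.

    The threshold defaults to an Otsu split of the intensity histogram; a
    uniform (blob-free) image yields None.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("detect_fly expects a non-empty single-channel image")
    if img.max() == img.min():
        return None
    thr = threshold if threshold is not None else threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        return None
    vv, uu = np.nonzero(mask)
    weights = img[vv, uu] - thr
    total = weights.sum()
    if total <= 0:
        weights = np.ones_like(weights)
        total = weights.sum()
    return (float((uu * weights).sum() / total), float((vv * weights).sum() / total))
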