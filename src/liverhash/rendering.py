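"""Pinhole rendering of a scene into 4-class contour maps.

Each database entry and each query is a single-channel integer label image:
0 background, 1 liver silhouette, 2 falciform ligament, 3 left anterior
ridge, 4 right anterior ridge. The silhouette is the morphological gradient
of the rasterized mesh mask; ligament and ridge labels are depth-tested
projections of the annotated 3D polylines drawn with a thick stroke
(emulating drawn surface-object ribbons; wide enough to survive erosion
passes of the training augmentations). Label
precedence where strokes overlap: ridges > ligament > silhouette, so every
pixel carries exactly one label.

Rasterization uses a perspective-correct z-buffer written with numba; no
shading is involved since only contours feed the hashing model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from PIL import Image
from skimage.morphology import dilation, erosion

from .phantom import LiverScene
from .poses import CameraPose

__all__ = ["PinholeCamera", "ContourMap", "OutOfViewError", "LABELS",
           "render_depth", "render_contour_map", "project_surface_points",
           "save_contour_map", "load_contour_map", "one_hot"]

#: label codes of the four contour classes
LABELS = {"silhouette": 1, "ligament": 2, "ridge_left": 3, "ridge_right": 4}

N_CLASSES = 4

# a contour map is a (H, W) uint8 array with values in {0..4}
ContourMap = np.ndarray

_PALETTE = np.array([[0, 0, 0], [255, 255, 255], [60, 100, 255],
                     [60, 200, 80], [230, 60, 60]], dtype=np.uint8)


class OutOfViewError(ValueError):
    """Raised when a pose renders no liver pixel at all."""


@dataclass(frozen=True)
class PinholeCamera:
    """Ideal pinhole intrinsics (pixels)."""

    width: int = 256
    height: int = 256
    fx: float = 221.7
    fy: float = 221.7
    cx: float = 127.5
    cy: float = 127.5

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")

    @classmethod
    def from_fov(cls, width: int = 256, height: int = 256,
                 vfov_deg: float = 60.0) -> "PinholeCamera":
        """Square-pixel camera from a vertical field of view (default 60°,
        typical of a laparoscope)."""
        f = (height / 2.0) / np.tan(np.radians(vfov_deg) / 2.0)
        return cls(width=width, height=height, fx=f, fy=f,
                   cx=(width - 1) / 2.0, cy=(height - 1) / 2.0)

    @classmethod
    def default(cls) -> "PinholeCamera":
        return cls.from_fov()


@njit(cache=True)
def _rasterize_depth(tris, fx, fy, cx, cy, height, width, near):  # pragma: no cover
    depth = np.full((height, width), np.inf)
    for t in range(tris.shape[0]):
        z0, z1, z2 = tris[t, 0, 2], tris[t, 1, 2], tris[t, 2, 2]
        if z0 <= near or z1 <= near or z2 <= near:
            continue
        x0 = fx * tris[t, 0, 0] / z0 + cx
        y0 = fy * tris[t, 0, 1] / z0 + cy
        x1 = fx * tris[t, 1, 0] / z1 + cx
        y1 = fy * tris[t, 1, 1] / z1 + cy
        x2 = fx * tris[t, 2, 0] / z2 + cx
        y2 = fy * tris[t, 2, 1] / z2 + cy
        lo_x = int(max(0.0, np.floor(min(x0, min(x1, x2)))))
        hi_x = int(min(width - 1.0, np.ceil(max(x0, max(x1, x2)))))
        lo_y = int(max(0.0, np.floor(min(y0, min(y1, y2)))))
        hi_y = int(min(height - 1.0, np.ceil(max(y0, max(y1, y2)))))
        if lo_x > hi_x or lo_y > hi_y:
            continue
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if abs(area) < 1e-12:
            continue
        w0, w1, w2 = 1.0 / z0, 1.0 / z1, 1.0 / z2
        for py in range(lo_y, hi_y + 1):
            for px in range(lo_x, hi_x + 1):
                b0 = ((x1 - px) * (y2 - py) - (x2 - px) * (y1 - py)) / area
                b1 = ((x2 - px) * (y0 - py) - (x0 - px) * (y2 - py)) / area
                b2 = 1.0 - b0 - b1
                if b0 < 0.0 or b1 < 0.0 or b2 < 0.0:
                    continue
                zinv = b0 * w0 + b1 * w1 + b2 * w2
                z = 1.0 / zinv
                if z < depth[py, px]:
                    depth[py, px] = z
    return depth


def render_depth(scene: LiverScene, pose: CameraPose,
                 camera: PinholeCamera, near: float = 1.0) -> np.ndarray:
    """Per-pixel camera-frame depth (mm); inf where no surface is hit."""
    verts_cam = pose.transform(scene.vertices)
    tris = verts_cam[scene.faces]
    return _rasterize_depth(np.ascontiguousarray(tris, dtype=np.float64),
                            camera.fx, camera.fy, camera.cx, camera.cy,
                            camera.height, camera.width, near)


def _resample_polyline(points: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Resample an ordered 3D polyline to a uniform arclength spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return points[:1]
    n = max(int(np.ceil(total / spacing_mm)) + 1, 2)
    t = np.linspace(0.0, total, n)
    return np.stack([np.interp(t, s, points[:, i]) for i in range(3)], axis=1)


def _stamp_polyline(labels: np.ndarray, depth: np.ndarray,
                    points_cam: np.ndarray, camera: PinholeCamera,
                    label: int, depth_tol: float, stroke_px: int) -> None:
    """Project depth-visible polyline samples and stamp a disk stroke."""
    z = points_cam[:, 2]
    valid = z > 1.0
    pts = points_cam[valid]
    if len(pts) == 0:
        return
    u = np.round(camera.fx * pts[:, 0] / pts[:, 2] + camera.cx).astype(int)
    v = np.round(camera.fy * pts[:, 1] / pts[:, 2] + camera.cy).astype(int)
    inside = (u >= 0) & (u < camera.width) & (v >= 0) & (v < camera.height)
    u, v, z = u[inside], v[inside], pts[inside, 2]
    visible = z <= depth[v, u] + depth_tol
    u, v = u[visible], v[visible]
    r = stroke_px // 2
    for du in range(-r, r + 1):
        for dv in range(-r, r + 1):
            if du * du + dv * dv > r * r + 1:
                continue
            uu = np.clip(u + du, 0, camera.width - 1)
            vv = np.clip(v + dv, 0, camera.height - 1)
            labels[vv, uu] = label


def render_contour_map(scene: LiverScene, pose: CameraPose,
                       camera: PinholeCamera | None = None,
                       depth_tol: float = 1.0, stroke_px: int = 5) -> ContourMap:
    """Render a scene into the 4-class contour label image.

    ``stroke_px`` is the drawn width of the contour bands (the silhouette
    band and the polyline strokes). The default emulates the thick drawn
    surface objects a surgeon annotates and, deliberately, keeps every
    contour class able to survive a couple of 3×3 erosion passes of the
    segmentation-error augmentation. ``depth_tol`` (mm) is the z-buffer
    slack accepting polyline samples that lie exactly on the surface as
    visible. Raises :class:`OutOfViewError` when the mesh misses the
    frustum entirely.
    """
    if camera is None:
        camera = PinholeCamera.default()
    depth = render_depth(scene, pose, camera)
    mask = np.isfinite(depth)
    if not mask.any():
        raise OutOfViewError("mesh does not intersect the view frustum")

    # silhouette band ~stroke_px wide, centred on the mask boundary
    footprint = np.ones((3, 3), dtype=bool)
    half = max((stroke_px - 1) // 2, 1)
    outer, inner = mask, mask
    for _ in range(half):
        outer = dilation(outer, footprint)
        inner = erosion(inner, footprint)
    gradient = outer & ~inner
    labels = np.zeros((camera.height, camera.width), dtype=np.uint8)
    labels[gradient] = LABELS["silhouette"]

    # scale-aware resampling keeps the projected stroke gap-free
    spacing = 0.5 * float(np.median(depth[mask])) / camera.fy
    spacing = float(np.clip(spacing, 0.05, 2.0))
    for name in ("ligament", "ridge_left", "ridge_right"):  # precedence order
        poly = scene.polylines[name]
        if len(poly) < 2:
            continue
        dense = _resample_polyline(poly, spacing)
        _stamp_polyline(labels, depth, pose.transform(dense), camera,
                        LABELS[name], depth_tol, stroke_px)
    return labels


def project_surface_points(points: np.ndarray, pose: CameraPose) -> np.ndarray:
    """Rigidly map world points (M, 3 mm) into the camera frame.

    No perspective division — the registration error metric compares 3D
    camera-frame coordinates, not pixels.
    """
    pts = np.asarray(points, dtype=float)
    hom = np.hstack([pts, np.ones((len(pts), 1))])
    return (pose.extrinsic @ hom.T).T[:, :3]


def one_hot(contour_map: ContourMap) -> np.ndarray:
    """(H, W, 4) float32 one-hot layers for classes 1..4 (background dropped)."""
    layers = [(contour_map == c).astype(np.float32)
              for c in range(1, N_CLASSES + 1)]
    return np.stack(layers, axis=-1)


def save_contour_map(contour_map: ContourMap, path) -> None:
    """Write a label image as an 8-bit palettised PNG."""
    img = Image.fromarray(contour_map.astype(np.uint8), mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    palette[:len(_PALETTE)] = _PALETTE
    img.putpalette(palette.ravel().tolist())
    img.save(path)


def load_contour_map(path) -> ContourMap:
    """Read a label image written by :func:`save_contour_map`."""
    arr = np.asarray(Image.open(path).convert("P"), dtype=np.uint8)
    return arr
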