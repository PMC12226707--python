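"""Procedural liver-like scenes with annotated contour features.

Real pipelines take a patient-specific surface segmented from CT together
with manually drawn 3D curves for the right and left anterior ridges and the
falciform ligament. This module builds a stand-in with the same topology so
the whole registration stack runs without any acquisition: a smooth
two-lobed surface (a larger right lobe and a smaller left lobe, blended
superellipsoids), a ridge polyline tracing the anterior-inferior edge of
each lobe, and a midline ligament polyline along the blend seam.

World frame (millimetres): x lateral (right lobe at positive x), y superior,
z anterior. The coronal plane is x-y; its normal (+z) is stored on the scene
and anchors the spherical pose sampling and the reference camera rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .poses import CameraPose

__all__ = ["LiverScene", "SyntheticQuery", "make_liver_scene",
           "make_synthetic_queries", "surface_sample"]


@dataclass
class LiverScene:
    """Triangulated liver-like surface with annotated feature polylines.

    vertices/faces describe the mesh (mm); ``ridge_right``, ``ridge_left``
    and ``ligament`` are ordered 3D polylines lying on the surface;
    ``centre`` is the vertex centroid; ``coronal_normal`` the unit normal of
    the patient coronal plane used as the spherical polar axis.
    """

    vertices: np.ndarray
    faces: np.ndarray
    ridge_right: np.ndarray
    ridge_left: np.ndarray
    ligament: np.ndarray
    coronal_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        for name in ("ridge_right", "ridge_left", "ligament"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = np.asarray(self.coronal_normal, dtype=float)
        self.coronal_normal = n / np.linalg.norm(n)

    @property
    def centre(self) -> np.ndarray:
        """Centroid of the mesh vertices (mm)."""
        return self.vertices.mean(axis=0)

    @property
    def polylines(self) -> dict[str, np.ndarray]:
        return {"ligament": self.ligament, "ridge_left": self.ridge_left,
                "ridge_right": self.ridge_right}

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    def save(self, mesh_path, sidecar_path=None) -> None:
        """Write the mesh (PLY/OBJ by extension) and a JSON sidecar holding
        the polylines, centre and coronal normal."""
        mesh_path = Path(mesh_path)
        self.as_trimesh().export(mesh_path)
        sidecar = Path(sidecar_path) if sidecar_path else \
            mesh_path.with_suffix(".features.json")
        payload = {
            "ridge_right": self.ridge_right.tolist(),
            "ridge_left": self.ridge_left.tolist(),
            "ligament": self.ligament.tolist(),
            "centre": self.centre.tolist(),
            "coronal_normal": self.coronal_normal.tolist(),
            "units": "mm",
        }
        sidecar.write_text(json.dumps(payload))

    @classmethod
    def load(cls, mesh_path, sidecar_path=None) -> "LiverScene":
        mesh_path = Path(mesh_path)
        mesh = trimesh.load(mesh_path, force="mesh", process=False)
        sidecar = Path(sidecar_path) if sidecar_path else \
            mesh_path.with_suffix(".features.json")
        payload = json.loads(sidecar.read_text())
        return cls(vertices=np.asarray(mesh.vertices),
                   faces=np.asarray(mesh.faces),
                   ridge_right=np.asarray(payload["ridge_right"]),
                   ridge_left=np.asarray(payload["ridge_left"]),
                   ligament=np.asarray(payload["ligament"]),
                   coronal_normal=np.asarray(payload["coronal_normal"]))


@dataclass
class SyntheticQuery:
    """A query contour map with known ground-truth pose."""

    contour_map: np.ndarray
    gt_pose: CameraPose
    augmented: bool = False


def _superellipsoid(points: np.ndarray, centre: np.ndarray,
                    radii: np.ndarray, exponent: float) -> np.ndarray:
    """Inside-negative implicit field of a superellipsoid."""
    q = np.abs((points - centre) / radii) ** exponent
    return q.sum(axis=-1) ** (1.0 / exponent) - 1.0


def _smooth_min(f1: np.ndarray, f2: np.ndarray, k: float) -> np.ndarray:
    # log-sum-exp union blend; k controls seam sharpness
    m = np.minimum(f1, f2)
    return m - np.log(np.exp(-k * (f1 - m)) + np.exp(-k * (f2 - m))) / k


def _lobe_params(rng: np.random.Generator):
    """Normalised-unit lobe geometry with seed-controlled jitter."""
    jit = lambda lo, hi: float(rng.uniform(lo, hi))
    right = {
        "centre": np.array([jit(0.30, 0.40), jit(-0.03, 0.03), 0.0]),
        "radii": np.array([jit(0.52, 0.62), jit(0.40, 0.48), jit(0.30, 0.36)]),
        "exponent": jit(2.3, 2.8),
    }
    left = {
        "centre": np.array([-jit(0.38, 0.48), jit(-0.08, 0.0), jit(0.0, 0.06)]),
        "radii": np.array([jit(0.38, 0.46), jit(0.26, 0.34), jit(0.20, 0.26)]),
        "exponent": jit(2.3, 2.8),
    }
    return right, left


def _section_extreme(mesh: trimesh.Trimesh, x: float,
                     direction: np.ndarray) -> np.ndarray | None:
    """On-surface point of the cross-section at ``x`` extremal along
    ``direction`` (used to trace the rounded anterior-inferior edge)."""
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[1.0, 0.0, 0.0], plane_origin=[x, 0.0, 0.0])
    if len(segments) == 0:
        return None
    pts = np.asarray(segments).reshape(-1, 3)
    return pts[np.argmax(pts @ direction)]


def _trace_ridge(mesh: trimesh.Trimesh, x_lo: float, x_hi: float,
                 n_stations: int = 24) -> np.ndarray:
    """Ridge polyline: per x-station extreme point towards anterior-inferior."""
    direction = np.array([0.0, -1.0, 1.0]) / np.sqrt(2.0)
    pts = []
    for x in np.linspace(x_lo, x_hi, n_stations):
        p = _section_extreme(mesh, x, direction)
        if p is not None:
            pts.append(p)
    return np.asarray(pts)


def _trace_ligament(mesh: trimesh.Trimesh, x_seam: float) -> np.ndarray:
    """Anterior arc of the sagittal cross-section at the lobe seam."""
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[1.0, 0.0, 0.0], plane_origin=[x_seam, 0.0, 0.0])
    pts = np.asarray(segments).reshape(-1, 3)
    centroid = pts.mean(axis=0)
    anterior = pts[pts[:, 2] >= centroid[2]]
    order = np.argsort(anterior[:, 1])  # inferior -> superior
    arc = anterior[order]
    # deduplicate segment endpoints shared between neighbours
    keep = np.ones(len(arc), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(arc, axis=0), axis=1) > 1e-9
    return arc[keep]


def make_liver_scene(seed: int, size_mm: float = 180.0) -> LiverScene:
    """Deterministic liver-like scene of maximal extent ≈ ``size_mm``.

    The surface is the blended union of two superellipsoids (larger right
    lobe), extracted with marching cubes; ridge polylines follow the
    anterior-inferior curvature of each lobe and the ligament runs along the
    anterior blend seam. Parameters are jittered from ``seed`` so distinct
    seeds give distinct geometry; ``size_mm`` is clamped to [100, 250].
    """
    size_mm = float(np.clip(size_mm, 100.0, 250.0))
    rng = np.random.default_rng(seed)
    right, left = _lobe_params(rng)

    n = 72
    lin = np.linspace(-1.35, 1.35, n)
    grid = np.stack(np.meshgrid(lin, lin, lin, indexing="ij"), axis=-1)
    f1 = _superellipsoid(grid, right["centre"], right["radii"],
                         right["exponent"])
    f2 = _superellipsoid(grid, left["centre"], left["radii"],
                         left["exponent"])
    field = _smooth_min(f1, f2, k=10.0)

    spacing = lin[1] - lin[0]
    verts, faces, _, _ = measure.marching_cubes(field, level=0.0,
                                                spacing=(spacing,) * 3)
    verts = verts + lin[0]

    # scale so the maximal bounding-box extent equals size_mm
    extent = (verts.max(axis=0) - verts.min(axis=0)).max()
    verts = verts * (size_mm / extent)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    scale = size_mm / extent
    seam_x = 0.5 * (right["centre"][0] + left["centre"][0]) * scale
    rc, rr = right["centre"] * scale, right["radii"] * scale
    lc, lr = left["centre"] * scale, left["radii"] * scale

    ridge_right = _trace_ridge(mesh, seam_x + 0.15 * rr[0],
                               rc[0] + 0.85 * rr[0])
    ridge_left = _trace_ridge(mesh, lc[0] - 0.85 * lr[0],
                              seam_x - 0.15 * lr[0])
    ligament = _trace_ligament(mesh, seam_x)

    return LiverScene(vertices=np.asarray(mesh.vertices),
                      faces=np.asarray(mesh.faces),
                      ridge_right=ridge_right, ridge_left=ridge_left,
                      ligament=ligament)


def surface_sample(scene: LiverScene, n: int, seed: int = 0) -> np.ndarray:
    """``n`` mesh vertices sampled without replacement (error-metric points)."""
    rng = np.random.default_rng(seed)
    n = min(n, len(scene.vertices))
    idx = rng.choice(len(scene.vertices), size=n, replace=False)
    return scene.vertices[idx]


def make_synthetic_queries(scene: LiverScene, poses, n: int,
                           augment=None, seed: int = 0,
                           camera=None) -> list[SyntheticQuery]:
    """Draw ``n`` ground-truthed query maps from a pose set.

    Poses are drawn without replacement; each query's contour map is the
    database render of its pose, optionally passed through the positive
    augmentation chain (the same chain used for training positives) to
    emulate intra-operative deformation, occlusion and segmentation error.
    A draw of the chain that wipes out every contour pixel is redrawn: an
    empty segmentation is not a registrable query.
    """
    from .augment import augment_positive
    from .rendering import PinholeCamera, render_contour_map

    if n > len(poses):
        raise ValueError(f"requested {n} queries from {len(poses)} poses")
    if camera is None:
        camera = PinholeCamera.default()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(poses), size=n, replace=False)
    queries = []
    for i in idx:
        pose = poses[int(i)]
        clean = render_contour_map(scene, pose, camera)
        contour, augmented = clean, False
        if augment is not None:
            for _ in range(100):
                contour = augment_positive(clean, augment, rng)
                if contour.any():
                    break
            augmented = True
        queries.append(SyntheticQuery(contour, pose, augmented))
    return queries
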