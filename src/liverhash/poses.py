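"""Camera-pose grids for render-and-retrieve registration.

Candidate camera poses are enumerated on a six-dimensional grid: positions
sampled in spherical coordinates (radius ``r``, polar angle ``theta``,
azimuth ``phi``) around the liver surface centre, and orientations obtained
by composing Euler perturbations (``alpha``, ``beta``, ``gamma``) with a
reference rotation that points the camera at the centre and keeps its image
axes aligned with the patient coronal plane.

Conventions (fixed, self-consistent between database building and inference):

* ``theta`` is the polar angle measured from the coronal normal,
  ``phi`` the azimuth within the coronal plane; both in degrees.
* The Euler perturbation is intrinsic about the camera axes in the order
  ``gamma`` (z, roll), ``beta`` (y), ``alpha`` (x), applied after the
  reference rotation: ``R = Rx(alpha) @ Ry(beta) @ Rz(gamma) @ R_ref``.
* Rotations are world-to-camera; ``extrinsic`` maps homogeneous world
  coordinates (mm) to camera coordinates.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RangeSpec",
    "PoseGridSpec",
    "CameraPose",
    "OrientationError",
    "expand_range",
    "reference_rotation",
    "euler_matrix",
    "spherical_direction",
    "enumerate_poses",
    "pose_distance",
    "poses_to_frame",
]

_AXIS_NAMES = ("r", "theta", "phi", "alpha", "beta", "gamma")


class OrientationError(ValueError):
    """Raised when a camera orientation is geometrically degenerate."""


@dataclass(frozen=True)
class RangeSpec:
    """Arithmetic range ``{min : step : max}`` (degrees, or mm for radius).

    The expanded sequence is ``min, min+step, ...`` up to the largest value
    not exceeding ``max`` (``max`` itself is included when it lands on the
    grid, up to floating-point slack).
    """

    min: float
    step: float
    max: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.min > self.max:
            raise ValueError(f"min {self.min} exceeds max {self.max}")

    def expand(self) -> np.ndarray:
        n = int(np.floor((self.max - self.min) / self.step + 1e-9)) + 1
        return self.min + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.expand())

    @classmethod
    def parse(cls, value) -> "RangeSpec":
        """Accept a RangeSpec, a ``[min, step, max]`` triple, a scalar, or a
        string like ``"[108:5:144]"``."""
        if isinstance(value, RangeSpec):
            return value
        if isinstance(value, str):
            nums = [float(x) for x in re.findall(r"[-+]?\d*\.?\d+", value)]
            if len(nums) != 3:
                raise ValueError(f"cannot parse range from {value!r}")
            return cls(nums[0], nums[1], nums[2])
        if np.isscalar(value):
            v = float(value)
            return cls(v, 1.0, v)
        seq = list(value)
        if len(seq) != 3:
            raise ValueError(f"range needs three values, got {seq}")
        return cls(float(seq[0]), float(seq[1]), float(seq[2]))


def expand_range(r: RangeSpec) -> np.ndarray:
    """Expanded ascending sequence of a ``{min : step : max}`` range."""
    return RangeSpec.parse(r).expand()


@dataclass(frozen=True)
class PoseGridSpec:
    """Six per-axis ranges defining the Cartesian pose grid."""

    radius: RangeSpec
    theta: RangeSpec
    phi: RangeSpec
    alpha: RangeSpec
    beta: RangeSpec
    gamma: RangeSpec

    def __len__(self) -> int:
        return int(np.prod([len(getattr(self, k)) for k in
                            ("radius", "theta", "phi", "alpha", "beta", "gamma")]))

    @classmethod
    def from_dict(cls, d: dict) -> "PoseGridSpec":
        key_map = {"r": "radius", "radius": "radius", "theta": "theta",
                   "phi": "phi", "alpha": "alpha", "beta": "beta",
                   "gamma": "gamma"}
        kwargs = {}
        for key, value in d.items():
            name = key_map.get(str(key).lower())
            if name is None:
                raise KeyError(f"unknown pose-grid axis {key!r}")
            kwargs[name] = RangeSpec.parse(value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PoseGridSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {name: [getattr(self, name).min, getattr(self, name).step,
                       getattr(self, name).max]
                for name in ("radius", "theta", "phi", "alpha", "beta", "gamma")}


@dataclass(frozen=True)
class CameraPose:
    """A rigid camera pose with its grid provenance.

    ``rotation`` is the 3x3 world-to-camera matrix; ``position`` the camera
    origin in world millimetres. ``provenance`` stores the sampled
    ``(r, theta, phi, alpha, beta, gamma)`` when the pose came off a grid.
    """

    position: np.ndarray
    rotation: np.ndarray
    provenance: tuple | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float).reshape(3))
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=float).reshape(3, 3))

    @property
    def extrinsic(self) -> np.ndarray:
        """4x4 homogeneous world-to-camera transform (mm)."""
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = -self.rotation @ self.position
        return T

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map world points (M, 3) into the camera frame."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.position) @ self.rotation.T


def _coronal_in_plane_axis(coronal_normal: np.ndarray) -> np.ndarray:
    """A fixed unit axis lying in the coronal plane.

    Chosen as the world axis least aligned with the normal, orthogonalised;
    fixed per normal so the reference frame is reproducible.
    """
    n = np.asarray(coronal_normal, dtype=float)
    n = n / np.linalg.norm(n)
    seed_axis = np.eye(3)[int(np.argmin(np.abs(n)))]
    a = seed_axis - (seed_axis @ n) * n
    return a / np.linalg.norm(a)


def reference_rotation(position: np.ndarray, centre: np.ndarray,
                       coronal_normal: np.ndarray) -> np.ndarray:
    """World-to-camera rotation looking from ``position`` at ``centre``.

    The camera principal (z) axis points from the camera to the liver
    centre; the camera x axis is the unit projection, orthogonal to z, of a
    fixed axis lying in the coronal plane, so that the image stays aligned
    with the patient's coronal orientation; y completes a right-handed
    frame.
    """
    position = np.asarray(position, dtype=float)
    centre = np.asarray(centre, dtype=float)
    view = centre - position
    norm = np.linalg.norm(view)
    if norm < 1e-12:
        raise OrientationError("camera position coincides with the centre")
    z = view / norm
    a = _coronal_in_plane_axis(coronal_normal)
    x = a - (a @ z) * z
    xn = np.linalg.norm(x)
    if xn < 1e-8:
        raise OrientationError(
            "viewing direction parallel to the coronal in-plane axis")
    x = x / xn
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=0)


def _rot_axis(angle_deg: float, axis: int) -> np.ndarray:
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    R = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R


def euler_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Intrinsic camera-frame perturbation ``Rx(alpha) Ry(beta) Rz(gamma)``."""
    return _rot_axis(alpha, 0) @ _rot_axis(beta, 1) @ _rot_axis(gamma, 2)


def spherical_direction(theta_deg: float, phi_deg: float,
                        coronal_normal: np.ndarray) -> np.ndarray:
    """Unit direction at polar angle ``theta`` from the coronal normal and
    azimuth ``phi`` inside the coronal plane."""
    n = np.asarray(coronal_normal, dtype=float)
    n = n / np.linalg.norm(n)
    u = _coronal_in_plane_axis(n)
    v = np.cross(n, u)
    th, ph = np.radians(theta_deg), np.radians(phi_deg)
    return (np.sin(th) * np.cos(ph) * u + np.sin(th) * np.sin(ph) * v
            + np.cos(th) * n)


def enumerate_poses(spec: PoseGridSpec, scene) -> list[CameraPose]:
    """All grid poses, lexicographic over (r, theta, phi, alpha, beta, gamma).

    ``scene`` provides ``centre`` and ``coronal_normal``. The position is
    ``centre + r * direction(theta, phi)`` and the rotation is the Euler
    perturbation composed with the reference rotation at that position.
    """
    centre = np.asarray(scene.centre, dtype=float)
    normal = np.asarray(scene.coronal_normal, dtype=float)
    axes = [expand_range(getattr(spec, name)) for name in
            ("radius", "theta", "phi", "alpha", "beta", "gamma")]
    poses = []
    for r, th, ph in itertools.product(*axes[:3]):
        position = centre + r * spherical_direction(th, ph, normal)
        ref = reference_rotation(position, centre, normal)
        for al, be, ga in itertools.product(*axes[3:]):
            rotation = euler_matrix(al, be, ga) @ ref
            poses.append(CameraPose(position, rotation,
                                    provenance=(r, th, ph, al, be, ga)))
    return poses


def pose_distance(a: CameraPose, b: CameraPose) -> tuple[float, float]:
    """(translation mm, geodesic rotation angle deg in [0, 180]) between poses."""
    translation = float(np.linalg.norm(a.position - b.position))
    rel = a.rotation @ b.rotation.T
    cos = (np.trace(rel) - 1.0) / 2.0
    rotation = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    return translation, rotation


def poses_to_frame(poses: Sequence[CameraPose]) -> pd.DataFrame:
    """Pose table: six provenance values plus the 12 extrinsic entries."""
    rows = []
    for p in poses:
        prov = p.provenance if p.provenance is not None else (np.nan,) * 6
        rows.append(list(prov) + list(p.extrinsic[:3].ravel()))
    cols = list(_AXIS_NAMES) + [f"T{i}{j}" for i in range(3) for j in range(4)]
    return pd.DataFrame(rows, columns=cols)
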