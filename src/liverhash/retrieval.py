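"""Hash database, k-NN retrieval, weighted-Hausdorff re-ranking, evaluation.

Registration of a query contour map proceeds in two stages: its hash code
is matched against the database by Euclidean k-nearest-neighbour search,
then the k candidate poses are re-rendered and the final pose is the one
minimising a weighted Hausdorff distance

    score(J) = Σ_f  w_f · H(I_f, J_f),        f ∈ {silhouette, ligament,
                                                   left ridge, right ridge}

where ``I_f`` / ``J_f`` are the per-class pixel sets of the query and the
candidate render, ``H`` the symmetric Hausdorff distance, and ``w_f`` the
fraction of the query's nonzero pixels carrying class ``f``. A class absent
from the query contributes nothing; a class present in the query but missing
from a candidate is penalised with the image diagonal.

Registration error against ground truth is the mean Euclidean distance
between liver surface points expressed in the ground-truth and in the
estimated camera frames, optionally decomposed along the camera axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .hashing import HashingModel
from .phantom import LiverScene, make_synthetic_queries, surface_sample
from .poses import CameraPose, PoseGridSpec, enumerate_poses
from .rendering import (ContourMap, N_CLASSES, PinholeCamera,
                        project_surface_points, render_contour_map)

__all__ = ["PoseDatabase", "RegistrationResult", "RegistrationError",
           "build_database", "knn_search", "weighted_hausdorff", "register",
           "registration_error", "error_vs_k_experiment"]


@dataclass
class PoseDatabase:
    """Aligned poses and hash codes, with the render source for re-ranking.

    ``render(i)`` re-renders candidate ``i`` on demand (re-ranking needs
    images, not codes); results are memoised because neighbouring queries
    retrieve overlapping candidate sets.
    """

    poses: list[CameraPose]
    codes: np.ndarray
    scene: LiverScene
    camera: PinholeCamera
    _render_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if len(self.poses) != len(self.codes):
            raise ValueError("pose/code count mismatch")

    def __len__(self) -> int:
        return len(self.poses)

    def render(self, index: int) -> ContourMap:
        if index not in self._render_cache:
            self._render_cache[index] = render_contour_map(
                self.scene, self.poses[index], self.camera)
        return self._render_cache[index]

    def save(self, path) -> None:
        """Persist codes plus the pose table (provenance + extrinsics)."""
        from .poses import poses_to_frame
        np.savez(path, codes=self.codes,
                 pose_table=poses_to_frame(self.poses).to_numpy())


@dataclass
class RegistrationResult:
    """Outcome of one retrieval + re-ranking pass."""

    candidate_indices: np.ndarray
    hash_distances: np.ndarray
    hausdorff_scores: np.ndarray
    selected_index: int

    @property
    def selected_candidate(self) -> int:
        """Position of the selected pose within the candidate list."""
        return int(np.argmin(self.hausdorff_scores))


@dataclass
class RegistrationError:
    """Mean surface displacement between two camera frames (mm)."""

    mean_mm: float
    per_axis_mm: np.ndarray


def build_database(scene: LiverScene, spec: PoseGridSpec,
                   model: HashingModel,
                   camera: PinholeCamera | None = None) -> PoseDatabase:
    """Render and encode every pose of the grid into a database."""
    if camera is None:
        camera = PinholeCamera.default()
    poses = enumerate_poses(spec, scene)
    renders = [render_contour_map(scene, p, camera) for p in poses]
    codes = model.encode(np.stack(renders))
    db = PoseDatabase(poses=poses, codes=codes, scene=scene, camera=camera)
    db._render_cache = dict(enumerate(renders))
    return db


def knn_search(db, query_code: np.ndarray, k: int):
    """Indices and distances of the k hash codes nearest to ``query_code``.

    Euclidean distances on the continuous codes, ascending; exact ties are
    broken by database index (stable sort).
    """
    codes = db.codes if hasattr(db, "codes") else np.asarray(db, dtype=float)
    q = np.asarray(query_code, dtype=float).reshape(-1)
    dists = np.linalg.norm(codes - q, axis=1)
    order = np.argsort(dists, kind="stable")[:k]
    return order, dists[order]


def _class_points(contour_map: ContourMap, label: int) -> np.ndarray:
    return np.argwhere(contour_map == label).astype(float)


def weighted_hausdorff(I: ContourMap, J: ContourMap) -> float:
    """Per-class weighted symmetric Hausdorff distance between label maps.

    Weights are the share of each class among the nonzero pixels of ``I``;
    distances are in pixels. Raises on an all-zero ``I``.
    """
    nnz = int(np.count_nonzero(I))
    if nnz == 0:
        raise ValueError("query contour map has no nonzero pixel")
    diagonal = float(np.hypot(*I.shape))
    score = 0.0
    for label in range(1, N_CLASSES + 1):
        pi = _class_points(I, label)
        if len(pi) == 0:
            continue
        w = len(pi) / nnz
        pj = _class_points(J, label)
        if len(pj) == 0:
            score += w * diagonal
            continue
        h = max(directed_hausdorff(pi, pj)[0], directed_hausdorff(pj, pi)[0])
        score += w * h
    return score


def register(query_map: ContourMap, db: PoseDatabase, model: HashingModel,
             k: int = 50) -> RegistrationResult:
    """Encode, retrieve k nearest codes, re-rank by weighted Hausdorff.

    The selected pose is the candidate minimising the weighted Hausdorff
    distance to the query; among exact score ties the hash-nearest (first)
    candidate wins.
    """
    code = model.encode(query_map)
    indices, dists = knn_search(db, code, k)
    scores = np.array([weighted_hausdorff(query_map, db.render(int(i)))
                       for i in indices])
    best = int(np.argmin(scores))
    return RegistrationResult(candidate_indices=indices, hash_distances=dists,
                              hausdorff_scores=scores,
                              selected_index=int(indices[best]))


def registration_error(gt: CameraPose, est: CameraPose,
                       surface_points: np.ndarray) -> RegistrationError:
    """Mean displacement of surface points between the two camera frames.

    ``mean_mm`` is the mean per-point Euclidean distance; ``per_axis_mm``
    the mean absolute displacement along each ground-truth camera axis
    (x, y, viewing direction z).
    """
    a = project_surface_points(surface_points, gt)
    b = project_surface_points(surface_points, est)
    diff = a - b
    return RegistrationError(
        mean_mm=float(np.mean(np.linalg.norm(diff, axis=1))),
        per_axis_mm=np.mean(np.abs(diff), axis=0))


def error_vs_k_experiment(scene: LiverScene, db: PoseDatabase,
                          model: HashingModel, n_queries: int,
                          k_list=(1, 5, 10, 20, 50), augment=None,
                          seed: int = 0, n_surface_points: int = 400,
                          ) -> pd.DataFrame:
    """Registration error versus candidate count k on synthetic queries.

    Draws ``n_queries`` ground-truthed queries from the database poses
    (optionally augmented), registers each once with the largest k, and
    evaluates the argmin over every prefix k of the candidate list — one
    retrieval pass scores all k values consistently. Returns a table with
    per-k mean, standard deviation and standard error of the mean error.
    """
    k_list = sorted(int(k) for k in k_list)
    k_max = max(k_list)
    points = surface_sample(scene, n_surface_points, seed=seed)
    queries = make_synthetic_queries(scene, db.poses, n_queries,
                                     augment=augment, seed=seed,
                                     camera=db.camera)
    errors = {k: [] for k in k_list}
    for q in queries:
        result = register(q.contour_map, db, model, k=k_max)
        for k in k_list:
            best = int(np.argmin(result.hausdorff_scores[:k]))
            est = db.poses[int(result.candidate_indices[best])]
            errors[k].append(
                registration_error(q.gt_pose, est, points).mean_mm)
    rows = []
    for k in k_list:
        e = np.asarray(errors[k])
        rows.append({"k": k, "mean_mm": e.mean(), "std_mm": e.std(ddof=1),
                     "sem_mm": e.std(ddof=1) / np.sqrt(len(e)),
                     "n_queries": len(e)})
    return pd.DataFrame(rows)
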