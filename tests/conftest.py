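"""Shared fixtures: one synthetic scene, small pose grids, one trained model.

Everything is generated at test time; the expensive pieces (renders of the
training grid, the trained tiny model, the fine retrieval database) are
session-scoped so the whole suite pays for them once. Problem sizes are
deliberately small desk-scale versions of the full pipeline: a few hundred
training poses, ~2600 retrieval poses, 64 px contour maps.
"""

from __future__ import annotations

import pytest

from liverhash import PinholeCamera, make_liver_scene
from liverhash.hashing import TrainConfig, train
from liverhash.poses import PoseGridSpec, RangeSpec, enumerate_poses
from liverhash.rendering import render_contour_map

RESOLUTION = 64

#: desk-scale training schedule: the full-scale setting (50 epochs over
#: hundreds of thousands of poses at lr 1e-4) is replaced by a short run on
#: a small grid with a proportionally larger step size
TRAIN_KW = dict(epochs=10, lr=1e-3, seed=0)


def grid(radius=(150, 40, 230), theta=(10, 15, 40), phi=(-30, 30, 30),
         alpha=(-15, 15, 15), beta=(0, 1, 0),
         gamma=(-15, 15, 15)) -> PoseGridSpec:
    return PoseGridSpec(radius=RangeSpec(*radius), theta=RangeSpec(*theta),
                        phi=RangeSpec(*phi), alpha=RangeSpec(*alpha),
                        beta=RangeSpec(*beta), gamma=RangeSpec(*gamma))


@pytest.fixture(scope="session")
def scene():
    return make_liver_scene(seed=0, size_mm=180.0)


@pytest.fixture(scope="session")
def camera():
    return PinholeCamera.from_fov(RESOLUTION, RESOLUTION, 60.0)


@pytest.fixture(scope="session")
def tiny_grid_spec():
    """243 poses — self-retrieval database scale."""
    return grid()


@pytest.fixture(scope="session")
def train_grid_spec():
    """567 poses — the coarse patient-specific training grid."""
    return grid(phi=(-45, 15, 45))


@pytest.fixture(scope="session")
def fine_grid_spec():
    """2625 poses — same ranges as the training grid, smaller steps."""
    return grid(theta=(10, 7.5, 40), phi=(-45, 15, 45),
                alpha=(-15, 7.5, 15), gamma=(-15, 7.5, 15))


@pytest.fixture(scope="session")
def train_poses(train_grid_spec, scene):
    return enumerate_poses(train_grid_spec, scene)


@pytest.fixture(scope="session")
def train_renders(train_poses, scene, camera):
    return [render_contour_map(scene, p, camera) for p in train_poses]


@pytest.fixture(scope="session")
def train_cfg():
    return TrainConfig(**TRAIN_KW)


@pytest.fixture(scope="session")
def trained_model(scene, train_grid_spec, train_cfg, camera, train_poses,
                  train_renders):
    return train(scene, train_grid_spec, train_cfg, camera=camera,
                 renders=train_renders, poses=train_poses)


@pytest.fixture(scope="session")
def fine_database(scene, fine_grid_spec, trained_model, camera):
    from liverhash.retrieval import build_database
    return build_database(scene, fine_grid_spec, trained_model, camera)
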