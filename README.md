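# liverhash

Deep-hashing retrieval for rigid 2D–3D registration of a pre-operative
liver surface to laparoscopic contour images.

## The problem

Augmented-reality overlays in laparoscopic liver surgery require the rigid
camera pose aligning the patient's CT-derived 3D liver surface with the
live 2D video. Optimisation-based 2D–3D registration needs a good manual
initialisation and fails on partial views. `liverhash` instead treats the
task as content-based image retrieval:

1. **Pre-operatively** — enumerate a dense 6-DoF grid of candidate camera
   poses (spherical positions × Euler orientations around the liver
   centre), render each pose into a 4-class contour map (liver silhouette,
   falciform ligament, left/right anterior ridge), and encode every map
   into a 64-dimensional hash code with a patient-specific Siamese CNN.
2. **Intra-operatively** — encode the segmented video contours with the
   same network, retrieve the k nearest codes (Euclidean), re-render the k
   candidate poses, and pick the pose minimising the weighted Hausdorff
   distance

   &nbsp;&nbsp;&nbsp;&nbsp;Ĵ = argmin<sub>J₁…J_k</sub> Σ_f w_f · H(I_f, J_f),

   where I_f / J_f are the per-class pixel sets of the query and candidate
   and w_f the class's share of the query's nonzero pixels.

The encoder is trained with triplets — query render, augmented copy
(shear, pixel dropout, erosion/dilation, occlusion), and a negative render
at least 30 mm or 30° away — under the loss
L = 10·L_c + 100·L_r + 1·L_b (margin contrastive + weighted
autoencoding reconstruction + binarisation towards ±1, margin 32).

A seeded synthetic-scene generator (two blended superellipsoid lobes with
on-surface ridge and ligament polylines) makes the whole pipeline runnable
and testable without any patient or phantom data.

## Worked example

```python
import numpy as np
from liverhash import (AugmentConfig, PinholeCamera, TrainConfig,
                       build_database, make_liver_scene,
                       make_synthetic_queries, register, train)
from liverhash.poses import PoseGridSpec
from liverhash.retrieval import registration_error
from liverhash.phantom import surface_sample

scene = make_liver_scene(seed=0, size_mm=180.0)
camera = PinholeCamera.from_fov(64, 64, 60.0)

coarse = PoseGridSpec.from_dict({           # 567 training poses
    "r": "[150:40:230]", "theta": "[10:15:40]", "phi": "[-45:15:45]",
    "alpha": "[-15:15:15]", "beta": "[0:1:0]", "gamma": "[-15:15:15]"})
fine = PoseGridSpec.from_dict({             # 2625 retrieval poses
    "r": "[150:40:230]", "theta": "[10:7.5:40]", "phi": "[-45:15:45]",
    "alpha": "[-15:7.5:15]", "beta": "[0:1:0]", "gamma": "[-15:7.5:15]"})

model = train(scene, coarse, TrainConfig(epochs=10, lr=1e-3, seed=0),
              camera=camera)
db = build_database(scene, fine, model, camera)

query = make_synthetic_queries(scene, db.poses, n=1,
                               augment=AugmentConfig(), seed=7,
                               camera=camera)[0]
result = register(query.contour_map, db, model, k=20)
err = registration_error(query.gt_pose, db.poses[result.selected_index],
                         surface_sample(scene, 300))
print(f"selected pose {result.selected_index}, "
      f"error {err.mean_mm:.1f} mm")
```

Typical output (a few minutes of CPU training):

```
selected pose 2480, error 0.0 mm
```

— the augmented query still retrieves its own generating pose; harder
draws land on a neighbouring grid pose instead, giving errors set by the
grid spacing (over 200 such queries the mean error drops from ≈16 mm at
k=1 to ≈13–15 mm at k=5–20, which is why more than one candidate is
retrieved before Hausdorff re-ranking).

A thin CLI wraps the same calls (`liverhash make-scene / train / build-db /
simulate-queries / register / evaluate`, each with a YAML config and
`--seed`); run `liverhash --help`.

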