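# Methods

## Problem

Augmented-reality guidance in laparoscopic liver surgery needs the rigid
camera pose that aligns a pre-operative 3D liver surface (from CT) with a
2D intra-operative video frame. Direct 2D–3D optimisation is fragile on
partial views, so `liverhash` treats the problem as content-based image
retrieval: render a dense database of candidate views of the patient's
surface ahead of time, compress each rendered contour image into a short
learned hash code, and register a new frame by nearest-neighbour search in
code space followed by geometric re-ranking.

## Pipeline

1. **Scene.** A triangulated liver surface with three annotated 3D curves:
   the right and left anterior-ridge contours and the falciform ligament.
   The synthetic generator (`phantom`) stands in for patient data: two
   smoothly blended superellipsoid lobes (the right larger), extracted by
   marching cubes; ridge polylines traced along each lobe's
   anterior-inferior extremal curve; the ligament along the anterior blend
   seam. All curves lie exactly on the mesh. The generator is seeded and
   deterministic.

2. **Pose grid (`poses`).** Camera positions on a spherical grid
   (radius r, polar angle θ from the coronal normal, azimuth φ in the
   coronal plane) around the surface centre; at each position a reference
   rotation points the camera z axis at the centre and aligns the image
   axes with the coronal plane, and Euler perturbations
   `Rx(α)·Ry(β)·Rz(γ)` are applied on top. Each axis is an inclusive
   arithmetic range `{min:step:max}`. Enumeration is lexicographic over
   (r, θ, φ, α, β, γ) and deterministic. Pose distance is Euclidean in
   position plus the geodesic rotation angle.

3. **Rendering (`rendering`).** A perspective-correct z-buffer rasterizer
   (numba) renders depth; the contour map is an integer label image —
   0 background, 1 silhouette (a band centred on the boundary of the
   rendered mask), 2 ligament, 3 left ridge, 4 right ridge, the curve
   labels depth-tested against the z-buffer with 1 mm slack and drawn with
   a disk stroke. Precedence where strokes overlap: ridges > ligament >
   silhouette. Default camera: square image, 60° vertical field of view
   (typical laparoscope optics); database and inference always share one
   camera.

4. **Augmentation (`augment`).** The positive of each training triplet is
   the query map degraded by, in order: affine shear uniform in ±10° (a 2D
   proxy for insufflation deformation), dropout of up to 5% of the nonzero
   pixels, 2–5 sequential 3×3 dilations or erosions (each direction with
   probability ½, applied per label layer and recomposed under the label
   precedence), and one rectangular occlusion of up to 5% of the image
   area centred on a contour pixel (aspect ratio uniform in [0.25, 4]).

5. **Hashing (`hashing`).** A Siamese encoder (three 3×3 stride-2
   convolution blocks, 32/64/128 channels, then FC 256 and a linear FC to
   a 64-dimensional code) with a mirrored decoder. Loss:

       L = w_c·L_c + w_r·L_r + w_b·L_b,    w_c=10, w_r=100, w_b=1

   * `L_c = max(0, m + D(h_q,h_p) − D(h_q,h_n))`, Euclidean D, margin
     m = 32 (half the code length).
   * `L_r` — mean squared reconstruction error of the one-hot map, each
     image weighted by its ratio of nonzero pixels (so sparse maps do not
     vanish from the objective).
   * `L_b = Σ ‖|h|−1‖²` over the three codes, pulling entries to ±1.

   The encoder output is linear; binarisation pressure comes only from
   `L_b`. Negatives are any database render at least 30 mm or 30° away
   from the query pose (rejection sampling). Optimiser: Adam. The network
   and its backward pass are implemented directly in numpy (channels-last,
   each convolution tap a single BLAS GEMM); training is single-threaded
   and bit-reproducible for a fixed seed.

6. **Retrieval (`retrieval`).** The database stores one code per grid
   pose. A query is encoded, its k nearest codes retrieved by exact
   Euclidean search (ties broken by database index), the k candidate poses
   re-rendered, and the final pose is the candidate minimising the
   weighted Hausdorff distance: per contour class, the symmetric Hausdorff
   distance between the query's and candidate's pixel sets, weighted by
   the class's share of the query's nonzero pixels. A class absent from
   the query contributes nothing; a class the candidate lacks is penalised
   with the image diagonal. Registration error against ground truth is the
   mean Euclidean distance between surface points expressed in the two
   camera frames, with a per-axis decomposition along the ground-truth
   camera axes.

## Parameter choices and scale

| Parameter | Default | Why |
|---|---|---|
| hash length | 64 | compact yet collision-free at database scale |
| margin m | 32 | half the code length |
| loss weights | 10 / 100 / 1 | contrastive / reconstruction / binarisation balance |
| negative rule | ≥30 mm or ≥30° | poses closer than this render near-identical views |
| batch / epochs / lr | 32 / 50 / 1e-4 | full-scale schedule (database of ~10⁵–10⁶ poses) |
| image | 256×256, 60° vfov | full-scale rendering default |
| stroke width | 5 px | emulates drawn surface-object ribbons; survives a couple of 3×3 erosion passes, so augmented positives keep signal |

The test-suite and the acceptance script run a deliberately small version
of the study: 64×64 images, a 567-pose training grid, a 2 625-pose
retrieval grid (same ranges, smaller steps), 10 epochs at learning rate
1e-3. With roughly three orders of magnitude fewer gradient steps than the
full schedule, a proportionally larger step size is required for the
optimiser to converge at all; the `TrainConfig` defaults keep the
full-scale values. Absolute registration errors at this scale are
grid-quantisation dominated and are not comparable to a full-scale run;
the qualitative behaviour (exact self-retrieval, error decreasing with k
up to ~20 then stabilising) is scale-independent and is what the
acceptance suite checks.

## What the synthetic scene does and does not capture

The generator reproduces the *topology* the method consumes — a smooth
two-lobed anterior surface, one ridge curve per lobe, a midline ligament —
with seed-controlled shape variation and millimetre units. It does not
reproduce real liver anatomy (no posterior fossae, no vascular
impressions), real segmentation noise statistics, insufflation
deformation, or camera calibration error. Passing tests therefore
demonstrate the correctness and internal consistency of the machinery
(rendering, hashing, retrieval, ranking) and the learnability of the
objective, not clinical accuracy.

## Numerical and design notes

* **Empty queries.** The augmentation chain can, rarely, erase every
  contour pixel. An empty map is not a registrable query (the weighted
  Hausdorff is undefined); the synthetic-query generator redraws the
  augmentation in that case, and `weighted_hausdorff` raises on an empty
  query by contract.
* **Hausdorff variant.** The symmetric (bidirectional) Hausdorff is used;
  with the directed variant a candidate whose contours form a subset of
  the query's would score spuriously well.
* **Continuous codes.** Retrieval uses the real-valued codes without sign
  binarisation: Euclidean search over float codes is exact and the
  binarisation loss keeps them near ±1 anyway.
* **Ties.** k-NN ties break by database index (stable sort); Hausdorff
  score ties break towards the hash-nearest candidate. This makes
  self-retrieval exact: a clean database render retrieves its own pose
  with distance 0 and Hausdorff 0.
* **Grid semantics.** Ranges include the endpoint when it lands on the
  grid (`{45:5:45}` is the single value 45). Grid size is exactly the
  product of the six range lengths; no visibility filtering is applied.
* **Conventions.** World-to-camera rotations; spherical polar axis =
  coronal normal; Euler perturbation intrinsic about camera z, y, x
  (γ, β, α) after the reference rotation. Any fixed convention works as
  long as database and inference share it.
* **Degenerate geometry.** The reference rotation is undefined when the
  viewing direction is parallel to the fixed in-plane coronal axis; this
  raises `OrientationError` rather than producing an arbitrary roll.

## Known limitations

* Exact k-NN and on-demand re-rendering limit databases to ~10⁵ poses on
  one CPU; the full-scale 10⁶-pose regime of a GPU deployment would need
  an ANN index and a render cache.
* The 2D shear is a crude stand-in for insufflation deformation; the
  method is rigid by construction and is intended to initialise, not
  replace, deformable refinement.
* Triplet hold-out accuracy is measured on the same *grid* (not the same
  triplets) used in training; a fully independent probe would sample
  off-grid poses, which the database by construction does not contain.
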