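"""Positive-sample augmentations for triplet training.

The positive of a triplet is the query map passed through a chain that
emulates the gap between a clean pre-operative render and an intra-operative
segmentation: affine shear (2D proxy for insufflation deformation), random
removal of contour pixels and erosion/dilation passes (segmentation error),
and a rectangular occlusion centred on a contour pixel (instruments, fat).

The chain order is fixed: shear → pixel dropout → morphology → occlusion.
All steps map valid label images to valid label images (values stay in
{0..4}, shape preserved) and are reproducible given a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, erosion
from skimage.transform import AffineTransform, warp

from .rendering import ContourMap, N_CLASSES

__all__ = ["AugmentConfig", "shear", "dropout_pixels", "morph_perturb",
           "occlude", "augment_positive"]

_FOOTPRINT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class AugmentConfig:
    """Parameter ranges of the augmentation chain.

    Defaults: shear uniform in [-10°, 10°]; up to 5% of nonzero pixels
    dropped; 2–5 erosion/dilation passes (each direction with probability
    ½); occluding rectangle of up to 5% of the image area.
    """

    shear_deg_range: tuple[float, float] = (-10.0, 10.0)
    dropout_max_frac: float = 0.05
    morph_ops_range: tuple[int, int] = (2, 5)
    occlusion_max_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_max_frac <= 1.0:
            raise ValueError("dropout_max_frac must lie in [0, 1]")
        if not 0.0 <= self.occlusion_max_frac <= 1.0:
            raise ValueError("occlusion_max_frac must lie in [0, 1]")
        if self.morph_ops_range[0] < 0 or \
                self.morph_ops_range[1] < self.morph_ops_range[0]:
            raise ValueError("morph_ops_range must be a non-negative pair")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        """Degenerate config under which the chain is the identity."""
        return cls(shear_deg_range=(0.0, 0.0), dropout_max_frac=0.0,
                   morph_ops_range=(0, 0), occlusion_max_frac=0.0)


def shear(contour_map: ContourMap, angle_deg: float) -> ContourMap:
    """Affine shear about the image centre, nearest-neighbour resampled."""
    if abs(angle_deg) > 45.0:
        raise ValueError("shear angle limited to ±45°")
    if angle_deg == 0.0:
        return contour_map.copy()
    h, w = contour_map.shape
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (AffineTransform(translation=-centre)
          + AffineTransform(shear=np.radians(angle_deg))
          + AffineTransform(translation=centre))
    out = warp(contour_map, tf.inverse, order=0, preserve_range=True,
               mode="constant", cval=0)
    return out.astype(np.uint8)


def dropout_pixels(contour_map: ContourMap, frac: float,
                   rng: np.random.Generator) -> ContourMap:
    """Zero exactly ``⌊frac · nnz⌋`` nonzero pixels, chosen uniformly."""
    out = contour_map.copy()
    nz = np.flatnonzero(out)
    n_remove = int(np.floor(frac * len(nz)))
    if n_remove == 0:
        return out
    chosen = rng.choice(nz, size=n_remove, replace=False)
    out.ravel()[chosen] = 0
    return out


def morph_perturb(contour_map: ContourMap, n_ops: int,
                  rng: np.random.Generator) -> ContourMap:
    """``n_ops`` sequential 3×3 dilations/erosions (each with probability ½).

    The drawn operation sequence is applied to each label layer
    independently so labels never bleed into each other; layers are then
    recomposed with the precedence ridges > ligament > silhouette.
    """
    ops = rng.integers(0, 2, size=n_ops)  # 1 = dilate, 0 = erode
    out = np.zeros_like(contour_map)
    for label in range(1, N_CLASSES + 1):  # ascending: higher label wins
        layer = contour_map == label
        if not layer.any():
            continue
        for op in ops:
            layer = dilation(layer, _FOOTPRINT) if op else \
                erosion(layer, _FOOTPRINT)
        out[layer] = label
    return out


def occlude(contour_map: ContourMap, frac: float,
            rng: np.random.Generator) -> ContourMap:
    """Zero one axis-aligned rectangle of area ≤ ``frac``·(H·W), centred on
    a uniformly chosen nonzero pixel; aspect ratio uniform in [0.25, 4]."""
    out = contour_map.copy()
    nz = np.flatnonzero(out)
    if frac <= 0.0 or len(nz) == 0:
        return out
    h, w = out.shape
    area = frac * h * w
    aspect = rng.uniform(0.25, 4.0)  # width / height
    rh = max(int(round(np.sqrt(area / aspect))), 1)
    rw = max(int(round(np.sqrt(area * aspect))), 1)
    # shrink the longer side if rounding pushed the area above the cap
    while rh * rw > area and max(rh, rw) > 1:
        if rw >= rh:
            rw -= 1
        else:
            rh -= 1
    cy, cx = np.unravel_index(rng.choice(nz), out.shape)
    y0 = max(cy - rh // 2, 0)
    x0 = max(cx - rw // 2, 0)
    out[y0:y0 + rh, x0:x0 + rw] = 0
    return out


def augment_positive(contour_map: ContourMap, cfg: AugmentConfig,
                     rng: np.random.Generator) -> ContourMap:
    """Full positive-augmentation chain with parameters drawn from ``cfg``.

    Shear angle ~ U(range); dropout fraction ~ U(0, max); number of
    morphology passes ~ U{lo..hi}; occlusion area fraction ~ U(0, max).
    """
    out = shear(contour_map, float(rng.uniform(*cfg.shear_deg_range)))
    out = dropout_pixels(out, float(rng.uniform(0.0, cfg.dropout_max_frac)),
                         rng)
    lo, hi = cfg.morph_ops_range
    out = morph_perturb(out, int(rng.integers(lo, hi + 1)), rng)
    out = occlude(out, float(rng.uniform(0.0, cfg.occlusion_max_frac)), rng)
    return out
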