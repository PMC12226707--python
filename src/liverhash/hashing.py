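"""Siamese deep-hashing model for contour maps.

A small convolutional encoder maps a 4-class contour map (fed as 4 one-hot
channels) to a 64-dimensional hash code; a symmetric decoder reconstructs
the map from the code. Training is patient-specific and triplet-based: the
query is a random database render, the positive an augmented copy of it,
and the negative any render whose pose differs from the query's by at
least 30 mm in position or 30° in rotation.

The training objective is the weighted sum

    L = w_c * L_c  +  w_r * L_r  +  w_b * L_b

of a margin contrastive loss over code distances (``L_c``), a nonzero-ratio
weighted reconstruction loss (``L_r``, keeps codes semantically meaningful),
and a binarisation loss (``L_b``) pulling code entries towards ±1. Default
weights 10 / 100 / 1, margin 32 (half the code length), Adam at 1e-4.

The encoder output is linear (no squashing): the binarisation loss, not an
activation, is what drives entries towards ±1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentConfig, augment_positive
from .phantom import LiverScene
from .poses import CameraPose, PoseGridSpec, enumerate_poses, pose_distance
from .rendering import (ContourMap, N_CLASSES, PinholeCamera, one_hot,
                        render_contour_map)

__all__ = ["TrainConfig", "LossBreakdown", "Triplet", "HashingModel",
           "DegenerateGridError", "encode", "decode", "contrastive_loss",
           "reconstruction_loss", "binarisation_loss", "total_loss",
           "sample_triplet", "train", "binarisation_deviation",
           "triplet_accuracy"]

_EPS = 1e-12


class DegenerateGridError(RuntimeError):
    """No admissible negative exists for the pose-distance predicate."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of patient-specific hashing training."""

    hash_len: int = 64
    margin: float = 32.0          # half the hash length by default
    w_c: float = 10.0
    w_r: float = 100.0
    w_b: float = 1.0
    lr: float = 1e-4
    epochs: int = 50
    batch: int = 32
    neg_translation_mm: float = 30.0
    neg_rotation_deg: float = 30.0
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if min(self.w_c, self.w_r, self.w_b) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-batch loss components and their weighted total."""

    L_c: float
    L_r: float
    L_b: float
    L: float
    recon_weights: tuple = ()


@dataclass
class Triplet:
    """Query / positive / negative contour maps with pose provenance."""

    query: ContourMap
    positive: ContourMap
    negative: ContourMap
    query_pose: CameraPose
    negative_pose: CameraPose


# ---------------------------------------------------------------------------
# losses


def contrastive_loss(h_q, h_p, h_n, m: float) -> float:
    """Margin contrastive loss ``max(0, m + D(h_q,h_p) - D(h_q,h_n))``.

    ``D`` is the Euclidean distance; batched inputs (B, L) are averaged.
    """
    h_q, h_p, h_n = (np.atleast_2d(np.asarray(h, dtype=float))
                     for h in (h_q, h_p, h_n))
    d_qp = np.linalg.norm(h_q - h_p, axis=1)
    d_qn = np.linalg.norm(h_q - h_n, axis=1)
    return float(np.mean(np.maximum(0.0, m + d_qp - d_qn)))


def _image_weight(original: np.ndarray) -> float:
    """Ratio of nonzero pixels of the original image (per-pixel for label
    maps / single-channel images; a one-hot stack counts a pixel nonzero
    when any class layer is set)."""
    arr = np.asarray(original)
    if arr.ndim == 3:  # (H, W, C) one-hot stack
        nonzero = (arr != 0).any(axis=-1)
    else:
        nonzero = arr != 0
    return float(nonzero.sum() / nonzero.size)


def reconstruction_loss(pairs) -> float:
    """Nonzero-ratio weighted squared reconstruction error.

    ``pairs`` is the sequence of (decoded, original) pairs for the query,
    positive and negative. Each pair contributes
    ``w * ||decoded - original||^2`` with ``w`` the ratio of nonzero pixels
    in the original; the sum is divided by the pixel count N.
    """
    total = 0.0
    n_pixels = None
    for decoded, original in pairs:
        decoded = np.asarray(decoded, dtype=float)
        original_f = np.asarray(original, dtype=float)
        if original_f.ndim == 2 and decoded.ndim == 3:
            original_f = one_hot(np.asarray(original))
        n_pixels = original_f.shape[0] * original_f.shape[1]
        w = _image_weight(original)
        total += w * float(np.sum((decoded - original_f) ** 2))
    return total / n_pixels


def binarisation_loss(h_q, h_p, h_n) -> float:
    """``Σ ‖|h| − 1‖²`` over the three codes (batches averaged)."""
    h_q, h_p, h_n = (np.atleast_2d(np.asarray(h, dtype=float))
                     for h in (h_q, h_p, h_n))
    total = 0.0
    for h in (h_q, h_p, h_n):
        total += float(np.mean(np.sum((np.abs(h) - 1.0) ** 2, axis=1)))
    return total


def total_loss(l_c: float, l_r: float, l_b: float,
               cfg: TrainConfig, recon_weights=()) -> LossBreakdown:
    """Weighted sum ``L = w_c L_c + w_r L_r + w_b L_b`` from the config."""
    L = cfg.w_c * l_c + cfg.w_r * l_r + cfg.w_b * l_b
    return LossBreakdown(L_c=float(l_c), L_r=float(l_r), L_b=float(l_b),
                         L=float(L), recon_weights=tuple(recon_weights))


def binarisation_deviation(codes: np.ndarray) -> float:
    """Mean over codes of ``‖|h|−1‖² / hash_len`` — 0 when fully binarised."""
    codes = np.atleast_2d(np.asarray(codes, dtype=float))
    return float(np.mean((np.abs(codes) - 1.0) ** 2))


# ---------------------------------------------------------------------------
# model


class HashingModel:
    """Encoder/decoder CNN operating on one-hot contour maps.

    Encoder: three 3×3 stride-2 convolution blocks (channels 32, 64, 128)
    with ReLU, then two fully connected layers (256 → ``hash_len``) with a
    linear output. Decoder mirrors the encoder with ×2 nearest-neighbour
    upsampling. Input resolution must be divisible by 8.
    """

    CHANNELS = (32, 64, 128)
    FC_DIM = 256

    def __init__(self, resolution: int = 256, hash_len: int = 64,
                 seed: int = 0):
        if resolution % 8 != 0:
            raise ValueError("resolution must be divisible by 8")
        self.resolution = int(resolution)
        self.hash_len = int(hash_len)
        self.bottom = resolution // 8
        self.training_log: pd.DataFrame | None = None
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.CHANNELS
        flat = c3 * self.bottom ** 2
        p = {}
        p["enc_c1_w"] = nn.he_init(rng, N_CLASSES * 9, (3, 3, N_CLASSES, c1))
        p["enc_c2_w"] = nn.he_init(rng, c1 * 9, (3, 3, c1, c2))
        p["enc_c3_w"] = nn.he_init(rng, c2 * 9, (3, 3, c2, c3))
        p["enc_f1_w"] = nn.he_init(rng, flat, (self.FC_DIM, flat))
        p["enc_f2_w"] = nn.he_init(rng, self.FC_DIM, (hash_len, self.FC_DIM))
        p["dec_f1_w"] = nn.he_init(rng, hash_len, (self.FC_DIM, hash_len))
        p["dec_f2_w"] = nn.he_init(rng, self.FC_DIM, (flat, self.FC_DIM))
        p["dec_c1_w"] = nn.he_init(rng, c3 * 9, (3, 3, c3, c2))
        p["dec_c2_w"] = nn.he_init(rng, c2 * 9, (3, 3, c2, c1))
        p["dec_c3_w"] = nn.he_init(rng, c1 * 9, (3, 3, c1, N_CLASSES))
        for key in list(p):
            out_dim = p[key].shape[3] if p[key].ndim == 4 else p[key].shape[0]
            p[key.replace("_w", "_b")] = np.zeros(out_dim, dtype=np.float32)
        self.params = p

    # -- forward/backward ---------------------------------------------------

    def _encode_forward(self, x: np.ndarray):
        p = self.params
        caches = {}
        h, caches["c1"] = nn.conv2d_forward(x, p["enc_c1_w"], p["enc_c1_b"], 2)
        h, caches["r1"] = nn.relu_forward(h)
        h, caches["c2"] = nn.conv2d_forward(h, p["enc_c2_w"], p["enc_c2_b"], 2)
        h, caches["r2"] = nn.relu_forward(h)
        h, caches["c3"] = nn.conv2d_forward(h, p["enc_c3_w"], p["enc_c3_b"], 2)
        h, caches["r3"] = nn.relu_forward(h)
        caches["shape"] = h.shape
        h = h.reshape(h.shape[0], -1)
        h, caches["f1"] = nn.linear_forward(h, p["enc_f1_w"], p["enc_f1_b"])
        h, caches["r4"] = nn.relu_forward(h)
        codes, caches["f2"] = nn.linear_forward(h, p["enc_f2_w"], p["enc_f2_b"])
        return codes, caches

    def _encode_backward(self, dcodes: np.ndarray, caches, grads: dict):
        p = self.params
        d, grads["enc_f2_w"], grads["enc_f2_b"] = \
            nn.linear_backward(dcodes, caches["f2"], p["enc_f2_w"])
        d = nn.relu_backward(d, caches["r4"])
        d, grads["enc_f1_w"], grads["enc_f1_b"] = \
            nn.linear_backward(d, caches["f1"], p["enc_f1_w"])
        d = d.reshape(caches["shape"])
        d = nn.relu_backward(d, caches["r3"])
        d, grads["enc_c3_w"], grads["enc_c3_b"] = \
            nn.conv2d_backward(d, caches["c3"], p["enc_c3_w"])
        d = nn.relu_backward(d, caches["r2"])
        d, grads["enc_c2_w"], grads["enc_c2_b"] = \
            nn.conv2d_backward(d, caches["c2"], p["enc_c2_w"])
        d = nn.relu_backward(d, caches["r1"])
        _, grads["enc_c1_w"], grads["enc_c1_b"] = \
            nn.conv2d_backward(d, caches["c1"], p["enc_c1_w"])

    def _decode_forward(self, codes: np.ndarray):
        p = self.params
        caches = {}
        c3 = self.CHANNELS[2]
        d, caches["f1"] = nn.linear_forward(codes, p["dec_f1_w"], p["dec_f1_b"])
        d, caches["r1"] = nn.relu_forward(d)
        d, caches["f2"] = nn.linear_forward(d, p["dec_f2_w"], p["dec_f2_b"])
        d, caches["r2"] = nn.relu_forward(d)
        d = d.reshape(d.shape[0], self.bottom, self.bottom, c3)
        d, caches["u1"] = nn.upsample2_forward(d)
        d, caches["c1"] = nn.conv2d_forward(d, p["dec_c1_w"], p["dec_c1_b"], 1)
        d, caches["r3"] = nn.relu_forward(d)
        d, caches["u2"] = nn.upsample2_forward(d)
        d, caches["c2"] = nn.conv2d_forward(d, p["dec_c2_w"], p["dec_c2_b"], 1)
        d, caches["r4"] = nn.relu_forward(d)
        d, caches["u3"] = nn.upsample2_forward(d)
        recon, caches["c3"] = nn.conv2d_forward(d, p["dec_c3_w"],
                                                p["dec_c3_b"], 1)
        return recon, caches

    def _decode_backward(self, drecon: np.ndarray, caches, grads: dict):
        p = self.params
        d, grads["dec_c3_w"], grads["dec_c3_b"] = \
            nn.conv2d_backward(drecon, caches["c3"], p["dec_c3_w"])
        d = nn.upsample2_backward(d, caches["u3"])
        d = nn.relu_backward(d, caches["r4"])
        d, grads["dec_c2_w"], grads["dec_c2_b"] = \
            nn.conv2d_backward(d, caches["c2"], p["dec_c2_w"])
        d = nn.upsample2_backward(d, caches["u2"])
        d = nn.relu_backward(d, caches["r3"])
        d, grads["dec_c1_w"], grads["dec_c1_b"] = \
            nn.conv2d_backward(d, caches["c1"], p["dec_c1_w"])
        d = nn.upsample2_backward(d, caches["u1"])
        d = d.reshape(d.shape[0], -1)
        d = nn.relu_backward(d, caches["r2"])
        d, grads["dec_f2_w"], grads["dec_f2_b"] = \
            nn.linear_backward(d, caches["f2"], p["dec_f2_w"])
        d = nn.relu_backward(d, caches["r1"])
        dcodes, grads["dec_f1_w"], grads["dec_f1_b"] = \
            nn.linear_backward(d, caches["f1"], p["dec_f1_w"])
        return dcodes

    # -- public API ---------------------------------------------------------

    def _to_batch(self, maps) -> np.ndarray:
        arr = np.asarray(maps)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.shape[-1] != self.resolution or arr.shape[-2] != self.resolution:
            raise ValueError(
                f"map resolution {arr.shape[-2:]} does not match the model "
                f"({self.resolution})")
        return np.stack([one_hot(m) for m in arr])

    def encode(self, maps, batch_size: int = 64) -> np.ndarray:
        """Hash codes for one map (-> (hash_len,)) or many (-> (B, hash_len))."""
        single = np.asarray(maps).ndim == 2
        x = self._to_batch(maps)
        codes = np.concatenate([
            self._encode_forward(x[i:i + batch_size])[0]
            for i in range(0, len(x), batch_size)])
        return codes[0] if single else codes

    def decode(self, codes: np.ndarray) -> np.ndarray:
        """Real-valued (H, W, 4) class-score reconstruction(s) of hash code(s)."""
        arr = np.asarray(codes, dtype=np.float32)
        single = arr.ndim == 1
        recon, _ = self._decode_forward(np.atleast_2d(arr))
        return recon[0] if single else recon

    def save(self, path) -> None:
        np.savez(path, resolution=self.resolution, hash_len=self.hash_len,
                 **self.params)

    @classmethod
    def load(cls, path) -> "HashingModel":
        data = np.load(path)
        model = cls(resolution=int(data["resolution"]),
                    hash_len=int(data["hash_len"]))
        model.params = {k: data[k] for k in data.files
                        if k not in ("resolution", "hash_len")}
        return model


def encode(contour_map: ContourMap, model: HashingModel) -> np.ndarray:
    """Hash code (length ``hash_len``) of a contour map."""
    return model.encode(contour_map)


def decode(code: np.ndarray, model: HashingModel) -> np.ndarray:
    """Reconstructed (H, W, 4) class-score image of a hash code."""
    return model.decode(code)


# ---------------------------------------------------------------------------
# triplets and training


def _admissible_negative(query_pose: CameraPose, candidate: CameraPose,
                         cfg: TrainConfig) -> bool:
    t, r = pose_distance(query_pose, candidate)
    return t >= cfg.neg_translation_mm or r >= cfg.neg_rotation_deg


def sample_triplet(db_renders, poses, cfg: TrainConfig,
                   rng: np.random.Generator, max_tries: int = 2000) -> Triplet:
    """Draw one training triplet.

    The query is uniform over the database; the negative is rejection
    sampled until its pose differs from the query's by ≥ 30 mm in position
    or ≥ 30° in rotation; the positive is the augmented query map.
    """
    qi = int(rng.integers(len(poses)))
    ni = None
    for _ in range(max_tries):
        j = int(rng.integers(len(poses)))
        if j != qi and _admissible_negative(poses[qi], poses[j], cfg):
            ni = j
            break
    if ni is None:
        raise DegenerateGridError(
            f"no pose at least {cfg.neg_translation_mm} mm or "
            f"{cfg.neg_rotation_deg}° away from the query after "
            f"{max_tries} draws")
    positive = augment_positive(db_renders[qi], cfg.augment, rng)
    return Triplet(query=db_renders[qi], positive=positive,
                   negative=db_renders[ni], query_pose=poses[qi],
                   negative_pose=poses[ni])


def _batch_losses_and_grads(model: HashingModel, x: np.ndarray,
                            weights: np.ndarray, cfg: TrainConfig):
    """One fused forward/backward pass over a stacked (3B, 4, H, W) batch
    laid out as [queries | positives | negatives]."""
    n = x.shape[0] // 3
    n_pixels = x.shape[1] * x.shape[2]
    codes, enc_caches = model._encode_forward(x)
    recon, dec_caches = model._decode_forward(codes)

    h_q, h_p, h_n = codes[:n], codes[n:2 * n], codes[2 * n:]

    # contrastive
    dqp_v = h_q - h_p
    dqn_v = h_q - h_n
    d_qp = np.sqrt(np.sum(dqp_v ** 2, axis=1) + _EPS)
    d_qn = np.sqrt(np.sum(dqn_v ** 2, axis=1) + _EPS)
    slack = cfg.margin + d_qp - d_qn
    active = slack > 0
    l_c = float(np.mean(np.maximum(slack, 0.0)))
    dcodes = np.zeros_like(codes)
    a = active[:, None] / n
    dcodes[:n] += a * (dqp_v / d_qp[:, None] - dqn_v / d_qn[:, None]) * cfg.w_c
    dcodes[n:2 * n] += a * (-dqp_v / d_qp[:, None]) * cfg.w_c
    dcodes[2 * n:] += a * (dqn_v / d_qn[:, None]) * cfg.w_c

    # binarisation
    absdev = np.abs(codes) - 1.0
    l_b = float(np.sum(absdev ** 2) / n)
    dcodes += cfg.w_b * 2.0 * absdev * np.sign(codes) / n

    # weighted reconstruction
    diff = recon - x
    per_image = weights * np.sum(diff ** 2, axis=(1, 2, 3)) / n_pixels
    l_r = float(np.sum(per_image) / n)
    drecon = (cfg.w_r * 2.0 / (n * n_pixels)) * \
        weights[:, None, None, None] * diff

    grads: dict = {}
    dcodes_total = dcodes.astype(np.float32) + \
        model._decode_backward(drecon.astype(np.float32), dec_caches, grads)
    model._encode_backward(dcodes_total, enc_caches, grads)
    breakdown = total_loss(l_c, l_r, l_b, cfg)
    return breakdown, grads


def train(scene: LiverScene, train_spec: PoseGridSpec, cfg: TrainConfig,
          camera: PinholeCamera | None = None,
          renders=None, poses=None) -> HashingModel:
    """Train a patient-specific hashing model on a pose grid.

    Renders every grid pose once, then runs ``cfg.epochs`` epochs of
    triplet batches (fresh random triplets each step, one step per
    ``cfg.batch`` database entries). The per-epoch mean loss components are
    stored on the returned model as ``training_log`` (a DataFrame). A
    non-finite loss aborts with a diagnostic.
    """
    if camera is None:
        camera = PinholeCamera.default()
    if poses is None:
        poses = enumerate_poses(train_spec, scene)
    if renders is None:
        renders = [render_contour_map(scene, p, camera) for p in poses]
    rng = np.random.default_rng(cfg.seed)
    model = HashingModel(resolution=camera.height, hash_len=cfg.hash_len,
                         seed=cfg.seed)
    optimiser = nn.Adam(model.params, lr=cfg.lr)
    steps_per_epoch = max(1, math.ceil(len(poses) / cfg.batch))
    log_rows = []
    for epoch in range(cfg.epochs):
        sums = np.zeros(4)
        for _ in range(steps_per_epoch):
            triplets = [sample_triplet(renders, poses, cfg, rng)
                        for _ in range(cfg.batch)]
            x = np.stack([one_hot(t.query) for t in triplets]
                         + [one_hot(t.positive) for t in triplets]
                         + [one_hot(t.negative) for t in triplets])
            maps = ([t.query for t in triplets]
                    + [t.positive for t in triplets]
                    + [t.negative for t in triplets])
            weights = np.array([_image_weight(m) for m in maps],
                               dtype=np.float32)
            breakdown, grads = _batch_losses_and_grads(model, x, weights, cfg)
            if not np.isfinite(breakdown.L):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {breakdown}")
            optimiser.step(model.params, grads)
            sums += (breakdown.L_c, breakdown.L_r, breakdown.L_b, breakdown.L)
        log_rows.append([epoch] + list(sums / steps_per_epoch))
    model.training_log = pd.DataFrame(
        log_rows, columns=["epoch", "L_c", "L_r", "L_b", "L"])
    return model


def triplet_accuracy(model: HashingModel, renders, poses, cfg: TrainConfig,
                     rng: np.random.Generator, n: int = 200) -> float:
    """Fraction of fresh triplets with ``D(h_q,h_p) < D(h_q,h_n)``."""
    correct = 0
    for _ in range(n):
        t = sample_triplet(renders, poses, cfg, rng)
        h = model.encode(np.stack([t.query, t.positive, t.negative]))
        if np.linalg.norm(h[0] - h[1]) < np.linalg.norm(h[0] - h[2]):
            correct += 1
    return correct / n
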