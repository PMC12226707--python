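"""Hashing model: loss definitions, triplet sampling, gradients, training."""

import numpy as np
import pytest

from liverhash.hashing import (DegenerateGridError, HashingModel, TrainConfig,
                               _batch_losses_and_grads, binarisation_loss,
                               contrastive_loss, decode, encode,
                               reconstruction_loss, sample_triplet,
                               total_loss)
from liverhash.poses import CameraPose, euler_matrix
from liverhash.rendering import one_hot

# -- independent scalar-loop oracles ----------------------------------------


def _contrastive_oracle(hq, hp, hn, m):
    dqp = sum((a - b) ** 2 for a, b in zip(hq, hp)) ** 0.5
    dqn = sum((a - b) ** 2 for a, b in zip(hq, hn)) ** 0.5
    return max(0.0, m + dqp - dqn)


def _reconstruction_oracle(pairs):
    total = 0.0
    for decoded, original in pairs:
        h, w = original.shape[:2]
        nz = 0
        for i in range(h):
            for j in range(w):
                val = original[i, j]
                if np.any(val != 0):
                    nz += 1
        weight = nz / (h * w)
        sq = 0.0
        for a, b in zip(np.ravel(decoded), np.ravel(original)):
            sq += (float(a) - float(b)) ** 2
        total += weight * sq
    return total / (h * w)


def _binarisation_oracle(codes):
    return sum((abs(float(v)) - 1.0) ** 2 for h in codes for v in h)


class TestContrastiveLoss:

    def test_hand_computed_boundary_cases(self):
        z = np.zeros(64)
        far = np.zeros(64)
        far[0] = 32.0
        assert contrastive_loss(z, z, far, m=32.0) == pytest.approx(0.0)
        assert contrastive_loss(z, z, z, m=32.0) == pytest.approx(32.0)
        hq, hp, hn = np.zeros(3), np.zeros(3), np.zeros(3)
        hp[0], hn[0] = 1.0, 3.0
        assert contrastive_loss(hq, hp, hn, m=1.0) == pytest.approx(0.0)

    def test_matches_scalar_oracle_on_random_codes(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            hq, hp, hn = rng.normal(size=(3, 64))
            m = rng.uniform(0, 40)
            assert contrastive_loss(hq, hp, hn, m) == pytest.approx(
                _contrastive_oracle(hq, hp, hn, m), abs=1e-10)

    def test_is_nonnegative_and_zero_beyond_margin(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            hq, hp, hn = rng.normal(size=(3, 16))
            m = rng.uniform(0, 10)
            val = contrastive_loss(hq, hp, hn, m)
            assert val >= 0.0
            dqp = np.linalg.norm(hq - hp)
            dqn = np.linalg.norm(hq - hn)
            if dqn >= dqp + m:
                assert val == pytest.approx(0.0, abs=1e-12)


class TestReconstructionLoss:

    def test_hand_computed_two_by_two(self):
        original = np.array([[1.0, 0.0], [0.0, 2.0]])
        decoded = np.array([[0.5, 0.0], [1.0, 2.0]])
        # weight 2/4; squared error 0.25 + 1.0; N = 4
        expected = 0.5 * 1.25 / 4.0
        assert reconstruction_loss([(decoded, original)]) == \
            pytest.approx(expected, abs=1e-12)

    def test_perfect_reconstruction_and_empty_originals_give_zero(self):
        x = np.zeros((4, 4))
        assert reconstruction_loss([(x, x)] * 3) == 0.0
        noisy = np.random.default_rng(0).normal(size=(4, 4))
        assert reconstruction_loss([(noisy, x)]) == 0.0  # zero weight

    @pytest.mark.parametrize("size", [2, 8, 32])
    def test_matches_scalar_oracle_on_random_images(self, size):
        rng = np.random.default_rng(size)
        pairs = [(rng.normal(size=(size, size)),
                  (rng.random((size, size)) > 0.6)
                  * rng.integers(1, 5, (size, size)).astype(float))
                 for _ in range(3)]
        assert reconstruction_loss(pairs) == pytest.approx(
            _reconstruction_oracle(pairs), abs=1e-10)

    def test_accepts_label_map_originals_with_onehot_decodings(self):
        rng = np.random.default_rng(3)
        label = rng.integers(0, 5, (8, 8)).astype(np.uint8)
        decoded = rng.normal(size=(8, 8, 4))
        expected = _reconstruction_oracle([(decoded, one_hot(label))])
        assert reconstruction_loss([(decoded, label)]) == \
            pytest.approx(expected, abs=1e-10)


class TestBinarisationLoss:

    def test_signed_unit_codes_give_zero(self):
        h = np.random.default_rng(0).choice([-1.0, 1.0], size=64)
        assert binarisation_loss(h, -h, h) == pytest.approx(0.0)

    def test_zero_codes_give_three_times_length(self):
        z = np.zeros(64)
        assert binarisation_loss(z, z, z) == pytest.approx(192.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            codes = rng.normal(scale=2.0, size=(3, 64))
            assert binarisation_loss(*codes) == pytest.approx(
                _binarisation_oracle(codes), abs=1e-10)


class TestTotalLoss:

    def test_zero_components_and_single_component(self):
        cfg = TrainConfig()
        assert total_loss(0, 0, 0, cfg).L == 0.0
        assert total_loss(1, 0, 0, cfg).L == pytest.approx(10.0)
        assert total_loss(0, 1, 0, cfg).L == pytest.approx(100.0)
        assert total_loss(0, 0, 1, cfg).L == pytest.approx(1.0)

    def test_weights_come_from_the_config(self):
        cfg = TrainConfig(w_c=2.0, w_r=3.0, w_b=5.0)
        out = total_loss(1.0, 1.0, 1.0, cfg)
        assert out.L == pytest.approx(10.0)
        assert (out.L_c, out.L_r, out.L_b) == (1.0, 1.0, 1.0)


@pytest.fixture(scope="module")
def model():
    return HashingModel(resolution=32, hash_len=64, seed=0)


@pytest.fixture(scope="module")
def maps():
    rng = np.random.default_rng(0)
    return (rng.random((3, 32, 32)) < 0.08).astype(np.uint8) * \
        rng.integers(1, 5, (3, 32, 32)).astype(np.uint8)


class TestEncoderDecoder:

    def test_codes_have_hash_length_and_are_deterministic(self, model, maps):
        a = model.encode(maps[0])
        b = model.encode(maps[0])
        assert a.shape == (64,)
        np.testing.assert_array_equal(a, b)

    def test_distinct_maps_get_distinct_codes(self, model, maps):
        codes = model.encode(maps)
        assert np.linalg.norm(codes[0] - codes[1]) > 0
        assert np.linalg.norm(codes[0] - codes[2]) > 0

    def test_decode_shape_matches_the_input_layout(self, model, maps):
        code = encode(maps[0], model)
        recon = decode(code, model)
        assert recon.shape == (32, 32, 4)
        assert np.isfinite(recon).all()
        np.testing.assert_array_equal(recon, decode(code, model))

    def test_resolution_mismatch_is_rejected(self, model):
        with pytest.raises(ValueError):
            model.encode(np.zeros((16, 16), dtype=np.uint8))

    def test_save_load_roundtrip(self, model, maps, tmp_path):
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = HashingModel.load(path)
        np.testing.assert_array_equal(model.encode(maps), loaded.encode(maps))


def test_analytic_gradients_match_finite_differences():
    """Spot-check every layer's gradient against central differences on a
    tiny network (float32: tolerances are loose but diagnostic)."""
    rng = np.random.default_rng(0)
    model = HashingModel(resolution=8, hash_len=16, seed=1)
    cfg = TrainConfig(margin=4.0)
    x = (rng.random((6, 8, 8, 4)) < 0.25).astype(np.float32)
    weights = np.full(6, 0.25, dtype=np.float32)
    _, grads = _batch_losses_and_grads(model, x, weights, cfg)

    def loss():
        bd, _ = _batch_losses_and_grads(model, x, weights, cfg)
        return bd.L

    checked = 0
    for key in ["enc_c1_w", "enc_c3_w", "enc_f1_w", "enc_f2_w",
                "dec_f1_w", "dec_c2_w", "dec_c3_b"]:
        p = model.params[key]
        flat_idx = rng.integers(p.size)
        idx = np.unravel_index(flat_idx, p.shape)
        eps = 1e-2
        old = p[idx]
        p[idx] = old + eps
        lp = loss()
        p[idx] = old - eps
        lm = loss()
        p[idx] = old
        numeric = (lp - lm) / (2 * eps)
        analytic = float(grads[key][idx])
        assert analytic == pytest.approx(numeric, rel=0.15, abs=0.05), key
        checked += 1
    assert checked == 7


class TestTripletSampling:

    @staticmethod
    def _poses_on_a_line(spacing_mm, n=10):
        return [CameraPose(np.array([i * spacing_mm, 0.0, 0.0]), np.eye(3))
                for i in range(n)]

    def test_negative_satisfies_the_distance_rule(self):
        from liverhash.poses import pose_distance
        rng = np.random.default_rng(0)
        poses = [CameraPose(rng.normal(scale=60, size=3),
                            euler_matrix(*rng.uniform(-60, 60, 3)))
                 for _ in range(40)]
        renders = [np.full((8, 8), i % 5, dtype=np.uint8)
                   for i in range(len(poses))]
        cfg = TrainConfig(augment=__import__(
            "liverhash.augment", fromlist=["AugmentConfig"]
        ).AugmentConfig.identity())
        for _ in range(50):
            t = sample_triplet(renders, poses, cfg, rng)
            trans, rot = pose_distance(t.query_pose, t.negative_pose)
            assert trans >= 30.0 or rot >= 30.0

    def test_degenerate_grid_raises(self):
        poses = self._poses_on_a_line(spacing_mm=1.0)  # all within 10 mm/0°
        renders = [np.zeros((8, 8), dtype=np.uint8)] * len(poses)
        with pytest.raises(DegenerateGridError):
            sample_triplet(renders, poses, TrainConfig(),
                           np.random.default_rng(0), max_tries=100)

    def test_fixed_seed_reproduces_triplets(self):
        poses = self._poses_on_a_line(spacing_mm=40.0)
        rng = np.random.default_rng(0)
        renders = [(np.full((8, 8), i % 5, dtype=np.uint8))
                   for i in range(len(poses))]
        cfg = TrainConfig()
        a = sample_triplet(renders, poses, cfg, np.random.default_rng(9))
        b = sample_triplet(renders, poses, cfg, np.random.default_rng(9))
        assert a.query_pose is b.query_pose
        assert a.negative_pose is b.negative_pose
        np.testing.assert_array_equal(a.positive, b.positive)


class TestTraining:

    def test_seeded_training_is_reproducible(self, scene, camera):
        """Two 1-epoch runs from the same seed produce identical logs."""
        from liverhash.hashing import train
        from liverhash.poses import enumerate_poses
        from liverhash.rendering import render_contour_map
        from conftest import grid
        spec = grid(radius=(180, 1, 180), theta=(10, 20, 30),
                    phi=(-30, 60, 30), alpha=(-15, 30, 15))
        poses = enumerate_poses(spec, scene)
        renders = [render_contour_map(scene, p, camera) for p in poses]
        cfg = TrainConfig(epochs=1, seed=3)
        a = train(scene, spec, cfg, camera, renders=renders, poses=poses)
        b = train(scene, spec, cfg, camera, renders=renders, poses=poses)
        assert a.training_log.equals(b.training_log)

    def test_training_reduces_the_objective(self, trained_model):
        log = trained_model.training_log
        assert np.isfinite(log.L).all()
        assert log.L.iloc[-1] < log.L.iloc[0]
        assert log.L_b.iloc[-1] < log.L_b.iloc[0]
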