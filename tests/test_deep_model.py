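import numpy as np
import pytest

from foldear.deep_model import (
    N_PARAMETERS,
    PARAM_SHAPES,
    SheepVGGLite,
    TrainConfig,
    build_model,
    eigencam,
    encode_labels,
    extract_deep_features,
    train,
)
from foldear.spectrograms import bilinear_resize


class TestArchitecture:
    def test_forward_shape_contract(self):
        m = build_model(seed=0)
        x = np.zeros((1, 3, 100, 100), dtype=np.float32)
        acts = m.forward(x, cache=True)
        assert acts["a1"].shape == (1, 16, 100, 100)
        assert acts["p1"].shape == (1, 16, 50, 50)
        assert acts["a2"].shape == (1, 32, 50, 50)
        assert acts["conv2_pooled"].shape == (1, 32, 25, 25)
        assert acts["flat"].shape == (1, 20_000)
        assert acts["fc1"].shape == (1, 128)
        assert acts["fc2"].shape == (1, 3)

    def test_parameter_count(self):
        m = build_model(seed=1)
        per_layer = (3 * 3 * 3 * 16 + 16, 3 * 3 * 16 * 32 + 32, 20_000 * 128 + 128, 128 * 3 + 3)
        assert m.num_parameters() == sum(per_layer) == 2_565_603 == N_PARAMETERS

    def test_serialized_size_below_11_7_mb(self, tmp_path):
        m = build_model(seed=0)
        assert m.serialized_size_bytes() == pytest.approx(10.26e6, rel=0.01)
        p = tmp_path / "model.bin"
        m.save(p)
        assert p.stat().st_size <= 11.7e6

    def test_gradients_match_numerical_differences(self, rng):
        m = SheepVGGLite(seed=3, dtype=np.float64)
        x = rng.random((2, 3, 100, 100))
        y = np.array([0, 2])
        _, grads = m.backward(m.forward(x, cache=True), y)

        def loss_at():
            l, _ = m.backward(m.forward(x, cache=True), y)
            return l

        eps = 1e-6
        for name in PARAM_SHAPES:
            for _ in range(2):
                idx = rng.integers(m.params[name].size)
                old = m.params[name].flat[idx]
                m.params[name].flat[idx] = old + eps
                lp = loss_at()
                m.params[name].flat[idx] = old - eps
                lm = loss_at()
                m.params[name].flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name].flat[idx]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), name


class TestTrainConfig:
    def test_learning_rate_schedule_endpoints_and_interpolation(self):
        cfg = TrainConfig()
        assert cfg.learning_rate(1) == pytest.approx(0.001)
        assert cfg.learning_rate(50) == pytest.approx(0.0001)
        for e in range(1, 51):
            assert cfg.learning_rate(e) == pytest.approx(0.001 - (e - 1) / 49 * 0.0009)
        lrs = [cfg.learning_rate(e) for e in range(1, 51)]
        assert np.all(np.diff(lrs) < 0)


class TestTrain:
    def test_missing_class_raises(self, rng):
        imgs = rng.random((8, 100, 100, 3))
        with pytest.raises(ValueError, match="classes"):
            train(build_model(0), imgs, ["foraging"] * 8, TrainConfig(epochs=1))

    def test_history_and_reproducibility_small(self, rng):
        imgs = np.clip(rng.random((24, 100, 100, 3)), 0, 1)
        labels = ["foraging"] * 8 + ["other"] * 8 + ["rumination"] * 8
        cfg = TrainConfig(epochs=3, seed=11)
        m1, h1 = train(build_model(5), imgs, labels, cfg)
        m2, h2 = train(build_model(5), imgs, labels, cfg)
        assert len(h1) == 3
        assert h1 == h2
        for name in m1.params:
            np.testing.assert_array_equal(m1.params[name], m2.params[name])


class TestDeepFeatures:
    def test_fc1_shape_and_nonnegativity(self, rng):
        m = build_model(seed=2)
        imgs = rng.random((5, 100, 100, 3))
        f1 = extract_deep_features(m, imgs, "FC1")
        assert f1.values.shape == (5, 128)
        assert np.all(f1.values >= 0)

    def test_fc2_shape(self, rng):
        m = build_model(seed=2)
        f2 = extract_deep_features(m, rng.random((4, 100, 100, 3)), "FC2")
        assert f2.values.shape == (4, 3)

    def test_unknown_layer_lists_valid_taps(self, rng):
        with pytest.raises(ValueError, match="FC1, FC2"):
            extract_deep_features(build_model(0), rng.random((1, 100, 100, 3)), "FC3")

    def test_repeated_extraction_identical(self, rng):
        m = build_model(seed=4)
        imgs = rng.random((3, 100, 100, 3))
        a = extract_deep_features(m, imgs, "FC1").values
        b = extract_deep_features(m, imgs, "FC1").values
        np.testing.assert_array_equal(a, b)


class TestSerialization:
    def test_save_load_bit_identical_logits(self, tmp_path, rng):
        m = build_model(seed=6)
        imgs = rng.random((3, 100, 100, 3)).astype(np.float32)
        p = tmp_path / "m.bin"
        m.save(p)
        m2 = SheepVGGLite.load(p)
        np.testing.assert_array_equal(m.predict_logits(imgs), m2.predict_logits(imgs))

    def test_save_twice_byte_identical(self, tmp_path):
        m = build_model(seed=6)
        m.save(tmp_path / "a.bin")
        m.save(tmp_path / "b.bin")
        assert (tmp_path / "a.bin").read_bytes() == (tmp_path / "b.bin").read_bytes()

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "x.bin"
        p.write_bytes(b"garbage")
        with pytest.raises(ValueError, match="not a SheepVGG-Lite"):
            SheepVGGLite.load(p)


class TestEigenCAM:
    class _StubModel:
        """Model stand-in returning fixed conv activations (synthetic)."""

        dtype = np.float32

        def __init__(self, acts):
            self._acts = acts

        def forward(self, x, cache=False):
            return {"conv2_pooled": self._acts}

    def test_all_zero_activations_give_zero_map(self):
        stub = self._StubModel(np.zeros((1, 32, 25, 25)))
        heat = eigencam(stub, np.zeros((100, 100, 3)))
        assert heat.shape == (100, 100)
        assert np.all(heat == 0)

    def test_rank_one_activations_recover_spatial_map(self, rng):
        spatial = rng.random((25, 25))
        channel = rng.random(32) + 0.1
        acts = spatial[None, None] * channel[None, :, None, None]  # rank-1, (1,32,25,25)
        heat = eigencam(self._StubModel(acts), np.zeros((100, 100, 3)))
        expect = bilinear_resize(spatial, 100, 100)
        expect = expect / expect.max()
        np.testing.assert_allclose(heat, expect, atol=1e-8)

    def test_projection_matches_dense_svd_oracle(self, rng):
        acts = np.maximum(rng.standard_normal((1, 32, 25, 25)), 0)
        heat = eigencam(self._StubModel(acts), np.zeros((100, 100, 3)))
        mat = acts[0].transpose(1, 2, 0).reshape(625, 32)
        u, s, vt = np.linalg.svd(mat)
        proj = mat @ vt[0]
        if -proj.min() > proj.max():
            proj = -proj
        oracle = np.maximum(bilinear_resize(np.maximum(proj.reshape(25, 25), 0), 100, 100), 0)
        oracle /= oracle.max()
        np.testing.assert_allclose(heat, oracle, atol=1e-6)

    def test_invariant_to_positive_rescaling(self, rng):
        acts = np.maximum(rng.standard_normal((1, 32, 25, 25)), 0)
        a = eigencam(self._StubModel(acts), np.zeros((100, 100, 3)))
        b = eigencam(self._StubModel(acts * 37.5), np.zeros((100, 100, 3)))
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_range_and_peak_convention(self, rng):
        acts = np.maximum(rng.standard_normal((1, 32, 25, 25)), 0)
        heat = eigencam(self._StubModel(acts), np.zeros((100, 100, 3)))
        assert heat.min() >= 0 and heat.max() == pytest.approx(1.0)


def test_encode_labels_rejects_unknown():
    with pytest.raises(ValueError, match="unknown label"):
        encode_labels(["foraging", "grazing"])
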