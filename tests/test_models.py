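import numpy as np
import pytest

import emodec as em
from emodec import nn
from emodec.errors import ValidationError
from emodec.models import conv_stage_flops, channel_reduction_ratio


def _toy_segments(n=24, p=64, c=4, seed=5, separable=True, effect=4.0):
    """Two classes differing in channel-0 amplitude; learnable in few epochs."""
    rng = np.random.default_rng(seed)
    tensor = rng.standard_normal((n, p, c))
    labels = np.array([0, 1] * (n // 2))
    if separable:
        t = np.arange(p) / 32.0
        burst = np.sin(2 * np.pi * 8 * t)
        tensor[labels == 1, :, 0] += effect * burst
    return em.SegmentSet(
        tensor, labels, np.array(["s"] * n, dtype=object), 32.0, [f"c{i}" for i in range(c)]
    )


class TestArchitectureShapes:
    def test_shallow_layer_arithmetic(self):
        """P=512, C=68: conv length 510, pooled length 121, dense in 40*121."""
        spec = em.ModelSpec(n_channels=68, n_timepoints=512)
        assert spec.pooled_length == (510 - 30) // 4 + 1 == 121
        model = em.build_model(spec)
        dense = model.network.layers[-1]
        assert dense.params[0].shape == (2, 40 * 121)
        x = np.zeros((3, 1, 512, 68))
        out = model.network.forward(x, training=False, rng=np.random.default_rng(0))
        assert out.shape == (3, 2)

    def test_softmax_rows_sum_to_one(self):
        spec = em.ModelSpec(n_channels=8, n_timepoints=64)
        model = em.build_model(spec, seed=3)
        segs = _toy_segments(n=8, c=8)
        probs, labels = em.predict(model, segs)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (8, 2)
        assert set(labels) <= {0, 1}

    def test_all_zero_input_finite(self):
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        model = em.build_model(spec)
        segs = em.SegmentSet(
            np.zeros((2, 64, 4)), np.array([0, 1]), np.array(["s", "s"], dtype=object), 32.0, list("abcd")
        )
        probs, _ = em.predict(model, segs)
        assert np.isfinite(probs).all()

    def test_too_short_p_reports_minimum(self):
        with pytest.raises(ValidationError, match="minimal admissible P is 32"):
            em.ModelSpec(n_channels=4, n_timepoints=16)

    def test_deep_net_instantiates_at_full_density_scale(self):
        spec = em.ModelSpec(n_channels=90, n_timepoints=512, architecture="deep")
        model = em.build_deep_model(spec)
        x = np.zeros((2, 1, 512, 90))
        out = model.network.forward(x, training=False, rng=np.random.default_rng(0))
        assert out.shape == (2, 2)

    def test_deep_has_more_parameters_than_shallow(self):
        shallow = em.build_model(em.ModelSpec(n_channels=32, n_timepoints=512))
        deep = em.build_deep_model(em.ModelSpec(n_channels=32, n_timepoints=512, architecture="deep"))
        assert deep.network.n_parameters() > shallow.network.n_parameters()


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Finite-difference check of the full shallow stack (dropout off)."""
        spec = em.ModelSpec(n_channels=3, n_timepoints=40, n_temporal_filters=4, dropout=0.0)
        rng = np.random.default_rng(0)
        model = em.build_model(spec, seed=1)
        net = model.network
        x = rng.standard_normal((4, 1, 40, 3))
        y = np.array([0, 1, 1, 0])

        def loss_at():
            scores = net.forward(x, training=True, rng=np.random.default_rng(9))
            loss, _ = nn.nll_loss_and_grad(scores, y)
            return loss

        scores = net.forward(x, training=True, rng=np.random.default_rng(9))
        _, grad = nn.nll_loss_and_grad(scores, y)
        net.backward(grad)
        eps = 1e-6
        checked = 0
        for p, g in net.parameters():
            flat_p, flat_g = p.ravel(), g.ravel()
            for idx in range(0, flat_p.size, max(1, flat_p.size // 5)):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss_at()
                flat_p[idx] = orig - eps
                down = loss_at()
                flat_p[idx] = orig
                num = (up - down) / (2 * eps)
                assert num == pytest.approx(flat_g[idx], rel=2e-4, abs=1e-7)
                checked += 1
        assert checked >= 20


class TestTraining:
    def test_learns_separable_problem(self):
        segs = _toy_segments()
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        cfg = em.TrainConfig(epochs=20, seed=2)
        model = em.train(em.build_model(spec), segs, cfg)
        assert model.history[-1]["train_acc"] >= 0.95

    def test_loss_nonincreasing_smoothed(self):
        """On a problem hard enough to need the full budget, the 5-epoch
        smoothed loss trend is monotone downward (small jitter allowed)."""
        segs = _toy_segments(effect=0.8, n=48)
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        model = em.train(em.build_model(spec), segs, em.TrainConfig(epochs=25, seed=2))
        losses = np.array([h["loss"] for h in model.history])
        window_means = losses.reshape(5, 5).mean(axis=1)
        assert (np.diff(window_means) <= 1e-3).all()
        assert window_means[-1] < 0.5 * window_means[0]

    def test_identical_seed_identical_history(self):
        segs = _toy_segments()
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        cfg = em.TrainConfig(epochs=3, seed=11)
        a = em.train(em.build_model(spec), segs, cfg)
        b = em.train(em.build_model(spec), segs, cfg)
        assert a.history == b.history
        for pa, pb in zip(a.network.state(), b.network.state()):
            np.testing.assert_array_equal(pa, pb)

    def test_history_length_equals_epochs(self):
        segs = _toy_segments()
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        model = em.train(em.build_model(spec), segs, em.TrainConfig(epochs=1, seed=0))
        assert len(model.history) == 1

    def test_single_class_rejected(self):
        segs = _toy_segments()
        segs.labels[:] = 1
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        with pytest.raises(ValidationError, match="single class"):
            em.train(em.build_model(spec), segs, em.TrainConfig(epochs=1))


class TestPredict:
    def test_empty_input(self):
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        model = em.build_model(spec)
        empty = em.SegmentSet(
            np.empty((0, 64, 4)), np.empty(0, int), np.empty(0, dtype=object), 32.0, list("abcd")
        )
        probs, labels = em.predict(model, empty)
        assert probs.shape == (0, 2) and labels.shape == (0,)

    def test_mismatched_channels_rejected(self):
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        model = em.build_model(spec)
        with pytest.raises(ValidationError, match="C=4"):
            em.predict(model, _toy_segments(c=5))

    def test_inference_deterministic(self):
        segs = _toy_segments()
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        model = em.train(em.build_model(spec), segs, em.TrainConfig(epochs=2, seed=1))
        p1, l1 = em.predict(model, segs)
        p2, l2 = em.predict(model, segs)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(l1, l2)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        segs = _toy_segments()
        spec = em.ModelSpec(n_channels=4, n_timepoints=64)
        model = em.train(em.build_model(spec), segs, em.TrainConfig(epochs=2, seed=4))
        path = tmp_path / "model.h5"
        em.save_model(model, path)
        back = em.load_model(path)
        assert back.spec == model.spec
        assert len(back.history) == 2
        np.testing.assert_array_equal(em.predict(back, segs)[0], em.predict(model, segs)[0])


class TestFlops:
    def test_linear_in_channels(self):
        spec = em.ModelSpec(n_channels=246, n_timepoints=512)
        f246 = conv_stage_flops(spec)
        for k in (1, 68, 123):
            assert channel_reduction_ratio(spec, k) == pytest.approx(k / 246, rel=1e-12)
            reduced = em.ModelSpec(n_channels=k, n_timepoints=512)
            assert conv_stage_flops(reduced) * 246 == f246 * k
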