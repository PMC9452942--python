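"""The spatially constrained network: architecture, custom layers, loss,
gradient correctness, and desk-scale training behaviour."""

import numpy as np
import pytest

from sccnn.errors import InvalidParameterError, SpecViolationError
from sccnn.network import (
    LayerSpec,
    LossConfig,
    NetworkSpec,
    ParamEstimation,
    SCNNDetector,
    SpatialConstraint,
    TrainConfig,
    build_network,
    epsilon_ratio,
    train_detector,
    weighted_xent_loss,
)
from sccnn.targets import build_probability_map

REFERENCE_SHAPES = [
    (27, 27, 1),
    (24, 24, 36),
    (12, 12, 36),
    (10, 10, 48),
    (5, 5, 48),
    (512,),
    (512,),
    (1, 3),
    (11, 11),
]


class TestNetworkSpec:
    def test_default_spec_chains_to_reference_shapes(self):
        assert NetworkSpec.default().shape_chain() == REFERENCE_SHAPES

    def test_parameter_layer_emits_three_numbers_per_candidate(self):
        spec = NetworkSpec.default(n_candidates=3)
        assert spec.shape_chain()[-2] == (3, 3)

    def test_output_side_is_eleven(self):
        assert NetworkSpec.default().map_shape == (11, 11)

    def test_enlarged_input_scales_by_valid_conv_arithmetic(self):
        layers = list(NetworkSpec.default().layers)
        layers[0] = LayerSpec("input", shape=(55, 55, 1))
        chain = NetworkSpec(tuple(layers)).shape_chain()
        # 55 -> 52 -> 26 -> 24 -> 12, closed-form size recurrence
        assert chain[1] == (52, 52, 36)
        assert chain[4] == (12, 12, 48)

    def test_inconsistent_chain_rejected(self):
        layers = (
            LayerSpec("input", shape=(9, 9, 1)),
            LayerSpec("conv", filter_size=(4, 4), c_out=8),
            LayerSpec("pool"),  # 6x6 -> 3x3
            LayerSpec("pool"),  # odd: must fail
        )
        with pytest.raises(SpecViolationError):
            NetworkSpec(layers).shape_chain()

    def test_forward_shapes_match_chain(self, rng):
        model = build_network(seed=0)
        cands, maps = model.forward(rng.random((3, 27, 27)))
        assert cands.shape == (3, 1, 3)
        assert maps.shape == (3, 11, 11)


class TestParamEstimation:
    def test_zero_weights_give_map_midpoint(self, rng):
        pe = ParamEstimation(16, 1, (11, 11), rng)
        pe.dense.w[...] = 0.0
        pe.dense.b[...] = 0.0
        out = pe.forward(np.ones((1, 16)))
        np.testing.assert_allclose(out[0, 0], [6.0, 6.0, 0.5])

    def test_outputs_bounded_by_construction(self, rng):
        pe = ParamEstimation(8, 2, (11, 11), rng)
        for _ in range(100):
            pe.dense.w[...] = rng.normal(scale=50.0, size=pe.dense.w.shape)
            pe.dense.b[...] = rng.normal(scale=50.0, size=pe.dense.b.shape)
            out = pe.forward(rng.normal(size=(5, 8)))
            assert np.all(out[:, :, 0] >= 1.0) and np.all(out[:, :, 0] <= 11.0)
            assert np.all(out[:, :, 1] >= 1.0) and np.all(out[:, :, 1] <= 11.0)
            assert np.all(out[:, :, 2] >= 0.0) and np.all(out[:, :, 2] <= 1.0)

    def test_gradient_matches_finite_differences(self, rng):
        pe = ParamEstimation(8, 2, (11, 11), rng)
        x = rng.normal(size=(3, 8))
        g = rng.normal(size=(3, 2, 3))
        pe.forward(x)
        dx = pe.backward(g)
        h = 1e-6
        num = np.zeros_like(x)
        for idx in np.ndindex(x.shape):
            for sign in (1, -1):
                xs = x.copy()
                xs[idx] += sign * h
                num[idx] += sign * np.sum(pe.forward(xs) * g)
        num /= 2 * h
        assert np.abs(num - dx).max() < 1e-5


class TestSpatialConstraint:
    def test_unit_height_candidate_reproduces_ground_truth_map(self):
        sc = SpatialConstraint((11, 11), d=4.0)
        cands = np.array([[[6.0, 4.0, 1.0]]])  # 1-based (6,4) -> pixel (5,3)
        predicted = sc.forward(cands)[0]
        truth = build_probability_map([(5.0, 3.0)], (11, 11), d=4.0)
        np.testing.assert_allclose(predicted, truth, atol=1e-12)

    def test_zero_heights_give_zero_map(self, rng):
        sc = SpatialConstraint((11, 11), d=4.0)
        cands = rng.uniform(1, 11, size=(2, 3, 3))
        cands[:, :, 2] = 0.0
        assert not sc.forward(cands).any()

    def test_coincident_candidates_same_as_one(self):
        sc = SpatialConstraint((11, 11), d=4.0)
        single = sc.forward(np.array([[[5.0, 7.0, 0.8]]]))
        double = sc.forward(np.array([[[5.0, 7.0, 0.8], [5.0, 7.0, 0.8]]]))
        np.testing.assert_allclose(single, double, atol=1e-12)

    def test_output_always_within_unit_interval(self, rng):
        sc = SpatialConstraint((11, 11), d=4.0)
        cands = np.stack(
            [rng.uniform([1, 1, 0], [11, 11, 1], size=(4, 3)) for _ in range(8)]
        )
        maps = sc.forward(cands)
        assert maps.min() >= 0.0 and maps.max() <= 1.0

    def test_gradient_matches_finite_differences(self, rng):
        sc = SpatialConstraint((11, 11), d=4.0)
        # keep candidates off the support boundary so the loss is smooth
        cands = np.array(
            [
                [[4.3, 5.2, 0.7], [8.1, 2.6, 0.4]],
                [[6.4, 6.6, 0.9], [3.7, 9.2, 0.2]],
            ]
        )
        g = rng.normal(size=(2, 11, 11))
        sc.forward(cands)
        dc = sc.backward(g)
        h = 1e-6
        num = np.zeros_like(cands)
        for idx in np.ndindex(cands.shape):
            for sign in (1, -1):
                cs = cands.copy()
                cs[idx] += sign * h
                num[idx] += sign * np.sum(sc.forward(cs) * g)
        num /= 2 * h
        assert np.abs(num - dc).max() < 1e-5


class TestLoss:
    def test_zero_when_prediction_equals_binary_target(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        loss = weighted_xent_loss(y, y, LossConfig(epsilon=0.1))
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_half_prediction_on_positive_pixel_is_log_two(self):
        y = np.array([[1.0]])
        yhat = np.array([[0.5]])
        loss = weighted_xent_loss(y, yhat, LossConfig(epsilon=1e-9))
        assert loss == pytest.approx(np.log(2.0), rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            weighted_xent_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_epsilon_ratio_policy(self):
        y = np.zeros((10, 10))
        y[:2, :5] = 0.5  # 10 nonzero of 100
        assert epsilon_ratio(y) == pytest.approx(10 / 90)
        assert epsilon_ratio(np.zeros((5, 5))) == 1e-3  # floor on all-zero batches

    def test_gradient_matches_finite_differences(self, rng):
        y = rng.random((5, 5))
        yhat = rng.uniform(0.05, 0.95, size=(5, 5))
        cfg = LossConfig(epsilon=0.2)
        _, grad = weighted_xent_loss(y, yhat, cfg, return_grad=True)
        h = 1e-6
        num = np.zeros_like(yhat)
        for idx in np.ndindex(yhat.shape):
            for sign in (1, -1):
                ys = yhat.copy()
                ys[idx] += sign * h
                num[idx] += sign * weighted_xent_loss(y, ys, cfg)
        num /= 2 * h
        assert np.abs(num - grad).max() < 1e-5


class TestEndToEndGradients:
    def test_trunk_weight_gradients_match_finite_differences(self, rng):
        model = build_network(seed=7)
        x = rng.random((2, 27, 27))
        y = np.stack(
            [build_probability_map([(5, 5)], (11, 11)), np.zeros((11, 11))]
        )
        cfg = LossConfig(epsilon=0.2)
        model.loss_and_backward(x, y, cfg)
        h = 1e-6
        for param, grad in ((model.trunk[0].w, model.trunk[0].dw),
                            (model.param.dense.w, model.param.dense.dw)):
            for _ in range(5):
                idx = tuple(rng.integers(0, s) for s in param.shape)
                orig = param[idx]
                param[idx] = orig + h
                up = weighted_xent_loss(y, model.forward(x)[1], cfg) / 2
                param[idx] = orig - h
                down = weighted_xent_loss(y, model.forward(x)[1], cfg) / 2
                param[idx] = orig
                assert abs((up - down) / (2 * h) - grad[idx]) < 1e-5


@pytest.fixture(scope="module")
def trained_on_scenes():
    """Detector trained for 30 epochs on patches from 8 synthetic tiles."""
    from sccnn.scenes import SceneSpec, make_training_set

    patches, targets, _, _ = make_training_set(SceneSpec(), n_tiles=8, seed=11)
    model, trace = train_detector(patches, targets, TrainConfig(epochs=30), seed=2)
    return patches, targets, model, trace


class TestTraining:
    def test_loss_decreases(self, trained_on_scenes):
        _, _, _, trace = trained_on_scenes
        assert trace[-1] < trace[0]

    def test_same_seed_gives_bitwise_identical_traces(self, trained_on_scenes):
        patches, targets, _, _ = trained_on_scenes
        _, a = train_detector(patches, targets, TrainConfig(epochs=2), seed=5)
        _, b = train_detector(patches, targets, TrainConfig(epochs=2), seed=5)
        assert a == b

    def test_empty_training_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            train_detector(np.zeros((0, 27, 27)), np.zeros((0, 11, 11)))

    def test_recovers_candidate_center_on_held_out_patches(self, trained_on_scenes):
        from sccnn.scenes import SceneSpec, hematoxylin_channel, simulate

        _, _, model, _ = trained_on_scenes
        errors = []
        for i in range(3):
            scene = simulate(SceneSpec(), seed=900 + i)
            conc = hematoxylin_channel(scene)
            for rec in scene.records:
                tr, tc = int(round(rec.row)) - 13, int(round(rec.col)) - 13
                if tr < 0 or tc < 0 or tr + 27 > 71 or tc + 27 > 71:
                    continue
                cands, _ = model.forward(conc[tr : tr + 27, tc : tc + 27][None])
                u, v, _ = cands[0, 0]
                errors.append(np.hypot(u - 1 - (rec.row - tr - 8), v - 1 - (rec.col - tc - 8)))
        assert np.mean(errors) < 1.0


class TestInferenceAndCheckpoints:
    def test_sliding_window_covers_interior(self):
        model = build_network(seed=0)
        prob = model.predict_image(np.zeros((71, 71)))
        assert prob.shape == (71, 71)

    def test_image_smaller_than_window_rejected(self):
        model = build_network(seed=0)
        with pytest.raises(InvalidParameterError):
            model.predict_image(np.zeros((20, 20)))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_network(seed=3)
        path = tmp_path / "detector.npz"
        model.save(path)
        loaded = SCNNDetector.load(path)
        x = rng.random((2, 27, 27))
        np.testing.assert_array_equal(model.predict_map(x), loaded.predict_map(x))
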