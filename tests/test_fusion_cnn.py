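"""Three-branch late-fusion CNN regressor."""

import numpy as np
import pytest

from uwbanthro import fusion_cnn as fc
from uwbanthro.signal_sim import ConfigurationError

from conftest import MiniImageSet, make_synthetic_cnn_dataset

SMALL = fc.NetworkSpec(depth=1, n_filters=4, fc_out=16, input_shape=(24, 24, 3))


def small_inputs(rng, batch=4, spec=SMALL):
    h, w, c = spec.input_shape
    return [rng.normal(size=(batch, h, w, c)).astype(np.float32)
            for _ in range(spec.n_branches)]


class TestBuildNetwork:
    def test_table_architecture_layer_counts(self):
        spec = fc.NetworkSpec(depth=3, n_filters=16, fc_out=1024)
        net = fc.build_network(spec, seed=0)
        assert len(net.branches) == 3
        for layers in net.branches:
            convs = [l for l in layers if isinstance(l, fc._Conv)]
            assert len(convs) == 3

    def test_forward_gives_single_finite_scalar_per_item(self):
        net = fc.build_network(SMALL, seed=0)
        out = net.forward(small_inputs(np.random.default_rng(0), batch=5))
        assert out.shape == (5,)
        assert np.all(np.isfinite(out))

    def test_parameter_count_matches_hand_count(self):
        # 1 branch, depth 1, 1 filter, (8,8,3) input: conv 3*3*3*1+1 = 28;
        # conv out 6x6 -> pool 3x3 -> flatten 9; fc 9*2+2 = 20; head 2+1 = 3
        spec = fc.NetworkSpec(n_branches=1, depth=1, n_filters=1, fc_out=2,
                              input_shape=(8, 8, 3))
        assert spec.parameter_count() == 28 + 20 + 3
        assert fc.build_network(spec, seed=0).parameter_count() == 51

    def test_excessive_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            fc.build_network(fc.NetworkSpec(depth=5, input_shape=(24, 24, 3)))

    def test_gradients_match_finite_differences(self):
        spec = fc.NetworkSpec(n_branches=2, depth=2, n_filters=2, fc_out=3,
                              input_shape=(14, 15, 3))
        net = fc.build_network(spec, seed=0)
        rng = np.random.default_rng(1)
        xs = [rng.normal(size=(3, 14, 15, 3)).astype(np.float32) for _ in range(2)]
        y = rng.normal(size=3).astype(np.float32)
        pred = net.forward(xs)
        grads = net.backward((2.0 / 3) * (pred - y))
        params = net.parameters()
        # directional derivative along a random direction: robust to the
        # float32 roundoff that plagues single-entry finite differences
        vs = [rng.normal(size=p.shape).astype(np.float32) for p in params]
        analytic = sum(float(np.sum(g * v)) for g, v in zip(grads, vs))
        eps = 1e-3
        for p, v in zip(params, vs):
            p += eps * v
        l1 = float(np.mean((net.forward(xs) - y) ** 2))
        for p, v in zip(params, vs):
            p -= 2 * eps * v
        l2 = float(np.mean((net.forward(xs) - y) ** 2))
        numeric = (l1 - l2) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=0.02)


class TestSplitDataset:
    def test_protocol_split_is_270_90(self):
        ds = make_synthetic_cnn_dataset(360, side=4, seed=0, n_subjects=45)
        tr, va = fc.split_dataset(ds, train_frac=0.75, seed=1, mode="acquisition")
        assert (len(tr), len(va)) == (270, 90)

    def test_subject_mode_has_no_leakage(self):
        ds = make_synthetic_cnn_dataset(40, side=4, seed=0, n_subjects=10)
        tr, va = fc.split_dataset(ds, seed=2, mode="subject")
        assert set(tr.subject_ids).isdisjoint(va.subject_ids)
        assert len(tr) + len(va) == 40

    def test_same_seed_same_split(self):
        ds = make_synthetic_cnn_dataset(24, side=4, seed=0, n_subjects=6)
        a = fc.split_dataset(ds, seed=3, mode="acquisition")
        b = fc.split_dataset(ds, seed=3, mode="acquisition")
        assert a[0].subject_ids == b[0].subject_ids

    def test_bad_fraction_rejected(self):
        ds = make_synthetic_cnn_dataset(8, side=4, seed=0)
        with pytest.raises(ConfigurationError):
            fc.split_dataset(ds, train_frac=1.5)


class TestTrain:
    def test_loss_decreases_on_learnable_synthetic_set(self):
        ds = make_synthetic_cnn_dataset(40, side=24, seed=5)
        net = fc.build_network(SMALL, seed=0)
        model = fc.train(net, ds, fc.TrainHyper(epochs=12, seed=0))
        assert model.history[-1] < model.history[0]

    def test_zero_learning_rate_freezes_parameters(self):
        ds = make_synthetic_cnn_dataset(16, side=24, seed=1)
        net = fc.build_network(SMALL, seed=0)
        before = [p.copy() for p in net.parameters()]
        model = fc.train(net, ds, fc.TrainHyper(learning_rate=0.0, epochs=3, seed=0))
        assert all(np.array_equal(a, b)
                   for a, b in zip(before, net.parameters()))
        assert np.allclose(model.history, model.history[0])

    def test_seeded_determinism(self):
        ds = make_synthetic_cnn_dataset(16, side=24, seed=1)
        m1 = fc.train(fc.build_network(SMALL, seed=4), ds,
                      fc.TrainHyper(epochs=3, seed=4))
        m2 = fc.train(fc.build_network(SMALL, seed=4), ds,
                      fc.TrainHyper(epochs=3, seed=4))
        assert m1.history == m2.history

    def test_history_length_equals_epochs(self):
        ds = make_synthetic_cnn_dataset(10, side=24, seed=2)
        model = fc.train(fc.build_network(SMALL, seed=0), ds,
                         fc.TrainHyper(epochs=5, seed=0))
        assert len(model.history) == 5

    def test_partial_final_minibatch_is_kept(self):
        # 10 items at batch 8 -> batches of 8 and 2; must train, not raise
        ds = make_synthetic_cnn_dataset(10, side=24, seed=2)
        model = fc.train(fc.build_network(SMALL, seed=0), ds,
                         fc.TrainHyper(epochs=1, seed=0))
        assert np.isfinite(model.history[0])

    def test_capacity_overfits_small_set(self):
        """The network can drive training RMSE below 5% of target SD."""
        ds = make_synthetic_cnn_dataset(16, side=24, seed=7)
        spec = fc.NetworkSpec(depth=1, n_filters=8, fc_out=32,
                              input_shape=(24, 24, 3))
        model = fc.train(fc.build_network(spec, seed=0), ds,
                         fc.TrainHyper(epochs=200, seed=0))
        # normalized-target MSE < 0.05^2 means RMSE < 5% of the SD
        assert min(model.history) < 0.05 ** 2


class TestPredict:
    def test_duplicate_inputs_get_identical_outputs(self):
        ds = make_synthetic_cnn_dataset(8, side=24, seed=3)
        model = fc.train(fc.build_network(SMALL, seed=0), ds,
                         fc.TrainHyper(epochs=1, seed=0))
        item = ds.items[0][0]
        out = fc.predict(model, [item, item])
        assert out[0] == out[1]

    def test_denormalization_round_trip(self):
        model = fc.TrainedModel(network=None, target_mean=62.2, target_sd=12.0)
        z = (np.array([70.0]) - model.target_mean) / model.target_sd
        assert z * model.target_sd + model.target_mean == pytest.approx(70.0)

    def test_shape_mismatch_rejected(self):
        ds = make_synthetic_cnn_dataset(8, side=24, seed=3)
        model = fc.train(fc.build_network(SMALL, seed=0), ds,
                         fc.TrainHyper(epochs=1, seed=0))
        rng = np.random.default_rng(0)
        bad = MiniImageSet([rng.integers(0, 255, (10, 10, 3)).astype(np.uint8)
                            for _ in range(3)])
        with pytest.raises(Exception):
            fc.predict(model, [bad])


class TestBranchWiring:
    def test_branch_weights_are_not_shared(self):
        net = fc.build_network(SMALL, seed=0)
        w0 = net.branches[0][0].W
        w1 = net.branches[1][0].W
        assert not np.array_equal(w0, w1)

    def test_permuting_sensor_order_changes_prediction(self):
        net = fc.build_network(SMALL, seed=0)
        xs = small_inputs(np.random.default_rng(2), batch=2)
        base = net.forward(xs)
        permuted = net.forward([xs[1], xs[2], xs[0]])
        assert not np.allclose(base, permuted)


class TestSweep:
    def test_single_cell_matches_direct_training(self):
        ds = make_synthetic_cnn_dataset(24, side=24, seed=6, n_subjects=8)
        hyper = fc.TrainHyper(epochs=2, seed=0)
        table = fc.sweep_architectures(ds, depths=[1], filters=[4], fc_widths=[16],
                                       hyper=hyper, seed=0,
                                       input_shape=(24, 24, 3))
        tr, va = fc.split_dataset(ds, seed=0, mode="subject")
        spec = fc.NetworkSpec(depth=1, n_filters=4, fc_out=16,
                              input_shape=(24, 24, 3))
        model = fc.train(fc.build_network(spec, seed=0), tr, hyper)
        est = fc.predict(model, [s for s, _ in va.items])
        from uwbanthro import metrics as m
        assert table.loc[0, "rmse"] == pytest.approx(m.rmse(est, va.targets()))

    def test_row_count_equals_grid_size(self):
        ds = make_synthetic_cnn_dataset(16, side=24, seed=6, n_subjects=8)
        table = fc.sweep_architectures(ds, depths=[1, 2], filters=[2, 4],
                                       fc_widths=[8],
                                       hyper=fc.TrainHyper(epochs=1, seed=0),
                                       seed=0, input_shape=(24, 24, 3))
        assert len(table) == 4

    def test_empty_grid_rejected(self):
        ds = make_synthetic_cnn_dataset(8, side=24, seed=6)
        with pytest.raises(ConfigurationError):
            fc.sweep_architectures(ds, depths=[], filters=[], fc_widths=[])
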