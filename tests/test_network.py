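import numpy as np
import pytest

from alm import (
    ALMConfig,
    ALMNetwork,
    MultivariateSeries,
    build_delay_matrix,
    collect_step_estimates,
    consistency_residual,
    consistent_phase,
    ensemble_predict,
    fit_predict,
    fuse_estimates,
    init_network,
    make_training_set,
    normalize_series,
    pairwise_phase,
    predict_multistep,
    train_alm,
)
from alm.network import StepEstimates


def _constant_series(n=4, M=10, value=3.0):
    vals = np.full((n, M), value) + np.arange(n)[:, None]  # distinct constants
    return MultivariateSeries(vals, [f"v{i}" for i in range(n)])


class TestInit:
    def test_same_seed_same_parameters(self, light_config):
        a = init_network(5, light_config)
        b = init_network(5, light_config)
        assert a.parameter_checksum() == b.parameter_checksum()

    def test_empty_hidden_gives_direct_linear_map(self):
        cfg = ALMConfig(L=3, hidden_sizes=())
        net = init_network(7, cfg)
        assert len(net.weights) == 1
        assert net.weights[0].shape == (7, 3)

    @pytest.mark.parametrize("L", [2, 5])
    def test_output_width_is_L(self, L):
        net = init_network(4, ALMConfig(L=L, hidden_sizes=(8,)))
        assert net.forward(np.zeros((3, 4))).shape == (3, L)


class TestPairwisePhase:
    def test_masked_cells_carry_no_gradient(self, small_series, light_config):
        """Altering label values under the unknown mask must not change training."""
        delay = build_delay_matrix(small_series, 0, light_config.L)
        normed, _ = normalize_series(small_series)
        a = make_training_set(normed, build_delay_matrix(normed, 0, light_config.L))
        b = make_training_set(normed, build_delay_matrix(normed, 0, light_config.L))
        b.labels = np.where(b.label_mask, b.labels, 123.0)  # poison unknown cells
        net_a = pairwise_phase(init_network(5, light_config), a, light_config)
        net_b = pairwise_phase(init_network(5, light_config), b, light_config)
        assert net_a.parameter_checksum() == net_b.parameter_checksum()

    def test_constant_target_converges_to_constant(self, light_config):
        series = _constant_series()
        net = train_alm(series, 0, light_config)
        losses = [e["loss"] for e in net.training_log if e["phase"] == "pairwise"]
        assert losses[-1] <= losses[0]
        assert losses[-1] < 1e-4

    def test_linear_fixture_fits_known_cells(self, linear_fixture):
        series, _ = linear_fixture
        # the delay map of a linear system is itself linear: a direct linear
        # readout must drive the known-cell error to ~0 in phase 1 alone
        cfg = ALMConfig(L=4, horizon=3, dropout_p=0.0, hidden_sizes=(), seed=2,
                        learning_rate=1e-2, epochs_pairwise=3000, epochs_consistent=300)
        normed, _ = normalize_series(series)
        delay = build_delay_matrix(normed, 0, cfg.L)
        train = make_training_set(normed, delay)
        net = pairwise_phase(init_network(series.n, cfg), train, cfg)
        Y = net.forward(train.inputs).T
        mse = np.mean((Y[train.label_mask] - train.labels[train.label_mask]) ** 2)
        assert mse < 1e-3


class TestConsistencyResidual:
    def test_zero_weight_network_has_zero_residual(self, small_series):
        cfg = ALMConfig(L=3, hidden_sizes=(8,))
        net = init_network(5, cfg)
        for W in net.weights:
            W[:] = 0.0
        assert consistency_residual(net, small_series) == 0.0

    def test_L1_is_zero_by_convention(self, small_series):
        net = init_network(5, ALMConfig(L=3, hidden_sizes=(8,)))
        assert consistency_residual(net, small_series, L=1) == 0.0

    def test_matches_brute_force_double_loop(self, small_series):
        L = 4
        net = init_network(5, ALMConfig(L=L, hidden_sizes=(8,), seed=9))
        res = consistency_residual(net, small_series)
        Y = net.forward(small_series.values.T)  # no stats attached
        M = small_series.M
        diffs = []
        for i in range(2, L + 1):  # 1-based delay row
            for j in range(1, M):  # 1-based time, needs j+1 <= M
                diffs.append(Y[j - 1, i - 1] - Y[j, i - 2])
        brute = np.sqrt(np.mean(np.square(diffs)))
        assert res == pytest.approx(brute, rel=1e-12)


class TestConsistentPhase:
    def test_zero_lambda_has_no_penalty_term(self, small_series, light_config):
        from dataclasses import replace

        cfg = replace(light_config, consistency_weight=0.0)
        normed, _ = normalize_series(small_series)
        train = make_training_set(normed, build_delay_matrix(normed, 0, cfg.L))
        net = pairwise_phase(init_network(5, cfg), train, cfg)
        net = consistent_phase(net, train, cfg)
        logs = [e for e in net.training_log if e["phase"] == "consistent"]
        assert all(e["loss"] == e["data"] for e in logs)

    def test_residual_decreases_with_penalty(self, linear_fixture):
        series, _ = linear_fixture
        cfg = ALMConfig(L=4, horizon=3, seed=5, hidden_sizes=(32,),
                        epochs_pairwise=800, epochs_consistent=800,
                        consistency_weight=1000.0, rehearsal_diagonals=0)
        normed, stats = normalize_series(series)
        train = make_training_set(normed, build_delay_matrix(normed, 0, cfg.L))
        net = init_network(series.n, cfg)
        net.stats = stats
        net.target_index = 0
        pairwise_phase(net, train, cfg)
        before = consistency_residual(net, series)
        consistent_phase(net, train, cfg)
        after = consistency_residual(net, series)
        assert after <= before


class TestStepEstimates:
    @pytest.fixture()
    def trained(self, small_series, light_config):
        return train_alm(small_series, 0, light_config)

    def test_h_Lminus1_single_estimate_from_last_row(self, trained, small_series):
        L, M = trained.config.L, small_series.M
        est = collect_step_estimates(trained, small_series, L - 1)
        assert len(est.entries) == 1
        i, j, _ = est.entries[0]
        assert (i, j) == (L, M)

    def test_h1_estimate_family(self, trained, small_series):
        est = collect_step_estimates(trained, small_series, 1)
        # L=4: rows 2..4 at columns M, M-1, M-2
        M = small_series.M
        assert [(i, j) for (i, j, _) in est.entries] == [(2, M), (3, M - 1), (4, M - 2)]

    def test_matches_brute_force_grid_enumeration(self, trained, small_series):
        L, M = trained.config.L, small_series.M
        for h in range(1, L):
            est = collect_step_estimates(trained, small_series, h)
            expected = sorted(
                (i, j)
                for i in range(2, L + 1)
                for j in range(1, M + 1)
                if i + j - 1 == M + h
            )
            assert sorted((i, j) for (i, j, _) in est.entries) == expected

    def test_h_out_of_range_rejected(self, trained, small_series):
        with pytest.raises(ValueError):
            collect_step_estimates(trained, small_series, trained.config.L)


class TestFusion:
    def _est(self, values):
        return StepEstimates(
            step=1, time_index=11,
            entries=[(i + 2, 9 - i, v) for i, v in enumerate(values)],
        )

    def test_uniform_is_mean(self):
        assert fuse_estimates(self._est([2.0, 4.0]), "uniform") == 3.0

    def test_single_estimate_either_mode(self):
        assert fuse_estimates(self._est([7.0]), "uniform") == 7.0
        err = np.full(10, 0.5)
        assert fuse_estimates(self._est([7.0]), "error_weighted", err) == 7.0

    def test_weights_sum_to_one_and_weighted_mean(self):
        est = self._est([4.0, 8.0])
        # rows 2 and 3; make row 2 errors smaller -> larger weight
        err = np.array([1.0, 0.1, 0.3, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        fused = fuse_estimates(est, "error_weighted", err)
        assert est.weights.sum() == pytest.approx(1.0)
        w = est.weights
        assert fused == pytest.approx(w[0] * 4.0 + w[1] * 8.0)
        assert w[0] > w[1]

    def test_hand_computed_weighted_mean(self):
        est = self._est([4.0, 8.0])
        est.weights = np.array([0.75, 0.25])
        assert float(est.weights @ [4.0, 8.0]) == 5.0

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            fuse_estimates(StepEstimates(step=1, time_index=1, entries=[]), "uniform")


class TestPredictMultistep:
    def test_constant_series_predicts_constant(self):
        series = _constant_series(value=6.0)
        # refinement off: per-step Adam restarts bounce around the exact
        # minimum at learning-rate amplitude, masking the fixed point
        cfg = ALMConfig(L=4, horizon=3, hidden_sizes=(16,), seed=0,
                        epochs_pairwise=3000, epochs_consistent=2000,
                        refit_epochs=0, refine_epochs=0)
        res = fit_predict(series, 1, cfg)
        assert np.allclose(res.values, 7.0, atol=1e-6)  # variable 1 constant at 6+1

    def test_horizon_beyond_L_rejected(self, small_series, light_config):
        from dataclasses import replace

        cfg = replace(light_config, horizon=light_config.L)
        net = train_alm(small_series, 0, replace(cfg, horizon=1))
        with pytest.raises(ValueError, match="enlarge L"):
            predict_multistep(net, small_series, cfg)

    def test_zero_refinement_equals_plain_fused_estimates(self, small_series, light_config):
        from dataclasses import replace

        cfg = replace(light_config, refine_epochs=0)
        net = train_alm(small_series, 0, cfg)
        res = predict_multistep(net, small_series)
        for h in range(1, cfg.horizon + 1):
            est = collect_step_estimates(net, small_series, h)
            fused = fuse_estimates(est, cfg.fusion_mode, net.row_rmse)
            assert res.values[h - 1] == pytest.approx(fused, rel=1e-12)

    def test_prediction_times_continue_the_series(self, small_series, light_config):
        res = fit_predict(small_series, 0, light_config)
        expected = small_series.start_time + small_series.tau * (
            small_series.M + np.arange(light_config.horizon)
        )
        assert np.allclose(res.times, expected)


class TestEnsemble:
    def test_deterministic_and_seed_sorted(self, small_series, light_config):
        a = ensemble_predict(small_series, 0, light_config, k=3)
        b = ensemble_predict(small_series, 0, light_config, k=3)
        assert np.array_equal(a.trajectories, b.trajectories)
        assert a.seeds == [light_config.seed + i for i in range(3)]

    def test_identical_members_give_zero_sd(self, small_series, light_config):
        res = fit_predict(small_series, 0, light_config)
        stacked = np.vstack([res.values, res.values])
        assert np.all(stacked.std(axis=0) == 0.0)

    def test_needs_at_least_two_members(self, small_series, light_config):
        with pytest.raises(ValueError):
            ensemble_predict(small_series, 0, light_config, k=1)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, small_series, light_config):
        net = train_alm(small_series, 0, light_config)
        path = tmp_path / "model.json"
        net.save(path)
        back = ALMNetwork.load(path)
        X = np.random.default_rng(0).normal(size=(4, 5))
        assert np.allclose(net.forward(X), back.forward(X), atol=1e-12)
        assert back.target_index == net.target_index
        assert np.allclose(back.row_rmse, net.row_rmse)
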