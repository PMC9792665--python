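import numpy as np
import pytest

from trunksyn import (EstimatorConfig, MTU, MuscleGeometrySeries,
                      StaticOptimization, SynergySet, TrunkActivationModel,
                      TrunkModel, activations_from_weights, cost_activation,
                      cost_activation_deviation, cost_moment_tracking,
                      cost_weight_deviation, extract_synergies, joint_moments,
                      normalize_activations, subtract_muscle_moments)
from trunksyn.estimator import InfeasibleFrameError
from trunksyn.evaluation import pearson_mean_curves


class TestActivationsFromWeights:
    def test_zero_weights_zero_activations(self):
        H = np.random.default_rng(0).random((3, 10))
        assert activations_from_weights(np.zeros((5, 3)), H).max() == 0.0

    def test_single_synergy_scales_peak(self):
        H = np.array([[0.2, 1.0, 0.5]])
        a = activations_from_weights(np.array([[0.6]]), H)
        assert a.max() == pytest.approx(0.6)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(1)
        w, H = rng.random((4, 3)), rng.random((3, 7))
        a = activations_from_weights(w, H)
        for t in range(7):
            for i in range(4):
                assert a[t, i] == pytest.approx(w[i] @ H[:, t])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            activations_from_weights(np.ones((2, 3)), np.ones((4, 5)))


class TestCostTerms:
    """Each term is 1 when every deviation equals its allowance, 0 at the
    ideal solution."""

    def test_moment_tracking_zero_and_unit(self):
        m = np.random.default_rng(2).random((4, 3))
        assert cost_moment_tracking(m, m, 5.0) == 0.0
        assert cost_moment_tracking(m + 5.0, m, 5.0) == pytest.approx(1.0)

    def test_moment_tracking_matches_direct_sum(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((4, 3)), rng.random((4, 3))
        direct = np.sum(((a - b) / 5.0) ** 2) / 12
        assert cost_moment_tracking(a, b, 5.0) == pytest.approx(direct)

    def test_activation_zero_unit_and_arithmetic(self):
        assert cost_activation(np.zeros((3, 2)), 0.5) == 0.0
        assert cost_activation(np.full((3, 2), 0.5), 0.5) == pytest.approx(1.0)
        assert cost_activation(np.array([[0.5]]), 0.25) == pytest.approx(4.0)

    def test_activation_deviation_zero_and_unit(self):
        grouping = {("ES", "right"): [0, 1]}
        same = np.tile([[0.3, 0.3]], (5, 1))
        assert cost_activation_deviation(same, grouping, 0.05) == 0.0
        split = np.array([[0.5, 0.6]])  # deviations +/-0.05
        assert cost_activation_deviation(split, grouping,
                                         0.05) == pytest.approx(1.0)

    def test_activation_deviation_matches_direct_sum(self):
        rng = np.random.default_rng(4)
        a = rng.random((6, 5))
        grouping = {"g1": [0, 1, 2], "g2": [3, 4]}
        direct = 0.0
        for members in grouping.values():
            block = a[:, members]
            mean = block.mean(axis=1, keepdims=True)
            direct += np.sum(((block - mean) / 0.05) ** 2) / (
                6 * len(members))
        assert cost_activation_deviation(a, grouping, 0.05) == pytest.approx(
            direct)

    def test_weight_deviation_zero_unit_and_oracle(self):
        grouping = {"g": [0, 1]}
        same = np.array([[0.2, 0.4], [0.2, 0.4]])
        assert cost_weight_deviation(same, grouping, 0.05) == 0.0
        w = np.array([[0.10], [0.20]])
        assert cost_weight_deviation(w, grouping, 0.05) == pytest.approx(1.0)
        rng = np.random.default_rng(5)
        w = rng.random((4, 3))
        grouping = {"a": [0, 1], "b": [2, 3]}
        direct = 0.0
        for members in grouping.values():
            block = w[members].T
            mean = block.mean(axis=1, keepdims=True)
            direct += np.sum(((block - mean) / 0.05) ** 2) / (
                3 * len(members))
        assert cost_weight_deviation(w, grouping, 0.05) == pytest.approx(
            direct)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cost_activation_deviation(np.ones((2, 2)), {"g": []}, 0.05)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            cost_moment_tracking(np.array([[np.nan]]), np.zeros((1, 1)))


class TestSubtractMuscleMoments:
    def _model(self, n=3, seed=6):
        rng = np.random.default_rng(seed)
        lmt = 0.30 + 0.01 * rng.random((4, n))
        arms = 0.05 * rng.standard_normal((4, n, 3))
        mtus = [MTU(f"p{i}", "ES", "right", 300.0, 0.10, 0.20)
                for i in range(n)]
        return TrunkModel(mtus, MuscleGeometrySeries(
            lmt, arms, ["a", "b", "c"]))

    def test_zero_subset_leaves_moments(self):
        model = self._model()
        m = np.random.default_rng(7).random((4, 3))
        out = subtract_muscle_moments(m, np.zeros((4, 3)), model)
        np.testing.assert_allclose(out, m)

    def test_full_subset_gives_zero_residual(self):
        model = self._model()
        a = np.random.default_rng(8).random((4, 3))
        m = joint_moments(a, model)
        np.testing.assert_allclose(subtract_muscle_moments(m, a, model),
                                   0.0, atol=1e-12)

    def test_matches_independent_difference(self):
        model = self._model(seed=9)
        rng = np.random.default_rng(10)
        m_total = rng.random((4, 3))
        a = rng.random((4, 3))
        expected = m_total - joint_moments(a, model)
        np.testing.assert_allclose(
            subtract_muscle_moments(m_total, a, model), expected)


def _two_mtu_instance():
    """2 MTUs, 1 synergy, 1 DoF, 3 samples; both MTUs in one group."""
    lmt = np.full((3, 2), 0.30)
    arms = np.zeros((3, 2, 1))
    arms[:, 0, 0] = 0.05
    arms[:, 1, 0] = 0.04
    mtus = [MTU("a", "ES", "right", 400.0, 0.10, 0.20),
            MTU("b", "ES", "right", 300.0, 0.10, 0.20)]
    model = TrunkModel(mtus, MuscleGeometrySeries(lmt, arms, ["ext"]))
    H = np.array([[1.0, 0.6, 0.2]])
    return model, H


class TestSynEstimator:
    def test_zero_moments_give_zero_weights(self, tiny_dataset):
        ds = tiny_dataset
        syns = {}
        for side in ("right", "left"):
            s = extract_synergies(ds.leg_activations[side][0], 3,
                                  restarts=5, seed=1, side=side)
            syns[side] = normalize_activations(s)
        cfg = EstimatorConfig(n_syn=3, allow_a=0.25)
        fit = TrunkActivationModel(ds.model,
                                   np.zeros_like(ds.m_id_clean), syns,
                                   cfg).fit()
        assert np.abs(fit.w_est).max() <= 1e-3

    def test_tiny_instance_matches_grid_search(self):
        model, H = _two_mtu_instance()
        m_id = np.array([[8.0], [5.0], [1.5]])
        cfg = EstimatorConfig(n_syn=1, allow_a=0.5)
        syn = {"right": SynergySet(np.ones((2, 1)), H, side="right")}
        fit = TrunkActivationModel(model, m_id, syn, cfg).fit()

        grouping = model.grouping
        grid = np.arange(0.0, 1.0 + 1e-9, 0.005)

        def objective(w0, w1):
            w = np.array([[w0], [w1]])
            a = (w @ H).T
            m = joint_moments(a, model)
            return (cost_moment_tracking(m, m_id, cfg.allow_dm)
                    + cost_activation(a, cfg.allow_a)
                    + cost_activation_deviation(a, grouping, cfg.allow_da)
                    + cost_weight_deviation(w, grouping, cfg.allow_dw))

        values = np.array([[objective(w0, w1) for w1 in grid]
                           for w0 in grid])
        i, j = np.unravel_index(np.argmin(values), values.shape)
        assert abs(fit.w_est[0, 0] - grid[i]) <= 0.005
        assert abs(fit.w_est[1, 0] - grid[j]) <= 0.005
        assert fit.costs["total"] <= values[i, j] + 1e-9

    def test_noiseless_recovery(self, tiny_dataset):
        ds = tiny_dataset
        syns = {}
        for side in ("right", "left"):
            s = extract_synergies(ds.leg_activations[side][0], 3,
                                  restarts=10, seed=2, side=side)
            syns[side] = normalize_activations(s)
        fit = TrunkActivationModel(ds.model, ds.m_id[0], syns,
                                   EstimatorConfig(n_syn=3)).fit()
        assert fit.moment_rmse().max() <= 0.5
        gm = fit.group_mean_activations()
        rs = [pearson_mean_curves(gm[key],
                                  ds.trunk_true_activations[:, mem].mean(
                                      axis=1))
              for key, mem in ds.model.grouping.items()
              if ds.trunk_true_activations[:, mem].mean(axis=1).std() > 1e-6
              and gm[key].std() > 1e-9]
        assert np.mean(rs) >= 0.95

    def test_constraints_and_cost_decomposition(self, noisy_dataset):
        ds = noisy_dataset
        syns = {}
        for side in ("right", "left"):
            s = extract_synergies(ds.leg_activations[side][0], 3,
                                  restarts=5, seed=3, side=side)
            syns[side] = normalize_activations(s)
        fit = TrunkActivationModel(ds.model, ds.m_id[0], syns,
                                   EstimatorConfig(n_syn=3)).fit()
        assert (fit.w_est >= 0).all()
        assert fit.a_est.min() >= -1e-6 and fit.a_est.max() <= 1 + 1e-6
        parts = sum(v for k, v in fit.costs.items() if k != "total")
        assert fit.costs["total"] == pytest.approx(parts, abs=1e-9)

    def test_solution_beats_zero_start(self, noisy_dataset):
        ds = noisy_dataset
        syns = {}
        for side in ("right", "left"):
            s = extract_synergies(ds.leg_activations[side][0], 3,
                                  restarts=5, seed=4, side=side)
            syns[side] = normalize_activations(s)
        cfg = EstimatorConfig(n_syn=3)
        est = TrunkActivationModel(ds.model, ds.m_id[0], syns, cfg)
        fit = est.fit()
        zero_cost = (cost_moment_tracking(
            joint_moments(np.zeros_like(fit.a_est), ds.model), ds.m_id[0],
            cfg.allow_dm))
        assert fit.costs["total"] <= zero_cost + 1e-9

    def test_unnormalized_synergies_rejected(self, tiny_dataset):
        ds = tiny_dataset
        H = 0.5 * ds.H_true["right"]
        syns = {"right": SynergySet(np.ones((6, 3)), H, side="right"),
                "left": SynergySet(np.ones((6, 3)), ds.H_true["left"],
                                   side="left")}
        with pytest.raises(ValueError, match="normalized"):
            TrunkActivationModel(ds.model, ds.m_id_clean, syns)

    def test_three_term_objective_flag(self, tiny_dataset):
        ds = tiny_dataset
        syns = {}
        for side in ("right", "left"):
            s = extract_synergies(ds.leg_activations[side][0], 3,
                                  restarts=5, seed=5, side=side)
            syns[side] = normalize_activations(s)
        cfg = EstimatorConfig(n_syn=3, include_jw_dev=False)
        fit = TrunkActivationModel(ds.model, ds.m_id[0], syns, cfg).fit()
        assert "J_w_dev" not in fit.costs


class TestStaticOptimization:
    def _frame_model(self, n_musc, arms_row, fmo=1000.0):
        lmt = np.full((1, n_musc), 0.30)
        arms = np.asarray(arms_row, float).reshape(1, n_musc, -1)
        mtus = [MTU(f"m{i}", "ES", "right", fmo, 0.10, 0.20)
                for i in range(n_musc)]
        return TrunkModel(mtus, MuscleGeometrySeries(
            lmt, arms, [f"d{j}" for j in range(arms.shape[2])]))

    def test_single_muscle_closed_form(self):
        model = self._frame_model(1, [0.05])
        res = StaticOptimization(model, np.array([[25.0]])).fit()
        assert res.a_est[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_two_identical_muscles_split_evenly(self):
        model = self._frame_model(2, [0.05, 0.05])
        res = StaticOptimization(model, np.array([[25.0]])).fit()
        np.testing.assert_allclose(res.a_est[0], [0.25, 0.25], atol=1e-6)

    def test_beats_random_feasible_points(self):
        rng = np.random.default_rng(11)
        n_musc, n_dof = 4, 2
        lmt = np.full((1, n_musc), 0.30)
        arms = 0.05 * rng.standard_normal((1, n_musc, n_dof))
        mtus = [MTU(f"m{i}", "ES", "right", rng.uniform(200, 900),
                    0.10, 0.20) for i in range(n_musc)]
        model = TrunkModel(mtus, MuscleGeometrySeries(lmt, arms,
                                                      ["d0", "d1"]))
        gains = np.array([m.fmo for m in model.mtus])
        E = arms[0].T * gains  # active_fl(1) = 1 at optimal length
        a_seed = rng.uniform(0.2, 0.6, size=n_musc)
        b = E @ a_seed
        res = StaticOptimization(model, b[np.newaxis, :]).fit()
        best = np.sum(res.a_est[0] ** 2)
        pinv = np.linalg.pinv(E)
        found = 0
        for _ in range(10_000):
            cand = rng.uniform(0, 1, size=n_musc)
            cand = cand - pinv @ (E @ cand - b)
            if (cand >= 0).all() and (cand <= 1).all():
                found += 1
                assert best <= np.sum(cand ** 2) + 1e-6
        assert found > 100  # the oracle actually sampled feasible points

    def test_infeasible_frame_raises_without_reserves(self):
        model = self._frame_model(1, [0.05], fmo=100.0)  # max 5 Nm
        with pytest.raises(InfeasibleFrameError, match="frame 0"):
            StaticOptimization(model, np.array([[50.0]])).fit()

    def test_reserves_absorb_infeasible_demand(self):
        model = self._frame_model(1, [0.05], fmo=100.0)
        res = StaticOptimization(model, np.array([[50.0]]),
                                 reserves=True).fit()
        total = res.m_est[0, 0] + res.reserve_torques[0, 0]
        assert total == pytest.approx(50.0, abs=1e-4)


class TestConfig:
    def test_invalid_allowables_rejected(self):
        with pytest.raises(ValueError):
            EstimatorConfig(allow_a=0.0)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_syn: 6\nallow_a: 0.25\ninclude_jw_dev: false\n")
        cfg = EstimatorConfig.from_file(p)
        assert cfg.n_syn == 6 and cfg.allow_a == 0.25
        assert not cfg.include_jw_dev

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_synergies: 6\n")
        with pytest.raises(ValueError, match="unknown"):
            EstimatorConfig.from_file(p)
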