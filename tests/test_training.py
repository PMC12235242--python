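"""Hybrid assembly, loss/metrics, training bookkeeping, grid machinery."""

import numpy as np
import pytest

from chromsol.network import (NetworkConfig, NetworkCorrection, init_network)
from chromsol.training import (Adam, Chromatogram, Experiment, TrainConfig,
                               _window_average_weights, full_grid, hybrid_rhs,
                               loss, loss_gradient, r_squared)


@pytest.fixture()
def obs():
    rng = np.random.default_rng(0)
    conc = np.abs(rng.normal(1.0, 0.5, size=(12, 4)))
    conc[:, 0] = np.linspace(30, 100, 12)
    return conc


CINJ = np.array([0.1, 0.888, 0.012])


class TestLoss:
    def test_perfect_prediction(self, obs):
        assert loss(obs, obs, CINJ) == 0.0

    def test_zero_prediction_gives_one(self, obs):
        assert loss(np.zeros_like(obs), obs, CINJ) == pytest.approx(1.0)

    def test_doubled_prediction_gives_one(self, obs):
        assert loss(2 * obs, obs, CINJ) == pytest.approx(1.0)

    def test_all_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            loss(np.ones((3, 4)), np.zeros((3, 4)), CINJ)

    def test_unit_rescaling_invariance(self, obs):
        # rescaling one adsorbate's units together with its feed
        # concentration leaves the normalized loss unchanged
        pred = obs * 1.1
        base = loss(pred, obs, CINJ)
        scale = np.array([1.0, 1.0, 1000.0, 1.0])
        cinj2 = CINJ * np.array([1.0, 1000.0, 1.0])
        assert loss(pred * scale, obs * scale, cinj2) == pytest.approx(base)

    def test_gradient_matches_finite_differences(self, obs):
        rng = np.random.default_rng(1)
        pred = obs * (1 + 0.1 * rng.normal(size=obs.shape))
        g = loss_gradient(pred, obs, CINJ)
        for idx in [(0, 1), (3, 2), (7, 3), (5, 0)]:
            e = np.zeros_like(pred)
            e[idx] = 1e-7
            fd = (loss(pred + e, obs, CINJ) - loss(pred - e, obs, CINJ)) / 2e-7
            assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-12)

    def test_modifier_flag_changes_pooling(self, obs):
        pred = obs.copy()
        pred[:, 0] += 5.0     # modifier-only error
        assert loss(pred, obs, CINJ) == 0.0
        assert loss(pred, obs, CINJ, include_modifier=True) > 0.0


class TestRSquared:
    def test_perfect_fit(self, obs):
        r2 = r_squared(obs, obs, CINJ)
        assert r2["overall"] == pytest.approx(1.0)
        assert all(r2[i] == pytest.approx(1.0) for i in range(3))

    def test_mean_prediction_scores_zero(self, obs):
        pred = obs.copy()
        pred[:, 1] = obs[:, 1].mean()
        assert r_squared(pred, obs, CINJ)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_points(self):
        # one adsorbate, normalized by cinj=1: obs (1,2,3), pred (1,2,4):
        # SS_res = 1, SS_tot = 2 -> R2 = 0.5
        obs = np.column_stack([[30, 40, 50], [1.0, 2.0, 3.0]])
        pred = np.column_stack([[30, 40, 50], [1.0, 2.0, 4.0]])
        r2 = r_squared(pred, obs, [1.0])
        assert r2[0] == pytest.approx(0.5)

    def test_zero_variance_reported_missing(self):
        obs = np.column_stack([[30, 40], [1.0, 1.0]])
        r2 = r_squared(obs.copy(), obs, [1.0])
        assert r2[0] is None


class TestWindowAverages:
    def test_rows_sum_to_one(self):
        times = np.linspace(0, 100, 23)
        edges = np.array([[5.0, 20.0], [20.0, 47.0], [60.0, 61.0]])
        W = _window_average_weights(times, edges)
        assert W.sum(axis=1) == pytest.approx(np.ones(3))

    def test_exact_for_linear_signal(self):
        times = np.linspace(0, 10, 17)
        edges = np.array([[1.0, 4.0], [4.0, 9.5]])
        W = _window_average_weights(times, edges)
        signal = 3.0 * times + 1.0
        # window average of a linear function is its midpoint value
        assert W @ signal == pytest.approx([3.0 * 2.5 + 1, 3.0 * 6.75 + 1])


class TestHybridRhs:
    def test_identity_initialized_network_degenerates(self, model,
                                                      generic_state):
        net = init_network(NetworkConfig(2, 14, 3, init_seed=0))
        hyb = hybrid_rhs(generic_state, 5.0, net, model)
        mech = model.assemble_rhs(generic_state, 5.0)
        assert np.array_equal(hyb, mech)

    def test_single_node_correction_doubles_one_rate(self, model,
                                                     generic_state):
        mech = model.assemble_rhs(generic_state, 5.0)

        class OneNodeDouble:
            def values(self, state, m):
                g = np.ones((state.shape[0], m.n_comp))
                g[4, 0] = 2.0
                return g

            def state_jacobian(self, state, m):
                return np.zeros((state.shape[0], m.n_comp,
                                 2 * m.n_comp + 1))

            def param_vjp(self, state, m, cot):
                return None

        hyb = model.assemble_rhs(generic_state, 5.0, OneNodeDouble())
        rW = mech[4, model.i_q(0)]
        assert hyb[4, model.i_q(0)] == pytest.approx(2 * rW)
        # the coupling and modifier balance follow the corrected rate
        assert hyb[4, model.i_c(0)] - mech[4, model.i_c(0)] == pytest.approx(
            -model.phi * rW)
        assert hyb[4, model.i_qm] - mech[4, model.i_qm] == pytest.approx(
            -model.nu[0] * rW)
        # all other nodes untouched
        mask = np.ones(model.n_nodes, bool)
        mask[4] = False
        assert np.array_equal(hyb[mask], mech[mask])

    def test_modifier_column_recomputed_from_corrected_rates(
            self, model, generic_state):
        net = init_network(NetworkConfig(1, 6, 3, init_seed=2))
        rng = np.random.default_rng(0)
        W, b = net.params[-1]
        net.params[-1] = (rng.normal(0, 1e-3, W.shape), b)
        hyb = hybrid_rhs(generic_state, 5.0, net, model)
        assert hyb[:, model.i_qm] == pytest.approx(
            -(hyb[:, model.q_slice] @ model.nu))


class TestMachinery:
    def test_reference_grid_has_228_cells(self):
        layers, nodes, lrs = full_grid()
        assert len(layers) * len(nodes) * len(lrs) == 228

    def test_adam_moves_against_gradient(self):
        opt = Adam(3, lr=0.1)
        p = np.array([1.0, -1.0, 0.0])
        g = np.array([1.0, -2.0, 0.0])
        p1 = opt.step(p, g)
        assert p1[0] < p[0] and p1[1] > p[1] and p1[2] == p[2]

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_experiment_role_and_span_checked(self, experiments):
        with pytest.raises(ValueError):
            Experiment("x", experiments[0].program, role="validate")
        chrom = Chromatogram(times=[1e9], cv=[1.0],
                             conc=np.ones((1, 4)))
        with pytest.raises(ValueError):
            Experiment("x", experiments[0].program, role="train",
                       observations=chrom)
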