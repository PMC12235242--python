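"""Mechanistic right-hand side: adsorption rate law, coupling, Jacobians."""

import numpy as np
import pytest

from chromsol.method import ComponentParams
from chromsol.network import NetworkConfig, NetworkCorrection, init_network
from chromsol.rhs import (MECH_PARAM_NAMES, ModifierDomainError,
                          SurfaceOverloadError, modifier_stationary_rate,
                          sdm_rate)


class TestSdmRate:
    W = ComponentParams("W", charge_nu=6.08, keq=7.38e-5, sigma=29.17,
                        kkin=2.89e-7)

    def test_empty_column_at_rest(self):
        assert sdm_rate(0.0, [0.0], 50.0, self.W, ligand=100.0) == 0.0

    def test_detailed_balance(self):
        # pick q so that keq (L - (nu+sigma) q)^nu c = q cm^nu exactly
        lig, cm, c = 200.0, 45.0, 0.3
        q = 1e-3
        free = lig - (self.W.charge_nu + self.W.sigma) * q
        keq = q * cm ** self.W.charge_nu / (free ** self.W.charge_nu * c)
        comp = self.W.replace(keq=keq)
        assert sdm_rate(c, [q], cm, comp, lig) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_single_node(self):
        # (1/kkin) [keq (L - (nu+sigma) q)^nu c - q cm^nu] with
        # L=200, q=0.5, c=0.2, cm=40: free = 200 - 35.25*0.5 = 182.375
        free = 200.0 - (6.08 + 29.17) * 0.5
        expected = (7.38e-5 * free ** 6.08 * 0.2 - 0.5 * 40.0 ** 6.08) \
            / 2.89e-7
        got = sdm_rate(0.2, [0.5], 40.0, self.W, ligand=200.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_surface_overload_error(self):
        with pytest.raises(SurfaceOverloadError):
            sdm_rate(0.1, [10.0], 40.0, self.W, ligand=100.0)

    def test_modifier_domain_error(self):
        with pytest.raises(ModifierDomainError):
            sdm_rate(0.1, [0.0], 0.0, self.W, ligand=100.0)


class TestModifierStationaryRate:
    def test_zero_rates(self):
        assert modifier_stationary_rate([0.0, 0.0, 0.0], [6.0, 7.7, 12.6]) == 0.0

    def test_direct_sum(self):
        assert modifier_stationary_rate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) \
            == pytest.approx(-6.0)

    def test_single_component_charge(self):
        got = modifier_stationary_rate([1.0, 0.0, 0.0], [6.08, 7.70, 12.63])
        assert got == pytest.approx(-6.08)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            modifier_stationary_rate([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAssembleRhs:
    def test_equilibrated_column_is_steady(self, model):
        rates = model.assemble_rhs(model.initial_state(), 1.0, step_idx=0)
        assert np.abs(rates).max() < 1e-9

    def test_nonbinding_tracer_reduces_to_transport(self, truth, model,
                                                    generic_state):
        # a component with keq = 0 and an empty surface is pure transport
        comps = [c.replace(keq=0.0) for c in truth.components]
        model.update_components(comps)
        state = generic_state.copy()
        state[:, model.q_slice] = 0.0
        rates = model.assemble_rhs(state, 1.0, step_idx=0)
        op = model.transport(0)
        for i in range(model.n_comp):
            pure = op.apply(state[:, model.i_c(i)], 0.0)
            assert rates[:, model.i_c(i)] == pytest.approx(pure)
            assert np.all(rates[:, model.i_q(i)] == 0.0)
        model.update_components(truth.components)

    def test_stationary_modifier_balances_charges(self, model, generic_state):
        rates = model.assemble_rhs(generic_state, 1.0, step_idx=0)
        dq = rates[:, model.q_slice]
        assert rates[:, model.i_qm] == pytest.approx(-(dq @ model.nu))

    def test_rhs_is_deterministic(self, model, generic_state):
        r1 = model.assemble_rhs(generic_state, 5.0, step_idx=0)
        r2 = model.assemble_rhs(generic_state, 5.0, step_idx=0)
        assert np.array_equal(r1, r2)


class TestJacobians:
    def _correction(self, model):
        # near-identity but state-dependent corrections: features reach the
        # hundreds (q~ of the trace component), so output weights must stay
        # small or softplus saturates and the corrected rates vanish
        net = init_network(NetworkConfig(1, 5, model.n_comp, init_seed=3))
        rng = np.random.default_rng(0)
        W, b = net.params[-1]
        net.params[-1] = (rng.normal(0, 1e-3, W.shape),
                          b + rng.normal(0, 0.05, b.shape))
        return NetworkCorrection(net)

    def test_state_jacobian_matches_finite_differences(self, model,
                                                       generic_state):
        corr = self._correction(model)
        t = 5.0
        J = model.rhs_jacobian(generic_state, t, corr, 0)
        flat0 = model.flatten(generic_state)
        f0 = model.flatten(model.assemble_rhs(generic_state, t, corr, 0))
        scale = 0.0
        Jfd = np.zeros_like(J)
        for j in range(flat0.size):
            h = 1e-6 * (1 + abs(flat0[j]))
            e = np.zeros_like(flat0)
            e[j] = h
            f1 = model.flatten(model.assemble_rhs(
                model.unflatten(flat0 + e), t, corr, 0))
            Jfd[:, j] = (f1 - f0) / h
        scale = np.abs(Jfd).max()
        assert np.abs(J - Jfd).max() / scale < 1e-4

    def test_parameter_vjp_matches_finite_differences(self, truth, model,
                                                      generic_state):
        corr = self._correction(model)
        rng = np.random.default_rng(3)
        w = rng.normal(size=generic_state.shape)
        mech_g, _ = model.param_vjp(generic_state, w, corr, want_mech=True)
        comps0 = list(model.components)

        def value(ci, name, v):
            comps = list(comps0)
            comps[ci] = comps[ci].replace(**{name: v})
            model.update_components(comps)
            out = float(np.sum(w * model.assemble_rhs(
                generic_state, 5.0, corr, 0)))
            model.update_components(comps0)
            return out

        for ci in range(model.n_comp):
            for pj, name in enumerate(MECH_PARAM_NAMES):
                v0 = getattr(comps0[ci], name)
                if name == "charge_nu":
                    h = 1e-6      # nu acts exponentially: tiny absolute step
                elif name == "keq":
                    h = 0.5 * v0  # rates are linear in keq: any step is exact
                elif v0 == 0.0:
                    h = 1e-7      # sigma_S = 0: one-sided
                    fd = (value(ci, name, h) - value(ci, name, 0.0)) / h
                    assert mech_g[ci, pj] == pytest.approx(fd, rel=2e-3,
                                                           abs=1e-9)
                    continue
                else:
                    h = 1e-3 * abs(v0)
                fd = (value(ci, name, v0 + h) - value(ci, name, v0 - h)) / (2 * h)
                assert mech_g[ci, pj] == pytest.approx(fd, rel=2e-3, abs=1e-9)

    def test_network_vjp_matches_finite_differences(self, model,
                                                    generic_state):
        corr = self._correction(model)
        net = corr.net
        rng = np.random.default_rng(5)
        w = rng.normal(size=generic_state.shape)
        _, corr_g = model.param_vjp(generic_state, w, corr,
                                    want_correction=True)
        flat_g = np.concatenate([np.concatenate([gW.ravel(), gb])
                                 for gW, gb in corr_g])
        p0 = net.flat_parameters()

        def value(p):
            net.set_flat_parameters(p)
            return float(np.sum(w * model.assemble_rhs(
                generic_state, 5.0, NetworkCorrection(net), 0)))

        gfd = np.zeros_like(p0)
        for j in range(p0.size):
            h = 1e-6 * (1 + abs(p0[j]))
            e = np.zeros_like(p0)
            e[j] = h
            gfd[j] = (value(p0 + e) - value(p0 - e)) / (2 * h)
        net.set_flat_parameters(p0)
        assert np.abs(flat_g - gfd).max() < 1e-5 * max(1.0, np.abs(gfd).max())
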