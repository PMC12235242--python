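"""Synthetic benchmark: program layout, observation generation, persistence."""

import numpy as np
import pytest

from chromsol.benchmark import (TruthSpec, fraction_grid, generate_observations,
                                make_programs, read_experiments,
                                write_experiments)
from chromsol.rhs import ColumnModel
from chromsol.training import loss, simulate


class TestPrograms:
    def test_six_runs_split_three_three(self, experiments):
        assert len(experiments) == 6
        assert sum(e.role == "train" for e in experiments) == 3
        assert sum(e.role == "test" for e in experiments) == 3

    def test_high_load_long_gradient_scaling(self, truth, experiments):
        exp = next(e for e in experiments if e.label == "Load22p5_GL8p5")
        base = next(e for e in experiments if e.label == "Load15_GL6p5")
        load_cv = exp.program.load_step().duration_cv
        base_cv = base.program.load_step().duration_cv
        assert load_cv / base_cv == pytest.approx(1.5)      # 150 % load
        gl = next(s for s in exp.program.steps if s.kind == "gradient")
        assert gl.duration_cv / 6.5 == pytest.approx(8.5 / 6.5)  # 130 %

    def test_all_gradients_run_30_to_100(self, experiments):
        for e in experiments:
            g = next(s for s in e.program.steps if s.kind == "gradient")
            assert (g.percentB_start, g.percentB_end) == (30.0, 100.0)

    def test_step_velocities_follow_method_table(self, experiments):
        kinds = [s.kind for s in experiments[0].program.steps]
        assert kinds == ["equilibration", "load", "wash", "gradient", "strip"]
        v_cm_h = [s.velocity * 360000.0 for s in experiments[0].program.steps]
        assert v_cm_h == pytest.approx([400, 300, 150, 200, 150])


class TestFractionGrid:
    def test_windows_tile_gradient_only(self, experiments):
        exp = experiments[0]
        t0, t1, _, _ = exp.program.gradient_window()
        edges = exp.fraction_edges
        assert edges[0, 0] == pytest.approx(t0)
        assert edges[-1, 1] == pytest.approx(t1)
        assert np.all(edges[1:, 0] == edges[:-1, 1])

    def test_doubling_volume_halves_count(self, experiments):
        p = experiments[0].program       # 6.5 CV gradient
        n1 = fraction_grid(p, 0.25).shape[0]
        n2 = fraction_grid(p, 0.50).shape[0]
        assert abs(n1 - 2 * n2) <= 1

    def test_partial_last_window(self, experiments):
        p = next(e for e in experiments if "GL4p6" in e.label).program
        n = fraction_grid(p, 0.25).shape[0]
        assert n == int(np.ceil(4.6 / 0.25))


class TestObservations:
    def test_same_seed_identical(self, truth, experiments, coarse_mesh,
                                 coarse_solver):
        truth_spec = TruthSpec(noise_rel=0.02, seed=7)
        a = generate_observations(truth_spec, experiments[:1], coarse_mesh,
                                  coarse_solver)
        b = generate_observations(truth_spec, experiments[:1], coarse_mesh,
                                  coarse_solver)
        assert np.array_equal(a[0].observations.conc, b[0].observations.conc)

    def test_noiseless_unit_truth_equals_mechanistic(self, truth, experiments,
                                                     coarse_mesh,
                                                     coarse_solver):
        class UnitTruth:
            def values(self, state, model):
                return np.ones((state.shape[0], model.n_comp))

            def state_jacobian(self, state, model):
                return np.zeros((state.shape[0], model.n_comp,
                                 2 * model.n_comp + 1))

            def param_vjp(self, state, model, cot):
                return None

        truth_spec = TruthSpec(noise_rel=0.0, correction=UnitTruth())
        filled = generate_observations(truth_spec, experiments[:1], coarse_mesh,
                                       coarse_solver)
        model = ColumnModel(truth_spec.column, truth_spec.components,
                            experiments[0].program, coarse_mesh)
        mech, _, _ = simulate(model, experiments[0], None, coarse_solver)
        assert np.allclose(filled[0].observations.conc, mech.conc,
                           rtol=0, atol=1e-12)

    def test_truth_correction_self_consistency(self, truth, experiments,
                                               coarse_mesh, coarse_solver):
        """Supplying the generating correction analytically reproduces the
        noiseless observations to round-off (loss < 1e-10)."""
        filled = generate_observations(truth, experiments[:2], coarse_mesh,
                                       coarse_solver)
        for exp in filled:
            model = ColumnModel(truth.column, truth.components,
                                exp.program, coarse_mesh)
            chrom, _, _ = simulate(model, exp, truth.correction, coarse_solver)
            assert loss(chrom.conc, exp.observations.conc,
                        model.cinj) < 1e-10

    def test_identity_misfit_strictly_positive(self, truth, experiments,
                                               coarse_mesh, coarse_solver):
        filled = generate_observations(truth, experiments[:1], coarse_mesh,
                                       coarse_solver)
        model = ColumnModel(truth.column, truth.components,
                            experiments[0].program, coarse_mesh)
        mech, _, _ = simulate(model, filled[0], None, coarse_solver)
        assert loss(mech.conc, filled[0].observations.conc, model.cinj) > 1e-3

    def test_noise_truncated_at_zero(self, experiments, coarse_mesh,
                                     coarse_solver):
        truth_spec = TruthSpec(noise_rel=2.0, seed=3)   # absurd noise: must clip
        filled = generate_observations(truth_spec, experiments[:1], coarse_mesh,
                                       coarse_solver)
        assert filled[0].observations.conc.min() >= 0.0


class TestPersistence:
    def test_write_read_round_trip(self, tmp_path, truth, experiments,
                                   coarse_mesh, coarse_solver):
        truth_spec = TruthSpec(noise_rel=0.02, seed=5)
        filled = generate_observations(truth_spec, experiments, coarse_mesh,
                                       coarse_solver)
        write_experiments(filled, truth_spec, tmp_path)
        loaded, reloaded_spec = read_experiments(tmp_path)
        assert [e.label for e in loaded] == [e.label for e in filled]
        assert [e.role for e in loaded] == [e.role for e in filled]
        for a, b in zip(loaded, filled):
            assert np.allclose(a.observations.conc, b.observations.conc)
            assert a.program.total_time == pytest.approx(
                b.program.total_time)
        assert reloaded_spec.components[0].keq == truth_spec.components[0].keq
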