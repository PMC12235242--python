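"""Mechanistic calibration: fit adsorption parameters to chromatograms.

The same differentiable simulator used for hybrid training provides exact
gradients of the chromatogram loss with respect to the adsorption
parameters (nu, keq, sigma, kkin per component), so calibration is a
gradient-based minimization in log-parameter space (which keeps every
parameter strictly positive) using the identical loss, normalization and
data partitioning as hybrid training. An optional coarse one-at-a-time
scan refines the starting point before the gradient descent.

The calibrated parameters are then frozen: hybrid training touches only
the correction network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import solver as bdf
from .method import ComponentParams
from .rhs import MECH_PARAM_NAMES
from .training import loss, loss_gradient, simulate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationConfig:
    """Which parameters move, and how.

    `free` maps component name -> parameter names from
    ('charge_nu', 'keq', 'sigma', 'kkin'); all parameters are fitted on a
    log scale. `scan_factors` is the coarse pre-scan grid (multiples of the
    initial guess per free parameter, best kept); empty tuple disables it.
    """

    free: dict
    max_iter: int = 60
    scan_factors: tuple = (0.25, 0.5, 1.0, 2.0, 4.0)
    log_bound: float = 8.0          # |log10 p / p0| bound, keeps L-BFGS sane
    include_modifier: bool = False

    def __post_init__(self) -> None:
        if not self.free or all(len(v) == 0 for v in self.free.values()):
            raise ValueError("need at least one free parameter")
        for names in self.free.values():
            for nm in names:
                if nm not in MECH_PARAM_NAMES:
                    raise ValueError(f"unknown parameter {nm!r}")


@dataclass
class CalibrationReport:
    history: list = field(default_factory=list)
    initial_loss: float = np.nan
    final_loss: float = np.nan
    n_evaluations: int = 0


def _free_index(components, config) -> list:
    idx = []
    for ci, comp in enumerate(components):
        for nm in config.free.get(comp.name, ()):
            idx.append((ci, nm, MECH_PARAM_NAMES.index(nm)))
    return idx


def _apply(components, free_idx, values) -> list:
    comps = list(components)
    for (ci, nm, _), v in zip(free_idx, values):
        comps[ci] = comps[ci].replace(**{nm: float(v)})
    return comps


def _mech_loss_and_grad(models, experiments, solver_config, include_modifier):
    """Mean mechanistic loss over experiments and d(loss)/d(mech params)."""
    n_exp = len(experiments)
    total = 0.0
    grad = np.zeros((models[0].n_comp, 4))
    out_node = models[0].mesh.outlet_index
    for model, exp in zip(models, experiments):
        chrom, traj, W = simulate(model, exp, None, solver_config,
                                  record_adjoint=True)
        obs = exp.observations.conc
        total += loss(chrom.conc, obs, model.cinj, include_modifier) / n_exp
        dL = loss_gradient(chrom.conc, obs, model.cinj, include_modifier) / n_exp
        dsnap = W.T @ dL
        bar = np.zeros_like(traj.states)
        cols = [model.i_cm] + [model.i_c(i) for i in range(model.n_comp)]
        for j, col in enumerate(cols):
            bar[:, out_node, col] = dsnap[:, j]
        mech_g, _ = bdf.backward(traj, model, bar, None,
                                 want_mech=True, want_correction=False)
        grad += mech_g
    return total, grad


def calibrate(models, experiments, components, config: CalibrationConfig,
              solver_config: bdf.SolverConfig | None = None):
    """Fit the selected adsorption parameters to the training chromatograms.

    `models` must wrap the same experiments' programs; their parameters are
    updated in place during the search and left at the optimum. Returns
    (fitted ComponentParams list, CalibrationReport).
    """
    solver_config = solver_config or bdf.SolverConfig()
    free_idx = _free_index(components, config)
    if not free_idx:
        raise ValueError("calibration config frees no parameter of these components")
    report = CalibrationReport()

    def set_values(values):
        comps = _apply(components, free_idx, values)
        for m in models:
            m.update_components(comps)
        return comps

    def value_vector(comps):
        return np.array([getattr(comps[ci], nm) for ci, nm, _ in free_idx])

    x0_values = value_vector(components)

    # coarse one-at-a-time scan around the initial guess
    values = x0_values.copy()
    if config.scan_factors:
        for k in range(len(free_idx)):
            best_v, best_L = values[k], np.inf
            for f in config.scan_factors:
                trial = values.copy()
                trial[k] = x0_values[k] * f
                set_values(trial)
                try:
                    L = float(np.mean([
                        loss(simulate(m, e, None, solver_config)[0].conc,
                             e.observations.conc, m.cinj,
                             config.include_modifier)
                        for m, e in zip(models, experiments)]))
                except Exception as exc:
                    logger.debug("scan point failed: %s", exc)
                    continue
                report.n_evaluations += 1
                if L < best_L:
                    best_L, best_v = L, trial[k]
            values[k] = best_v

    x0 = np.log(values)
    bounds = [(x - config.log_bound * np.log(10), x + config.log_bound * np.log(10))
              for x in np.log(x0_values)]

    best = {"loss": np.inf, "x": x0.copy()}

    def objective(x):
        comps = set_values(np.exp(x))
        try:
            L, g = _mech_loss_and_grad(models, experiments, solver_config,
                                       config.include_modifier)
        except Exception as exc:
            raise RuntimeError(
                f"simulation diverged during calibration at parameters "
                f"{[(c.name, c.charge_nu, c.keq, c.sigma, c.kkin) for c in comps]}"
            ) from exc
        if not np.isfinite(L):
            raise RuntimeError(f"non-finite calibration loss at x={x}")
        report.n_evaluations += 1
        report.history.append(L)
        if L < best["loss"]:
            best["loss"], best["x"] = L, x.copy()
        g_free = np.array([g[ci, col] for ci, _, col in free_idx])
        return L, g_free * np.exp(x)       # chain rule to log space

    report.initial_loss, _ = objective(np.log(x0_values))
    minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
             options={"maxiter": config.max_iter})
    # keep the best point seen (L-BFGS-B's last evaluation need not be it)
    fitted = set_values(np.exp(best["x"]))
    report.final_loss = best["loss"]
    logger.info("calibration: loss %.4g -> %.4g in %d evaluations",
                report.initial_loss, report.final_loss, report.n_evaluations)
    return fitted, report
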