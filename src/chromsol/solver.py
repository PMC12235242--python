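"""Fixed-step BDF time integration (operator SOL), differentiable end to end.

The column ODE system is integrated with backward differentiation formulas
of orders 1-5 at a fixed step (a configurable fraction of the total
simulated time, 5 per mille by default). Solver step boundaries are aligned
with method-step boundaries so the discontinuous forcing (velocity jumps,
feed switching) is never integrated across, and the order ramps 1 -> max
from the start of every method step so the multistep history never spans a
discontinuity.

Each implicit step solves the BDF relation

    a_0 y_n + ... + a_s y_{n+s} = h * beta_s * f(y_{n+s}, t_{n+s})

by Newton iteration; every Newton iteration solves a linear system through
an LU factorization of (a_s I - h beta_s J), with J the analytic RHS
Jacobian. Differentiability is obtained by the implicit-function theorem
applied step by step: the forward pass stores the LU factors at the
converged states and a reverse sweep propagates loss cotangents through
the whole unrolled integration, yielding exact (discretize-then-optimize)
gradients with respect to correction-network and adsorption parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgWarning, lu_factor as _lu_factor, lu_solve


def lu_factor(M, **kw):
    """LU factorization that stays quiet about singular iteration matrices:
    rejected Newton trial states can make a_s I - h b J numerically singular,
    and the resulting non-finite steps are detected and backtracked."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", LinAlgWarning)
        return _lu_factor(M, **kw)

# ascending coefficients [a_0 .. a_s] (a_s normalized to 1) and beta_s
BDF_COEFFS = {
    1: (np.array([-1.0, 1.0]), 1.0),
    2: (np.array([1 / 3, -4 / 3, 1.0]), 2 / 3),
    3: (np.array([-2 / 11, 9 / 11, -18 / 11, 1.0]), 6 / 11),
    4: (np.array([3 / 25, -16 / 25, 36 / 25, -48 / 25, 1.0]), 12 / 25),
    5: (np.array([-12 / 137, 75 / 137, -200 / 137, 300 / 137, -300 / 137, 1.0]),
        60 / 137),
}


class SolverError(RuntimeError):
    """Newton failed to converge after the order-reduction retry."""


@dataclass(frozen=True)
class SolverConfig:
    """Fixed-step BDF settings.

    step_fraction: solver step as a fraction of the total simulated time
    (0.005 -> 200 steps). newton_tol is relative to the per-column state
    magnitude (columns span g/L to ligand-density units, so a single
    absolute tolerance would be meaningless).
    """

    step_fraction: float = 0.005
    max_order: int = 5
    newton_tol: float = 1e-10
    newton_max_iter: int = 12

    def __post_init__(self) -> None:
        if not 0.0 < self.step_fraction <= 0.05:
            raise ValueError("step_fraction must lie in (0, 0.05]")
        if not 1 <= self.max_order <= 5:
            raise ValueError("max_order must be in 1..5")


@dataclass
class StepRecord:
    """Adjoint bookkeeping for one accepted BDF step."""

    new_idx: int
    hist_idx: tuple
    alphas: np.ndarray
    hbeta: float
    lu: tuple
    t_new: float
    step_idx: int


@dataclass
class Trajectory:
    """Time grid and state snapshots of one integration."""

    times: np.ndarray
    states: np.ndarray        # (n_snapshots, n_nodes, n_fields)
    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("snapshot times must strictly increase")


def _newton_solve(rhs_flat, jac_flat, hist, alphas, hbeta, tolvec, max_iter,
                  lu0=None):
    """Solve a_s y + sum(a_i y_i) = hbeta f(y) for y; returns (y, converged).

    Newton with an LU-factored iteration matrix built at the predictor
    (rebuilt once at the current iterate if convergence stalls); steps that
    land on non-finite residuals are backtracked. `lu0` optionally supplies
    the predictor factorization (the caller may already hold the LU of
    a_s I - hbeta J at the previous converged state, which *is* this step's
    predictor).
    """
    a_s = alphas[-1]
    const = sum(a * y for a, y in zip(alphas[:-1], hist))

    def residual(y):
        # trial states far from the solution may overflow the adsorption
        # power laws; non-finite residuals are detected and backtracked, so
        # the numpy warnings carry no information here
        with np.errstate(over="ignore", invalid="ignore"):
            return a_s * y + const - hbeta * rhs_flat(y)

    y = hist[-1].copy()
    res = residual(y)
    if not np.all(np.isfinite(res)):
        return y, False
    eye = np.eye(y.size)

    # phase 1/2: chord Newton with the LU frozen at the predictor, then once
    # more at the current iterate; cheap and sufficient for most steps
    for _rebuild in range(2):
        if _rebuild == 0 and lu0 is not None:
            lu = lu0
        else:
            with np.errstate(over="ignore", invalid="ignore"):
                M = a_s * eye - hbeta * jac_flat(y)
            if not np.all(np.isfinite(M)):
                return y, False
            lu = lu_factor(M, check_finite=False)
        for _ in range(max_iter):
            dy = lu_solve(lu, -res, check_finite=False)
            if not np.all(np.isfinite(dy)):
                break
            step = 1.0
            for _damp in range(8):
                y_try = y + step * dy
                res_try = residual(y_try)
                if np.all(np.isfinite(res_try)):
                    break
                step *= 0.25
            else:
                break
            y, res = y_try, res_try
            if step == 1.0 and np.max(np.abs(dy) / tolvec) < 1.0:
                return y, True

    # phase 3: full Newton (Jacobian refreshed every iteration, mildly
    # damped) for the rare stiff-wave steps where the chord iteration
    # stalls; restarted from the predictor, not the stalled iterate
    y = hist[-1].copy()
    res = residual(y)
    prev_dn = np.inf
    for _ in range(max_iter + 8):
        with np.errstate(over="ignore", invalid="ignore"):
            J = jac_flat(y)
        if not np.all(np.isfinite(J)):
            return y, False
        dy = lu_solve(lu_factor(a_s * eye - hbeta * J, check_finite=False), -res, check_finite=False)
        dn = np.max(np.abs(dy) / tolvec)
        if not np.isfinite(dn):
            return y, False
        step = 1.0 if dn < 4.0 * prev_dn else 0.5
        for _damp in range(8):
            y_try = y + step * dy
            res_try = residual(y_try)
            if np.all(np.isfinite(res_try)):
                break
            step *= 0.25
        else:
            return y, False
        y, res = y_try, res_try
        prev_dn = dn
        if step == 1.0 and dn < 1.0:
            return y, True
    return y, False


def bdf_step(history, rhs, h: float, order: int, jac=None,
             tol: float = 1e-10, max_iter: int = 12) -> np.ndarray:
    """One BDF step on flat vectors (reference form used in unit tests).

    `history` holds the most recent `order` states (oldest first); `rhs`
    maps a flat state to its flat time derivative; `jac` its Jacobian
    (finite differences if omitted). Returns y at t + h.
    """
    if order not in BDF_COEFFS:
        raise ValueError("BDF order must be 1..5")
    hist = [np.atleast_1d(np.asarray(y, dtype=float)) for y in history]
    if len(hist) < order:
        raise ValueError(f"order {order} needs {order} history states")
    hist = hist[-order:]
    if h <= 0:
        raise ValueError("step size must be positive")
    if jac is None:
        def jac(y, _rhs=rhs):
            n = y.size
            J = np.empty((n, n))
            f0 = _rhs(y)
            for j in range(n):
                e = np.zeros(n)
                e[j] = 1e-7 * (1.0 + abs(y[j]))
                J[:, j] = (_rhs(y + e) - f0) / e[j]
            return J
    alphas, beta = BDF_COEFFS[order]
    tolvec = tol * np.maximum(1.0, np.abs(hist[-1]))
    y, ok = _newton_solve(rhs, jac, hist, alphas, h * beta, tolvec, max_iter)
    if not ok:
        raise SolverError(f"Newton failed to converge at order {order}")
    return y


def integrate(model, y0: np.ndarray, config: SolverConfig, correction=None,
              record_adjoint: bool = False, check_states: bool = True) -> Trajectory:
    """Integrate the column model over its full method program.

    `correction` (optional) multiplies the adsorption rates inside every
    implicit solve (the hybrid right-hand side); with `record_adjoint` the
    LU factors at the converged states are kept so `backward` can run the
    reverse sweep. With correction identically one the trajectory is
    bit-identical to the purely mechanistic run.
    """
    program = model.program
    total = program.total_time
    h_target = config.step_fraction * total
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (model.n_nodes, model.n_fields):
        raise ValueError("initial state does not conform to the mesh")
    snapshots = [y0.copy()]
    times = [0.0]
    records: list[StepRecord] = []

    for step_idx in range(len(program.steps)):
        t0, t1 = program.step_window(step_idx)
        duration = t1 - t0
        n_sub = max(1, int(np.ceil(duration / h_target - 1e-9)))
        h = duration / n_sub

        def rhs_flat(yf, _t=None, _si=step_idx):
            return model.flatten(model.assemble_rhs(
                model.unflatten(yf), _t, correction, _si))

        def jac_flat(yf, _t=None, _si=step_idx):
            return model.rhs_jacobian(model.unflatten(yf), _t, correction, _si)

        carry_lu, carry_key = None, None
        for k in range(n_sub):
            order = min(k + 1, config.max_order)
            t_new = t0 + (k + 1) * h if k + 1 < n_sub else t1
            hist_global = list(range(len(snapshots) - order, len(snapshots)))
            hist = [model.flatten(snapshots[i]) for i in hist_global]
            colmax = np.maximum(1.0, np.abs(snapshots[-1]).max(axis=0))
            tolvec = np.repeat(config.newton_tol * colmax, model.n_nodes)
            for attempt_order in (order, 1):
                alphas, beta = BDF_COEFFS[attempt_order]
                hbeta = h * beta
                use_hist = hist[-attempt_order:]
                use_global = hist_global[-attempt_order:]
                lu0 = carry_lu if carry_key == (attempt_order, hbeta) else None
                yf, ok = _newton_solve(
                    lambda y: rhs_flat(y, t_new),
                    lambda y: jac_flat(y, t_new),
                    use_hist, alphas, hbeta, tolvec, config.newton_max_iter,
                    lu0=lu0)
                if ok:
                    break
            if not ok:
                raise SolverError(
                    f"Newton failed at t={t_new:.6g} s "
                    f"(method step {step_idx}, solver step {k})")
            y_new = model.unflatten(yf)
            if check_states:
                model.check_state(y_new, where=f"at t={t_new:.6g} s")
            snapshots.append(y_new)
            times.append(t_new)
            if record_adjoint:
                # the LU at the converged state serves both the adjoint
                # sweep and (a_s/hbeta permitting) the next step's predictor
                J = jac_flat(yf, t_new)
                M = alphas[-1] * np.eye(model.dim) - hbeta * J
                lu = lu_factor(M, check_finite=False)
                records.append(StepRecord(
                    new_idx=len(snapshots) - 1,
                    hist_idx=tuple(use_global),
                    alphas=alphas, hbeta=hbeta,
                    lu=lu, t_new=t_new, step_idx=step_idx))
                carry_lu, carry_key = lu, (attempt_order, hbeta)

    return Trajectory(np.array(times), np.array(snapshots), records)


def backward(traj: Trajectory, model, bar_states: np.ndarray, correction=None,
             want_mech: bool = False, want_correction: bool = True):
    """Reverse (adjoint) sweep through a recorded trajectory.

    `bar_states` is dL/d(snapshot) with the same shape as traj.states.
    Returns (mech_grads, correction_grads): mech_grads is (n_components, 4)
    ordered (nu, keq, sigma, kkin); correction_grads matches the structure
    of the correction's parameters (list of (dW, db) for a network).
    """
    if not traj.records:
        raise ValueError("trajectory was integrated without record_adjoint")
    bar = np.array(bar_states, dtype=float, copy=True)
    mech_total = np.zeros((model.n_comp, 4))  # columns (nu, keq, sigma, kkin)
    corr_total = None
    for rec in reversed(traj.records):
        w = bar[rec.new_idx]
        if not w.any():
            continue
        lam_flat = lu_solve(rec.lu, model.flatten(w), trans=1, check_finite=False)
        lam = model.unflatten(lam_flat)
        for idx, a in zip(rec.hist_idx, rec.alphas[:-1]):
            bar[idx] -= a * lam
        mech_g, corr_g = model.param_vjp(
            traj.states[rec.new_idx], lam, correction,
            want_mech=want_mech, want_correction=want_correction)
        if want_mech and mech_g is not None:
            mech_total += rec.hbeta * mech_g
        if want_correction and corr_g is not None:
            if corr_total is None:
                corr_total = [(rec.hbeta * gW, rec.hbeta * gb)
                              for gW, gb in corr_g]
            else:
                corr_total = [(tW + rec.hbeta * gW, tb + rec.hbeta * gb)
                              for (tW, tb), (gW, gb) in zip(corr_total, corr_g)]
    return (mech_total if want_mech else None), corr_total


def outlet_series(traj: Trajectory, model, sample_times=None) -> np.ndarray:
    """Outlet mobile-phase concentrations [cm, c_1..c_n] sampled at the
    requested times (linear interpolation between solver snapshots)."""
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    out_node = model.mesh.outlet_index
    cols = [model.i_cm] + [model.i_c(i) for i in range(model.n_comp)]
    raw = traj.states[:, out_node, :][:, cols]
    if sample_times is None:
        return raw
    t = np.atleast_1d(np.asarray(sample_times, dtype=float))
    if t.min() < traj.times[0] - 1e-9 or t.max() > traj.times[-1] + 1e-9:
        raise ValueError("requested times fall outside the trajectory span")
    out = np.column_stack([
        np.interp(t, traj.times, raw[:, j]) for j in range(raw.shape[1])])
    return out
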