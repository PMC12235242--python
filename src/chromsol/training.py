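"""Hybrid-model assembly, loss, training loop and hyperparameter search.

The hybrid forward map composes the mechanistic operator F, the node-wise
correction network NN and the implicit BDF solver SOL: at every solver
step the network's positive multipliers scale the adsorption rates before
the implicit solve. Training minimizes a normalized mean-squared error
between fraction-averaged simulated chromatograms and observations, with
gradients obtained by the adjoint sweep through the unrolled integration,
and Adam updating only the network parameters (the calibrated mechanistic
parameters stay frozen).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solver as bdf
from .method import ColumnSpec, MethodProgram, time_to_cv
from .network import (CorrectionNetwork, NetworkConfig, NetworkCorrection,
                      init_network)
from .rhs import ColumnModel

logger = logging.getLogger(__name__)


@dataclass
class Chromatogram:
    """Outlet time series on the fraction-collector grid.

    `conc` has one row per fraction and columns [modifier, adsorbate_1..n]
    (modifier in %B, adsorbates in g/L); `window_edges` are the fraction
    start/end times in seconds when the values are window averages.
    """

    times: np.ndarray
    cv: np.ndarray
    conc: np.ndarray
    window_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if len(self.times) < 1:
            raise ValueError("a chromatogram needs at least one sample")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must strictly increase")
        if self.conc.shape[0] != len(self.times):
            raise ValueError("conc rows must match sample times")

    @property
    def n_adsorbates(self) -> int:
        return self.conc.shape[1] - 1


@dataclass
class Experiment:
    """One gradient-elution run: method program plus (optional) observations."""

    label: str
    program: MethodProgram
    role: str
    observations: Chromatogram | None = None
    fraction_edges: np.ndarray | None = None   # (nt, 2) seconds

    def __post_init__(self) -> None:
        if self.role not in ("train", "test"):
            raise ValueError("role must be 'train' or 'test'")
        if self.observations is not None:
            tmax = self.program.total_time
            if (self.observations.times.min() < -1e-9
                    or self.observations.times.max() > tmax + 1e-9):
                raise ValueError("observation times outside program span")


@dataclass(frozen=True)
class TrainConfig:
    """Adam training settings (full-batch: every epoch simulates every
    training experiment once and backpropagates the mean loss)."""

    learning_rate: float = 1e-3
    epochs: int = 2000
    seed: int = 0
    record_history: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    include_modifier: bool = False
    stop_loss: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("need at least one epoch")


@dataclass
class FitReport:
    """Training bookkeeping: loss history, per-experiment contributions,
    best epoch/parameters and goodness-of-fit."""

    history: np.ndarray
    per_experiment: np.ndarray
    best_epoch: int
    best_loss: float
    best_parameters: np.ndarray | None
    r2: dict = field(default_factory=dict)

    def to_frame(self, labels=None) -> pd.DataFrame:
        cols = labels or [f"exp{i}" for i in range(self.per_experiment.shape[1])]
        df = pd.DataFrame(self.per_experiment, columns=cols)
        df.insert(0, "loss", self.history)
        df.insert(0, "epoch", np.arange(1, len(self.history) + 1))
        return df


# ---------------------------------------------------------------------------
# loss and metrics


def _normalize(conc: np.ndarray, cinj, include_modifier: bool) -> np.ndarray:
    """Scale adsorbate columns by their feed concentrations; the modifier
    column passes through unscaled (or is dropped when excluded)."""
    cinj = np.asarray(cinj, dtype=float)
    scaled = conc.copy()
    scaled[:, 1:] = scaled[:, 1:] / cinj
    return scaled if include_modifier else scaled[:, 1:]


def loss(pred: np.ndarray, obs: np.ndarray, cinj,
         include_modifier: bool = False) -> float:
    """Normalized MSE ||C_hat - C||^2 / ||C||^2 over all pooled columns."""
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation shapes differ")
    p = _normalize(pred, cinj, include_modifier)
    o = _normalize(obs, cinj, include_modifier)
    denom = float(np.sum(o * o))
    if denom == 0.0:
        raise ValueError("all-zero observations: loss normalization undefined")
    return float(np.sum((p - o) ** 2) / denom)


def loss_gradient(pred: np.ndarray, obs: np.ndarray, cinj,
                  include_modifier: bool = False) -> np.ndarray:
    """dL/d(pred) for the normalized MSE, on the raw (unscaled) prediction."""
    cinj = np.asarray(cinj, dtype=float)
    p = _normalize(pred, cinj, include_modifier)
    o = _normalize(obs, cinj, include_modifier)
    denom = float(np.sum(o * o))
    gnorm = 2.0 * (p - o) / denom
    grad = np.zeros_like(pred)
    if include_modifier:
        grad[:, 0] = gnorm[:, 0]
        grad[:, 1:] = gnorm[:, 1:] / cinj
    else:
        grad[:, 1:] = gnorm / cinj
    return grad


def r_squared(pred: np.ndarray, obs: np.ndarray, cinj,
              include_modifier: bool = False) -> dict:
    """Coefficient of determination on normalized concentrations.

    Returns {'overall': pooled over the adsorbate columns, 0: .., 1: ..}
    per adsorbate; zero-variance observations report None.
    """
    p = _normalize(pred, cinj, True)
    o = _normalize(obs, cinj, True)
    out = {}
    cols = range(o.shape[1]) if include_modifier else range(1, o.shape[1])
    for j in cols:
        ss_tot = float(np.sum((o[:, j] - o[:, j].mean()) ** 2))
        ss_res = float(np.sum((p[:, j] - o[:, j]) ** 2))
        key = "modifier" if j == 0 else j - 1
        out[key] = None if ss_tot == 0 else 1.0 - ss_res / ss_tot
    pa, oa = p[:, 1:], o[:, 1:]
    ss_tot = float(np.sum((oa - oa.mean()) ** 2))
    ss_res = float(np.sum((pa - oa) ** 2))
    out["overall"] = None if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return out


# ---------------------------------------------------------------------------
# forward simulation on the fraction grid


def _window_average_weights(times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Weights mapping snapshot values to window averages of their linear
    interpolant: conc_frac = W @ conc_snap (rows sum to one)."""
    nt = edges.shape[0]
    W = np.zeros((nt, len(times)))
    for w, (ta, tb) in enumerate(edges):
        pts = [ta] + [float(t) for t in times if ta < t < tb] + [tb]
        for u, v in zip(pts[:-1], pts[1:]):
            for t_eval, wt in ((u, 0.5 * (v - u)), (v, 0.5 * (v - u))):
                j = np.searchsorted(times, t_eval, side="right") - 1
                j = min(max(j, 0), len(times) - 2)
                frac = (t_eval - times[j]) / (times[j + 1] - times[j])
                W[w, j] += wt * (1.0 - frac)
                W[w, j + 1] += wt * frac
        W[w] /= (tb - ta)
    return W


def hybrid_rhs(state: np.ndarray, t: float, net: CorrectionNetwork,
               model: ColumnModel) -> np.ndarray:
    """Mechanistic rates with the network's multiplicative correction applied
    to the adsorption terms (and consistently to the stationary-modifier
    balance and the mobile-phase coupling); transport is never corrected."""
    return model.assemble_rhs(state, t, NetworkCorrection(net))


def simulate(model: ColumnModel, experiment: Experiment,
             correction=None, config: bdf.SolverConfig | None = None,
             record_adjoint: bool = False):
    """Integrate one experiment and return (Chromatogram, Trajectory, W).

    The chromatogram lives on the experiment's fraction grid, fraction-
    averaged to match the observation model; W is the linear map from
    snapshot outlet values to fractions (reused by the adjoint sweep).
    """
    config = config or bdf.SolverConfig()
    traj = bdf.integrate(model, model.initial_state(), config,
                         correction=correction, record_adjoint=record_adjoint)
    if experiment.fraction_edges is None:
        raise ValueError(f"experiment {experiment.label} has no fraction grid")
    edges = np.asarray(experiment.fraction_edges, dtype=float)
    W = _window_average_weights(traj.times, edges)
    raw = bdf.outlet_series(traj, model)          # (n_snap, 1+n)
    conc = W @ raw
    centers = edges.mean(axis=1)
    cv = np.array([time_to_cv(experiment.program, t) for t in centers])
    chrom = Chromatogram(times=centers, cv=cv, conc=conc, window_edges=edges)
    return chrom, traj, W


def build_models(column: ColumnSpec, components, experiments, mesh,
                 cinj=None) -> list:
    """One ColumnModel per experiment (programs differ, mesh is shared)."""
    return [ColumnModel(column, components, e.program, mesh, cinj=cinj)
            for e in experiments]


def experiment_losses(models, experiments, correction=None,
                      config: bdf.SolverConfig | None = None,
                      include_modifier: bool = False) -> np.ndarray:
    """Per-experiment normalized MSE for a fixed correction (no gradients)."""
    vals = []
    for model, exp in zip(models, experiments):
        chrom, _, _ = simulate(model, exp, correction, config)
        vals.append(loss(chrom.conc, exp.observations.conc, model.cinj,
                         include_modifier))
    return np.array(vals)


def loss_and_grad(models, experiments, net: CorrectionNetwork,
                  config: bdf.SolverConfig | None = None,
                  include_modifier: bool = False, want_mech: bool = False):
    """Mean loss over experiments and its gradient.

    Returns (total_loss, per_experiment_losses, flat_net_grad, mech_grad).
    The gradient chain is: loss -> fraction averages -> snapshot outlet
    values -> adjoint sweep through every BDF step -> network (and
    optionally adsorption-parameter) cotangents.
    """
    config = config or bdf.SolverConfig()
    correction = NetworkCorrection(net)
    n_exp = len(experiments)
    total = 0.0
    per_exp = np.zeros(n_exp)
    flat_grad = np.zeros(net.n_parameters)
    mech_grad = np.zeros((models[0].n_comp, 4)) if want_mech else None
    out_node = models[0].mesh.outlet_index
    for k, (model, exp) in enumerate(zip(models, experiments)):
        chrom, traj, W = simulate(model, exp, correction, config,
                                  record_adjoint=True)
        obs = exp.observations.conc
        L = loss(chrom.conc, obs, model.cinj, include_modifier)
        per_exp[k] = L
        total += L / n_exp
        dL_dconc = loss_gradient(chrom.conc, obs, model.cinj,
                                 include_modifier) / n_exp
        dL_dsnap = W.T @ dL_dconc                  # (n_snap, 1+n)
        bar = np.zeros_like(traj.states)
        cols = [model.i_cm] + [model.i_c(i) for i in range(model.n_comp)]
        for j, col in enumerate(cols):
            bar[:, out_node, col] = dL_dsnap[:, j]
        mech_g, corr_g = bdf.backward(traj, model, bar, correction,
                                      want_mech=want_mech,
                                      want_correction=True)
        if corr_g is not None:
            flat_grad += np.concatenate(
                [np.concatenate([gW.ravel(), gb]) for gW, gb in corr_g])
        if want_mech and mech_g is not None:
            mech_grad += mech_g
    return total, per_exp, flat_grad, mech_grad


# ---------------------------------------------------------------------------
# optimization


class Adam:
    """Plain Adam on a flat parameter vector."""

    def __init__(self, n: int, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mh = self.m / (1 - self.beta1 ** self.t)
        vh = self.v / (1 - self.beta2 ** self.t)
        return params - self.lr * mh / (np.sqrt(vh) + self.eps)


def train(models, experiments, net: CorrectionNetwork, config: TrainConfig,
          solver_config: bdf.SolverConfig | None = None) -> FitReport:
    """Adam gradient descent on the correction-network parameters only.

    One epoch = one full forward simulation of every training experiment
    plus backpropagation of the mean loss. The best (lowest-loss) epoch's
    parameters are retained and written back into `net`.
    """
    if not experiments:
        raise ValueError("need at least one training experiment")
    opt = Adam(net.n_parameters, config.learning_rate,
               config.beta1, config.beta2, config.eps)
    params = net.flat_parameters()
    history, per_hist = [], []
    best_loss, best_epoch, best_params = np.inf, -1, params.copy()
    for epoch in range(config.epochs):
        net.set_flat_parameters(params)
        total, per_exp, grad, _ = loss_and_grad(
            models, experiments, net, solver_config,
            include_modifier=config.include_modifier)
        if not np.isfinite(total):
            raise RuntimeError(f"non-finite loss at epoch {epoch + 1}")
        history.append(total)
        per_hist.append(per_exp)
        if total < best_loss:
            best_loss, best_epoch, best_params = total, epoch, params.copy()
        logger.info("epoch %d loss %.6g", epoch + 1, total)
        if config.stop_loss is not None and total <= config.stop_loss:
            break
        params = opt.step(params, grad)
    net.set_flat_parameters(best_params)
    r2 = {}
    correction = NetworkCorrection(net)
    for model, exp in zip(models, experiments):
        chrom, _, _ = simulate(model, exp, correction, solver_config)
        r2[exp.label] = r_squared(chrom.conc, exp.observations.conc, model.cinj)
    return FitReport(
        history=np.array(history),
        per_experiment=np.array(per_hist),
        best_epoch=best_epoch,
        best_loss=best_loss,
        best_parameters=best_params,
        r2=r2,
    )


# ---------------------------------------------------------------------------
# hyperparameter grid search


def grid_search(models, experiments, n_layers_grid, n_nodes_grid, lr_grid,
                epochs: int = 20, seed: int = 0, baseline_loss: float | None = None,
                solver_config: bdf.SolverConfig | None = None,
                include_modifier: bool = False):
    """Train every (nL, nl, alpha) cell for a few epochs from the same
    layer-initialization seed and tabulate the best loss per cell.

    Returns (table, best_row, beat_fraction): `table` is a DataFrame with
    one row per cell; ties in the argmin break toward fewer parameters,
    then lower learning rate; `beat_fraction` is the share of cells whose
    loss beats the mechanistic baseline (the empirical-distribution
    summary), or None when no baseline is given.
    """
    n_comp = models[0].n_comp
    rows = []
    for nL in n_layers_grid:
        for nl in n_nodes_grid:
            for lr in lr_grid:
                net = init_network(NetworkConfig(
                    n_hidden_layers=nL, nodes_per_layer=nl,
                    n_components=n_comp, init_seed=seed))
                t0 = time.perf_counter()
                try:
                    report = train(models, experiments, net,
                                   TrainConfig(learning_rate=lr, epochs=epochs,
                                               include_modifier=include_modifier),
                                   solver_config)
                    cell_loss = report.best_loss
                    err = ""
                except Exception as exc:      # cell failures recorded, not fatal
                    cell_loss, err = np.nan, str(exc)
                    logger.warning("grid cell (%d,%d,%g) failed: %s",
                                   nL, nl, lr, exc)
                rows.append({
                    "n_layers": nL, "n_nodes": nl, "learning_rate": lr,
                    "loss": cell_loss,
                    "n_parameters": net.n_parameters,
                    "runtime_s": time.perf_counter() - t0,
                    "error": err,
                })
    table = pd.DataFrame(rows)
    ok = table[np.isfinite(table["loss"])]
    if len(ok) == 0:
        raise RuntimeError("every grid cell failed")
    ranked = ok.sort_values(["loss", "n_parameters", "learning_rate"],
                            kind="mergesort")
    best = ranked.iloc[0]
    beat = None
    if baseline_loss is not None:
        beat = float(np.mean(ok["loss"].to_numpy() < baseline_loss))
    return table, best, beat


def full_grid() -> tuple:
    """The reference search space: 3 x 19 x 4 = 228 cells."""
    return ([1, 2, 3], list(range(3, 22)), [1e-4, 1e-3, 1e-2, 1e-1])
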