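"""Synthetic six-experiment gradient-elution benchmark.

Emulates a small preparative campaign on a reversed-phase column: a ternary
mixture of a weakly adsorbed impurity (W), the main product (P) and a
strongly adsorbed impurity (S) separated by a linear 30-100 %B gradient,
run at three resin loadings (7.5 / 15 / 22.5 g per litre of packed column)
crossed with three gradient lengths (4.6 / 6.5 / 8.5 CV) in six printed
combinations, split 1:1 into training and test roles. Observations are
produced by the hybrid simulator itself using a *known* smooth positive
correction of the adsorption rates in place of the network, fraction-
averaged over the gradient step and perturbed with seeded multiplicative
noise — so training and testing can be exercised end to end with a ground
truth in hand.

The adsorption parameters are benchmark fixtures: the orderings are the
physically meaningful content (charge and retention increase W -> P -> S,
the strongly adsorbed impurity carries no shielding), while the magnitudes
were set by forward-simulation screening so that all three species are
fully retained during loading and elute inside the shortest gradient
window. The modifier enters the rate law in %B units, so keq values are on
that basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import solver as bdf
from .dgfem import build_mesh
from .method import (CM_PER_H_TO_M_PER_S, ColumnSpec, ComponentParams,
                     MethodProgram, MethodStep, cv_to_time)
from .rhs import ColumnModel
from .training import Chromatogram, Experiment, simulate

#: feed mass fractions of W : P : S (the strongly adsorbed impurity is a
#: trace component, ~1% of the crude mixture)
FEED_FRACTIONS = (0.10, 0.888, 0.012)
FEED_TOTAL_G_L = 1.0

#: the six (load g/L_column, gradient length CV, role) combinations
BENCHMARK_RUNS = (
    ("Load15_GL6p5", 15.0, 6.5, "train"),
    ("Load7p5_GL6p5", 7.5, 6.5, "train"),
    ("Load15_GL8p5", 15.0, 8.5, "train"),
    ("Load15_GL4p6", 15.0, 4.6, "test"),
    ("Load22p5_GL6p5", 22.5, 6.5, "test"),
    ("Load22p5_GL8p5", 22.5, 8.5, "test"),
)


def default_column() -> ColumnSpec:
    """100 x 4.6 mm column, total porosity 0.54; ligand density and plate
    count are benchmark fixtures. The apparent plate count is deliberately
    low (it lumps extra-column broadening) so that every peak is resolved
    even on the reduced 4-element quadratic mesh used for fast training:
    under-resolved peaks ring, and zero-truncated noisy observations of a
    ringing signal acquire a rectification bias no correction could fit."""
    return ColumnSpec(length=0.100, inner_diameter=0.0046, total_porosity=0.54,
                      ligand_density=4.0e4, plate_count=10.0)


def default_components() -> list:
    """Ternary SDM fixture: charges and shielding ordered as in the real
    system (nu_W < nu_P < nu_S, sigma_S = 0); keq chosen so each species'
    retention factor crosses unity at ~65 / 78 / 88 %B; kkin sets the
    adsorption relaxation time at the elution composition to ~3 / 20 / 80 s
    (W fast, P and S visibly rate-limited, so kinetic corrections leave a
    clear fingerprint on the chromatograms)."""
    return [
        ComponentParams("W", charge_nu=6.0, keq=2.16e-17, sigma=29.2,
                        kkin=2.26e11),
        ComponentParams("P", charge_nu=7.7, keq=1.59e-21, sigma=12.5,
                        kkin=7.4e15),
        ComponentParams("S", charge_nu=12.6, keq=4.27e-34, sigma=0.0,
                        kkin=2.5e26),
    ]


class TruthCorrection:
    """Known smooth positive correction generating the benchmark data.

    g_W = 1,
    g_P = 1 + aP * c~P / (bP + c~P)   (saturable boost with mobile product),
    g_S = 1 + aS * q~S / (bS + q~S)   (saturable boost with adsorbed S),

    on the same normalized features the network sees. Both non-unit
    corrections are bounded Langmuir-type accelerations of the adsorption
    kinetics; coefficients are fixtures chosen so the identity-corrected
    (purely mechanistic) model misfits the data measurably while the
    implicit solver stays well conditioned (an unbounded correction on the
    trace component S, whose normalized q~S reaches hundreds, produces
    rate multipliers in the hundreds and intractable implicit systems).
    The features pass through a smooth (C^1) positive part before entering
    g: they are physically non-negative, but small discretization
    undershoots must neither flip the correction's sign (positive by
    invariant) nor create a derivative kink for Newton to chatter on.
    """

    def __init__(self, a_p: float = 0.3, b_p: float = 0.1, a_s: float = 4.0,
                 b_s: float = 3.0, smooth_eps: float = 0.01):
        self.a_p, self.b_p, self.a_s, self.b_s = a_p, b_p, a_s, b_s
        self.smooth_eps = smooth_eps

    def _pos(self, x):
        return 0.5 * (x + np.sqrt(x * x + self.smooth_eps ** 2))

    def _dpos(self, x):
        return 0.5 * (1.0 + x / np.sqrt(x * x + self.smooth_eps ** 2))

    def values(self, state, model):
        feat = model.features(state)
        g = np.ones((state.shape[0], model.n_comp))
        cP = self._pos(feat[:, 2])                      # c~P
        qS = self._pos(feat[:, 1 + model.n_comp + 2])   # q~S
        g[:, 1] = 1.0 + self.a_p * cP / (self.b_p + cP)
        g[:, 2] = 1.0 + self.a_s * qS / (self.b_s + qS)
        return g

    def state_jacobian(self, state, model):
        feat = model.features(state)
        J = np.zeros((state.shape[0], model.n_comp, 2 * model.n_comp + 1))
        cP_raw = feat[:, 2]
        qS_raw = feat[:, 1 + model.n_comp + 2]
        cP = self._pos(cP_raw)
        qS = self._pos(qS_raw)
        J[:, 1, 2] = (self.a_p * self.b_p / (self.b_p + cP) ** 2
                      * self._dpos(cP_raw))
        J[:, 2, 1 + model.n_comp + 2] = (self.a_s * self.b_s
                                         / (self.b_s + qS) ** 2
                                         * self._dpos(qS_raw))
        return J * model.feature_scales()[None, None, :]

    def param_vjp(self, state, model, cotangent):
        return None


@dataclass
class TruthSpec:
    """Everything that determines the synthetic observations."""

    components: list = field(default_factory=default_components)
    column: ColumnSpec = field(default_factory=default_column)
    correction: TruthCorrection = field(default_factory=TruthCorrection)
    noise_rel: float = 0.02
    noise_floor: float = 0.0
    fraction_cv: float = 0.5
    feed_total: float = FEED_TOTAL_G_L
    feed_fractions: tuple = FEED_FRACTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_rel < 0 or self.noise_floor < 0:
            raise ValueError("noise levels must be >= 0")
        if self.fraction_cv <= 0:
            raise ValueError("fraction volume must be positive")

    @property
    def feed_concentrations(self) -> tuple:
        return tuple(self.feed_total * f for f in self.feed_fractions)


def build_program(column: ColumnSpec, load_g_per_l: float,
                  gradient_cv: float, feed_concentrations) -> MethodProgram:
    """Standard five-step method: 3 CV equilibration at 30 %B (400 cm/h),
    load at 300 cm/h (volume = load / total feed concentration), 2 CV wash
    at 30 %B (150 cm/h), linear 30-100 %B gradient at 200 cm/h, 2 CV strip
    at 100 %B (150 cm/h). The load step runs at the 30 %B of its
    neighbours."""
    feed = tuple(feed_concentrations)
    feed_total = sum(feed)
    if feed_total <= 0:
        raise ValueError("feed must contain some adsorbate")
    load_cv = load_g_per_l / feed_total
    v = CM_PER_H_TO_M_PER_S
    steps = [
        MethodStep("equilibration", 30, 30, 400 * v, 3.0),
        MethodStep("load", 30, 30, 300 * v, load_cv, feed),
        MethodStep("wash", 30, 30, 150 * v, 2.0),
        MethodStep("gradient", 30, 100, 200 * v, gradient_cv),
        MethodStep("strip", 100, 100, 150 * v, 2.0),
    ]
    return MethodProgram(steps, column)


def fraction_grid(program: MethodProgram, fraction_cv: float) -> np.ndarray:
    """Fraction windows (start, end seconds) tiling the gradient step only."""
    t0, t1, cv0, cv1 = program.gradient_window()
    n = int(np.ceil((cv1 - cv0) / fraction_cv - 1e-9))
    cv_edges = cv0 + np.minimum(np.arange(n + 1) * fraction_cv, cv1 - cv0)
    t_edges = np.array([cv_to_time(program, c) for c in cv_edges])
    return np.column_stack([t_edges[:-1], t_edges[1:]])


def make_programs(truth: TruthSpec | None = None) -> list:
    """The six benchmark experiment shells (no observations yet)."""
    truth = truth or TruthSpec()
    exps = []
    for label, load, gl, role in BENCHMARK_RUNS:
        program = build_program(truth.column, load, gl,
                                truth.feed_concentrations)
        exps.append(Experiment(
            label=label, program=program, role=role,
            fraction_edges=fraction_grid(program, truth.fraction_cv)))
    return exps


def generate_observations(truth: TruthSpec, experiments, mesh=None,
                          solver_config: bdf.SolverConfig | None = None,
                          rng=None) -> list:
    """Simulate every experiment with the ground-truth correction, fraction-
    average over the gradient windows, and add seeded multiplicative noise
    (truncated at zero). Returns new Experiment objects with observations."""
    mesh = mesh or build_mesh(7, 3, truth.column.length)
    solver_config = solver_config or bdf.SolverConfig()
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    out = []
    for exp in experiments:
        model = ColumnModel(truth.column, truth.components, exp.program, mesh)
        chrom, _, _ = simulate(model, exp, truth.correction, solver_config)
        conc = chrom.conc.copy()
        if truth.noise_rel > 0 or truth.noise_floor > 0:
            sd = truth.noise_rel * np.abs(conc) + truth.noise_floor
            conc = np.maximum(0.0, conc + sd * rng.standard_normal(conc.shape))
        obs = Chromatogram(times=chrom.times, cv=chrom.cv, conc=conc,
                           window_edges=chrom.window_edges)
        out.append(replace(exp, observations=obs))
    return out


# ---------------------------------------------------------------------------
# on-disk layout: one delimited text file per experiment plus a manifest


def write_experiments(experiments, truth: TruthSpec, out_dir) -> Path:
    """Write observations as CSV (one file per run) plus a JSON manifest
    from which the whole benchmark can be reconstructed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = [c.name for c in truth.components]
    runs = []
    for exp, (label, load, gl, role) in zip(experiments, BENCHMARK_RUNS):
        obs = exp.observations
        df = pd.DataFrame({"time_s": obs.times, "volume_cv": obs.cv,
                           "modifier_percentB": obs.conc[:, 0]})
        for j, nm in enumerate(names):
            df[f"c_{nm}_gL"] = obs.conc[:, 1 + j]
        path = out_dir / f"{exp.label}_observations.csv"
        df.to_csv(path, index=False)
        runs.append({"label": exp.label, "role": exp.role,
                     "load_g_per_l": load, "gradient_cv": gl,
                     "file": path.name})
    col = truth.column
    manifest = {
        "column": {"length_mm": col.length * 1e3, "id_mm": col.inner_diameter * 1e3,
                   "porosity": col.total_porosity,
                   "ligand_density": col.ligand_density,
                   "plate_count": col.plate_count},
        "components": [{"name": c.name, "nu": c.charge_nu, "keq": c.keq,
                        "sigma": c.sigma, "kkin": c.kkin}
                       for c in truth.components],
        "feed_total": truth.feed_total,
        "feed_fractions": list(truth.feed_fractions),
        "fraction_cv": truth.fraction_cv,
        "noise_rel": truth.noise_rel,
        "noise_floor": truth.noise_floor,
        "seed": truth.seed,
        "runs": runs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out_dir / "manifest.json"


def read_experiments(data_dir):
    """Rebuild (experiments, truth) from a benchmark directory.

    The manifest's component block echoes the *generating* parameters; a
    fresh calibration should start from its own guesses, not from these.
    """
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        man = json.load(fh)
    column = ColumnSpec(
        length=man["column"]["length_mm"] * 1e-3,
        inner_diameter=man["column"]["id_mm"] * 1e-3,
        total_porosity=man["column"]["porosity"],
        ligand_density=man["column"]["ligand_density"],
        plate_count=man["column"]["plate_count"])
    components = [ComponentParams(c["name"], c["nu"], c["keq"], c["sigma"],
                                  c["kkin"]) for c in man["components"]]
    truth = TruthSpec(
        components=components, column=column,
        noise_rel=man["noise_rel"], noise_floor=man["noise_floor"],
        fraction_cv=man["fraction_cv"], feed_total=man["feed_total"],
        feed_fractions=tuple(man["feed_fractions"]), seed=man["seed"])
    exps = []
    for run in man["runs"]:
        program = build_program(column, run["load_g_per_l"],
                                run["gradient_cv"], truth.feed_concentrations)
        df = pd.read_csv(data_dir / run["file"])
        conc_cols = [c for c in df.columns if c.startswith("c_")]
        conc = np.column_stack([df["modifier_percentB"].to_numpy()]
                               + [df[c].to_numpy() for c in conc_cols])
        edges = fraction_grid(program, truth.fraction_cv)
        obs = Chromatogram(times=df["time_s"].to_numpy(),
                           cv=df["volume_cv"].to_numpy(),
                           conc=conc, window_edges=edges)
        exps.append(Experiment(label=run["label"], program=program,
                               role=run["role"], observations=obs,
                               fraction_edges=edges))
    return exps, truth
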