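"""Column description, physical units, and the multi-step inlet program.

Everything downstream of this module works in SI units (m, s) with
concentrations in g/L for adsorbates and %B for the organic modifier.
Configuration files use the units chromatographers print in method tables
(cm/h for velocities, column volumes (CV) for step durations, mm for
geometry); conversion happens once, on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

#: seconds per hour / metres per cm — cm/h to m/s
CM_PER_H_TO_M_PER_S = 0.01 / 3600.0

STEP_KINDS = ("equilibration", "load", "wash", "gradient", "strip")


class ProgramRangeError(ValueError):
    """Raised when a query time falls outside the method-program span."""


@dataclass(frozen=True)
class ColumnSpec:
    """Packed-column geometry and efficiency.

    Parameters
    ----------
    length : float
        Bed length in metres.
    inner_diameter : float
        Column inner diameter in metres.
    total_porosity : float
        Total (interstitial + intraparticle) porosity, dimensionless.
    ligand_density : float
        Stationary-phase ligand capacity in model units (same basis as the
        adsorbed-phase concentrations q).
    plate_count : float
        Column efficiency N used to lump band broadening into an apparent
        dispersion coefficient.
    """

    length: float
    inner_diameter: float
    total_porosity: float
    ligand_density: float
    plate_count: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("column length must be positive")
        if self.inner_diameter <= 0:
            raise ValueError("inner diameter must be positive")
        if not 0.0 < self.total_porosity < 1.0:
            raise ValueError("total porosity must lie in (0, 1)")
        if self.ligand_density <= 0:
            raise ValueError("ligand density must be positive")
        if self.plate_count < 1:
            raise ValueError("plate count must be >= 1")

    @property
    def cross_section(self) -> float:
        """Column cross-sectional area in m^2."""
        return math.pi * (self.inner_diameter / 2.0) ** 2

    @property
    def volume(self) -> float:
        """Total column volume (1 CV) in m^3."""
        return self.cross_section * self.length

    @property
    def phase_ratio(self) -> float:
        """(1 - eps_t) / eps_t, the stationary/mobile volume ratio."""
        return (1.0 - self.total_porosity) / self.total_porosity


@dataclass(frozen=True)
class ComponentParams:
    """Stoichiometric-displacement adsorption parameters of one species.

    The adsorption rate law is

        kkin * dq_i/dt = keq_i * (Lambda - sum_j (nu_j + sigma_j) q_j)^nu_i * c_i
                         - q_i * cm^nu_i

    with cm the modifier concentration (%B here), nu the characteristic
    charge, sigma the steric shielding factor and Lambda the ligand density.
    """

    name: str
    charge_nu: float
    keq: float
    sigma: float
    kkin: float

    def __post_init__(self) -> None:
        if self.charge_nu <= 0:
            raise ValueError("characteristic charge nu must be positive")
        if self.keq < 0:
            raise ValueError("equilibrium constant keq must be >= 0")
        if self.sigma < 0:
            raise ValueError("shielding factor sigma must be >= 0")
        if self.kkin <= 0:
            raise ValueError("kinetic coefficient kkin must be positive")

    def replace(self, **kw) -> "ComponentParams":
        d = dict(
            name=self.name, charge_nu=self.charge_nu, keq=self.keq,
            sigma=self.sigma, kkin=self.kkin,
        )
        d.update(kw)
        return ComponentParams(**d)


@dataclass(frozen=True)
class MethodStep:
    """One step of a chromatographic method.

    velocity is the superficial velocity in m/s (configured in cm/h);
    duration is in column volumes. feed_concentrations (g/L per adsorbate)
    is nonzero only for load steps.
    """

    kind: str
    percentB_start: float
    percentB_end: float
    velocity: float
    duration_cv: float
    feed_concentrations: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise ValueError(f"unknown step kind {self.kind!r}")
        for b in (self.percentB_start, self.percentB_end):
            if not 0.0 <= b <= 100.0:
                raise ValueError("%B must lie in [0, 100]")
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.duration_cv <= 0:
            raise ValueError("step duration must be positive")
        if self.kind != "gradient" and self.percentB_start != self.percentB_end:
            raise ValueError("only gradient steps may ramp %B")
        if self.kind != "load" and any(f != 0 for f in self.feed_concentrations):
            raise ValueError("feed concentrations only allowed on load steps")


class MethodProgram:
    """Ordered chromatographic steps driving one simulation.

    Provides the piecewise inlet profile (modifier %B and adsorbate feed),
    the CV <-> time accounting, and per-step flow context.
    """

    def __init__(self, steps: Sequence[MethodStep], column: ColumnSpec):
        if not steps:
            raise ValueError("program needs at least one step")
        if not any(s.kind == "gradient" for s in steps):
            raise ValueError("program needs at least one gradient step")
        self.steps = tuple(steps)
        self.column = column
        # per-step duration in seconds: duration_cv CV at superficial u
        # takes duration_cv * (A L) / (u A) = duration_cv * L / u seconds
        durs = np.array([s.duration_cv * column.length / s.velocity for s in steps])
        self.step_durations_s = durs
        self.step_edges_s = np.concatenate([[0.0], np.cumsum(durs)])
        cv = np.array([s.duration_cv for s in steps])
        self.step_edges_cv = np.concatenate([[0.0], np.cumsum(cv)])
        if not np.all(np.diff(self.step_edges_s) > 0):
            raise ValueError("cumulative durations must strictly increase")

    @property
    def total_time(self) -> float:
        """Program span in seconds."""
        return float(self.step_edges_s[-1])

    @property
    def total_cv(self) -> float:
        return float(self.step_edges_cv[-1])

    @property
    def n_adsorbates(self) -> int:
        for s in self.steps:
            if s.kind == "load":
                return len(s.feed_concentrations)
        return 0

    def step_index_at(self, t: float) -> int:
        if t < 0 or t > self.total_time:
            raise ProgramRangeError(
                f"t={t} s outside program span [0, {self.total_time}] s"
            )
        i = int(np.searchsorted(self.step_edges_s, t, side="right") - 1)
        return min(i, len(self.steps) - 1)

    def step_window(self, i: int) -> tuple:
        """(t_start, t_end) of step i in seconds."""
        return float(self.step_edges_s[i]), float(self.step_edges_s[i + 1])

    def gradient_window(self) -> tuple:
        """(t_start, t_end, cv_start, cv_end) of the first gradient step."""
        for i, s in enumerate(self.steps):
            if s.kind == "gradient":
                t0, t1 = self.step_window(i)
                return t0, t1, float(self.step_edges_cv[i]), float(self.step_edges_cv[i + 1])
        raise ValueError("no gradient step")  # unreachable per invariant

    def load_step(self) -> MethodStep | None:
        for s in self.steps:
            if s.kind == "load":
                return s
        return None


def inlet_profile(program: MethodProgram, t: float) -> tuple:
    """Inlet modifier (%B) and adsorbate feed (g/L) at time t.

    Constant %B within non-gradient steps, linear ramp within gradient
    steps; adsorbate feed is nonzero only during the load step.
    """
    i = program.step_index_at(t)
    step = program.steps[i]
    t0, t1 = program.step_window(i)
    if step.kind == "gradient":
        frac = (t - t0) / (t1 - t0)
        pb = step.percentB_start + frac * (step.percentB_end - step.percentB_start)
    else:
        pb = step.percentB_start
    n = program.n_adsorbates
    feed = np.zeros(n)
    if step.kind == "load":
        feed[:] = step.feed_concentrations
    return float(pb), feed


def apparent_dispersion(u: float, column: ColumnSpec) -> float:
    """Apparent axial dispersion coefficient from plate count.

    D_app = u L / (2 eps_t N); recomputed per step so dispersion follows
    the step's flow rate.
    """
    if u <= 0:
        raise ValueError("superficial velocity must be positive")
    return u * column.length / (2.0 * column.total_porosity * column.plate_count)


def cv_to_time(program: MethodProgram, volume_cv: float) -> float:
    """Elapsed time (s) at which the cumulative throughput reaches volume_cv.

    Piecewise-linear in CV with per-step slope L/u; strictly monotone, so
    time_to_cv inverts it exactly.
    """
    if volume_cv < 0:
        raise ValueError("volume must be >= 0")
    if volume_cv > program.total_cv + 1e-12:
        raise ProgramRangeError(f"{volume_cv} CV exceeds program total {program.total_cv}")
    edges_cv = program.step_edges_cv
    i = min(int(np.searchsorted(edges_cv, volume_cv, side="right") - 1),
            len(program.steps) - 1)
    dcv = volume_cv - edges_cv[i]
    return float(program.step_edges_s[i]
                 + dcv * program.column.length / program.steps[i].velocity)


def time_to_cv(program: MethodProgram, t: float) -> float:
    """Inverse of cv_to_time."""
    i = program.step_index_at(t)
    dt = t - program.step_edges_s[i]
    return float(program.step_edges_cv[i]
                 + dt * program.steps[i].velocity / program.column.length)


# ---------------------------------------------------------------------------
# structured configuration


def column_from_dict(d: dict) -> ColumnSpec:
    return ColumnSpec(
        length=d["length_mm"] * 1e-3,
        inner_diameter=d["id_mm"] * 1e-3,
        total_porosity=d["porosity"],
        ligand_density=d["ligand_density"],
        plate_count=d["plate_count"],
    )


def components_from_list(items: list) -> list:
    return [
        ComponentParams(
            name=c["name"], charge_nu=c["nu"], keq=c["keq"],
            sigma=c["sigma"], kkin=c["kkin"],
        )
        for c in items
    ]


def step_from_dict(d: dict, n_adsorbates: int) -> MethodStep:
    if "percentB_range" in d:
        b0, b1 = d["percentB_range"]
    else:
        b0 = b1 = d["percentB"]
    feed = tuple(d.get("feed", ()))
    if d["kind"] == "load" and len(feed) != n_adsorbates:
        raise ValueError("load step feed must list one concentration per adsorbate")
    return MethodStep(
        kind=d["kind"],
        percentB_start=float(b0),
        percentB_end=float(b1),
        velocity=d["velocity_cm_h"] * CM_PER_H_TO_M_PER_S,
        duration_cv=float(d["volume_cv"]),
        feed_concentrations=feed,
    )


def load_config(path) -> dict:
    """Read a structured YAML config into column/components/program objects."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    column = column_from_dict(raw["column"])
    components = components_from_list(raw["components"])
    steps = [step_from_dict(s, len(components)) for s in raw["program"]]
    program = MethodProgram(steps, column)
    return {"column": column, "components": components, "program": program,
            "raw": raw}


def dump_config(column: ColumnSpec, components, program: MethodProgram, path) -> None:
    """Write the standard config format (inverse of load_config)."""
    steps = []
    for s in program.steps:
        d = {"kind": s.kind, "velocity_cm_h": s.velocity / CM_PER_H_TO_M_PER_S,
             "volume_cv": s.duration_cv}
        if s.kind == "gradient":
            d["percentB_range"] = [s.percentB_start, s.percentB_end]
        else:
            d["percentB"] = s.percentB_start
        if s.kind == "load":
            d["feed"] = list(s.feed_concentrations)
        steps.append(d)
    raw = {
        "column": {
            "length_mm": column.length * 1e3,
            "id_mm": column.inner_diameter * 1e3,
            "porosity": column.total_porosity,
            "ligand_density": column.ligand_density,
            "plate_count": column.plate_count,
        },
        "components": [
            {"name": c.name, "nu": c.charge_nu, "keq": c.keq,
             "sigma": c.sigma, "kkin": c.kkin}
            for c in components
        ],
        "program": steps,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
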