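"""Semi-discrete governing equations of the column (operator F).

State layout: a nodal matrix of shape [K*(np+1)] x (2n+2) with columns

    [cm, c_1 .. c_n, qm, q_1 .. q_n]

for n adsorbates (n=3 for the standard W/P/S ternary): mobile modifier (%B),
mobile adsorbates (g/L), stationary modifier bookkeeping and stationary
adsorbates. Mobile phases follow an equilibrium-dispersive transport model,
the stationary phase a simplified stoichiometric-displacement rate law, and
the stationary modifier balances the charge displaced by adsorption, so
qm + sum_j nu_j q_j is conserved pointwise by construction.

Besides the rate evaluation itself this module provides the *analytic*
Jacobian of the rates with respect to the state (used by the implicit
solver's Newton iterations and by the adjoint sweep) and vector-Jacobian
products with respect to both the adsorption parameters and the parameters
of an optional multiplicative rate correction. These make the whole
simulator differentiable without an autodiff framework.
"""

from __future__ import annotations

import logging

import numpy as np

from .dgfem import DGMesh, TransportOperator
from .method import ColumnSpec, ComponentParams, MethodProgram, apparent_dispersion

logger = logging.getLogger(__name__)

_CM_FLOOR = 1e-300  # guards fractional powers inside Newton trial states

MECH_PARAM_NAMES = ("charge_nu", "keq", "sigma", "kkin")


class SurfaceOverloadError(RuntimeError):
    """Accessible ligand capacity went negative: non-physical state."""


class ModifierDomainError(RuntimeError):
    """Modifier concentration is non-positive where a power law needs it."""


def sdm_rate(c_i: float, q_all, cm: float, params_i: ComponentParams,
             ligand: float, all_params=None) -> float:
    """Adsorption rate of one component at one point (scalar reference form).

    Returns (1/kkin) [ keq (Lambda - sum_j (nu_j+sigma_j) q_j)^nu c_i
                       - q_i cm^nu ].

    `q_all` lists the adsorbed concentrations of every component;
    `all_params` the matching ComponentParams (defaults to params_i alone).
    """
    if all_params is None:
        all_params = [params_i]
    q_all = np.asarray(q_all, dtype=float)
    if len(all_params) != q_all.size:
        raise ValueError("q_all and all_params lengths differ")
    blocked = sum((p.charge_nu + p.sigma) * q
                  for p, q in zip(all_params, q_all))
    free = ligand - blocked
    if free < 0:
        raise SurfaceOverloadError(f"free ligand capacity {free} < 0")
    if cm <= 0:
        raise ModifierDomainError(f"modifier concentration {cm} <= 0")
    idx = all_params.index(params_i)
    nu = params_i.charge_nu
    return (params_i.keq * free ** nu * c_i - q_all[idx] * cm ** nu) / params_i.kkin


def modifier_stationary_rate(dq_rates, charges) -> np.ndarray:
    """Stationary-modifier rate -sum_j nu_j dq_j/dt (pointwise)."""
    dq = np.asarray(dq_rates, dtype=float)
    nu = np.asarray(charges, dtype=float)
    if dq.shape[-1] != nu.shape[0]:
        raise ValueError("rate and charge vectors have mismatched lengths")
    return -(dq @ nu)


class ColumnModel:
    """Bundles column, adsorption parameters, program and mesh into the
    semi-discrete operator F, with Jacobians and parameter adjoints.

    `cinj` (g/L per adsorbate) normalizes the correction-network features
    and the chromatogram loss; it defaults to the program's load-step feed.
    """

    def __init__(self, column: ColumnSpec, components, program: MethodProgram,
                 mesh: DGMesh, cinj=None):
        self.column = column
        self.components = list(components)
        self.program = program
        self.mesh = mesh
        self.n_comp = len(self.components)
        self.nu = np.array([c.charge_nu for c in self.components])
        self.sigma = np.array([c.sigma for c in self.components])
        self.keq = np.array([c.keq for c in self.components])
        self.kkin = np.array([c.kkin for c in self.components])
        self.ligand = column.ligand_density
        self.eps_t = column.total_porosity
        self.phi = column.phase_ratio
        if cinj is None:
            load = program.load_step()
            cinj = np.array(load.feed_concentrations) if load is not None else None
        self.cinj = None if cinj is None else np.asarray(cinj, dtype=float)
        if self.cinj is not None and np.any(self.cinj <= 0):
            raise ValueError("injection concentrations must be positive")
        self._ops: dict[int, TransportOperator] = {}

    def update_components(self, components) -> None:
        """Swap adsorption parameters in place (transport cache is kept:
        the DG operators do not depend on them). Used by calibration."""
        if len(components) != self.n_comp:
            raise ValueError("component count cannot change")
        self.components = list(components)
        self.nu = np.array([c.charge_nu for c in self.components])
        self.sigma = np.array([c.sigma for c in self.components])
        self.keq = np.array([c.keq for c in self.components])
        self.kkin = np.array([c.kkin for c in self.components])

    # --- layout helpers ---------------------------------------------------

    @property
    def n_fields(self) -> int:
        return 2 * self.n_comp + 2

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    @property
    def dim(self) -> int:
        return self.n_fields * self.n_nodes

    @property
    def i_cm(self) -> int:
        return 0

    def i_c(self, i: int) -> int:
        return 1 + i

    @property
    def i_qm(self) -> int:
        return 1 + self.n_comp

    def i_q(self, i: int) -> int:
        return 2 + self.n_comp + i

    @property
    def c_slice(self):
        return slice(1, 1 + self.n_comp)

    @property
    def q_slice(self):
        return slice(2 + self.n_comp, 2 + 2 * self.n_comp)

    def flatten(self, state: np.ndarray) -> np.ndarray:
        return state.T.ravel()

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        return flat.reshape(self.n_fields, self.n_nodes).T

    # --- setup ------------------------------------------------------------

    def initial_state(self) -> np.ndarray:
        """Fully regenerated, equilibrated column: mobile phase at the first
        step's inlet, empty adsorbate surface, qm datum set to the ligand
        density so qm + sum nu_j q_j has an interpretable conserved value."""
        y0 = np.zeros((self.n_nodes, self.n_fields))
        y0[:, self.i_cm] = self.program.steps[0].percentB_start
        y0[:, self.i_qm] = self.ligand
        return y0

    def transport(self, step_idx: int) -> TransportOperator:
        if step_idx not in self._ops:
            step = self.program.steps[step_idx]
            Dapp = apparent_dispersion(step.velocity, self.column)
            self._ops[step_idx] = TransportOperator(
                self.mesh, step.velocity, self.eps_t, Dapp)
        return self._ops[step_idx]

    def inlet_at(self, t: float, step_idx: int):
        """Inlet (%B, feed vector) at time t, pinned to a given step so
        evaluations at segment edges use that segment's own program."""
        step = self.program.steps[step_idx]
        t0, t1 = self.program.step_window(step_idx)
        if step.kind == "gradient":
            frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
            pb = step.percentB_start + frac * (step.percentB_end - step.percentB_start)
        else:
            pb = step.percentB_start
        feed = np.zeros(self.n_comp)
        if step.kind == "load":
            feed[:] = step.feed_concentrations
        return pb, feed

    # --- kinetics ---------------------------------------------------------

    def _kinetics(self, state: np.ndarray):
        """Raw adsorption rates r (N, n) plus reusable intermediates.

        The power-law bases are clipped well outside the physical range
        (modifier <= 10x the maximum %B, free capacity <= 10x the ligand
        density) so that Newton *trial* states far from the solution cannot
        overflow; accepted states are physicality-checked separately and
        never sit near these clips.
        """
        cm = np.clip(state[:, self.i_cm], _CM_FLOOR, 1e3)
        c = state[:, self.c_slice]
        q = state[:, self.q_slice]
        free = self.ligand - q @ (self.nu + self.sigma)
        free_pos = np.clip(free, 0.0, 10.0 * self.ligand)
        spow = free_pos[:, None] ** self.nu[None, :]
        cmpow = cm[:, None] ** self.nu[None, :]
        r = (self.keq * spow * c - q * cmpow) / self.kkin
        return r, {"cm": cm, "c": c, "q": q, "free": free,
                   "free_pos": free_pos, "spow": spow, "cmpow": cmpow}

    def check_state(self, state: np.ndarray, where: str = "") -> None:
        """Physicality checks applied to accepted (converged) states."""
        free = self.ligand - state[:, self.q_slice] @ (self.nu + self.sigma)
        if np.any(free < 0):
            raise SurfaceOverloadError(
                f"ligand capacity exceeded (min free = {free.min():.3g}) {where}")
        if np.any(state[:, self.i_cm] <= 0):
            raise ModifierDomainError(f"modifier <= 0 at a node {where}")
        cmin = state[:, self.c_slice].min()
        if cmin < -1e-6:
            logger.debug("negative mobile concentration %.3g %s", cmin, where)

    def correction_values(self, state: np.ndarray, correction):
        if correction is None:
            return None
        return correction.values(state, self)

    # --- operator F -------------------------------------------------------

    def assemble_rhs(self, state: np.ndarray, t: float, correction=None,
                     step_idx: int | None = None) -> np.ndarray:
        """Time derivative of the full state (RatesVector).

        A `correction` (duck-typed: values/state_jacobian/param_vjp) scales
        the adsorption rates multiplicatively before they enter the
        stationary-modifier balance and the mobile-phase coupling; transport
        terms are never corrected.
        """
        if step_idx is None:
            step_idx = self.program.step_index_at(t)
        pb, feed = self.inlet_at(t, step_idx)
        op = self.transport(step_idx)
        r, _ = self._kinetics(state)
        if correction is not None:
            r = r * correction.values(state, self)
        rates = np.empty_like(state)
        nm = 1 + self.n_comp          # mobile columns [cm, c_1..c_n]
        inlet = np.concatenate([[pb], feed])
        rates[:, :nm] = op.A @ state[:, :nm] + np.outer(op.g, inlet)
        rates[:, self.c_slice] -= self.phi * r
        rates[:, self.i_qm] = -(r @ self.nu)
        rates[:, self.q_slice] = r
        return rates

    # --- Jacobian ---------------------------------------------------------

    def _rate_state_jacobian(self, state: np.ndarray, correction):
        """d(corrected rates)/d(state columns) as (N, n, 2n+1) in the column
        order [cm, c_1..c_n, q_1..q_n] (qm never enters)."""
        n, N = self.n_comp, self.n_nodes
        r, aux = self._kinetics(state)
        free, spow, cmpow = aux["free_pos"], aux["spow"], aux["cmpow"]
        cm, c, q = aux["cm"], aux["c"], aux["q"]
        spow_m1 = np.where(free[:, None] > 0,
                           free[:, None] ** (self.nu[None, :] - 1.0), 0.0)
        dr_dfree = self.keq * self.nu * spow_m1 * c / self.kkin      # (N, n)
        dr = np.zeros((N, n, 2 * n + 1))
        dr[:, :, 0] = -q * self.nu * cm[:, None] ** (self.nu[None, :] - 1.0) / self.kkin
        for i in range(n):
            dr[:, i, 1 + i] = self.keq[i] * spow[:, i] / self.kkin[i]
        for j in range(n):
            dr[:, :, 1 + n + j] = dr_dfree * (-(self.nu[j] + self.sigma[j]))
            dr[:, j, 1 + n + j] -= cmpow[:, j] / self.kkin[j]
        if correction is None:
            return dr, r, None
        g = correction.values(state, self)
        dg = correction.state_jacobian(state, self)                  # (N, n, 2n+1)
        drt = g[:, :, None] * dr + r[:, :, None] * dg
        return drt, r, g

    @property
    def _jac_index(self):
        """Cached flat index arrays for the node-local kinetics blocks."""
        if getattr(self, "_jac_index_cache", None) is None:
            n, N = self.n_comp, self.n_nodes
            diag = np.arange(N)
            cols = [self.i_cm] + [self.i_c(i) for i in range(n)] \
                + [self.i_q(i) for i in range(n)]
            col_flat = np.array([c * N + diag for c in cols])        # (2n+1, N)
            rowq = np.array([self.i_q(i) * N + diag for i in range(n)])
            rowc = np.array([self.i_c(i) * N + diag for i in range(n)])
            rowqm = self.i_qm * N + diag
            self._jac_index_cache = (col_flat, rowq, rowc, rowqm)
        return self._jac_index_cache

    def rhs_jacobian(self, state: np.ndarray, t: float, correction=None,
                     step_idx: int | None = None) -> np.ndarray:
        """Dense Jacobian d(rates)/d(state) on the flattened (field-major)
        layout, for Newton solves and the adjoint sweep."""
        if step_idx is None:
            step_idx = self.program.step_index_at(t)
        A = self.transport(step_idx).A
        n, N = self.n_comp, self.n_nodes
        J = np.zeros((self.dim, self.dim))
        for f in range(1 + n):                       # mobile fields share A
            J[f * N:(f + 1) * N, f * N:(f + 1) * N] = A
        drt, _, _ = self._rate_state_jacobian(state, correction)
        col_flat, rowq, rowc, rowqm = self._jac_index
        vals = drt.transpose(1, 2, 0)                # (n, 2n+1, N)
        J[rowq[:, None, :], col_flat[None, :, :]] += vals
        J[rowc[:, None, :], col_flat[None, :, :]] += -self.phi * vals
        J[rowqm[None, :], col_flat] += -np.einsum("ikN,i->kN", vals, self.nu)
        return J

    # --- parameter adjoints -------------------------------------------------

    def rate_cotangent(self, w: np.ndarray) -> np.ndarray:
        """Cotangent on the corrected adsorption rates given a cotangent w
        (N, n_fields) on the full RatesVector: combines the stationary rate,
        the mobile coupling and the stationary-modifier balance."""
        omega = w[:, self.q_slice] - self.phi * w[:, self.c_slice]
        omega = omega - w[:, [self.i_qm]] * self.nu[None, :]
        return omega

    def param_vjp(self, state: np.ndarray, w: np.ndarray, correction=None,
                  want_mech: bool = True, want_correction: bool = True):
        """Vector-Jacobian products of the rates with parameters.

        Returns (mech_grads, correction_grads); mech_grads is (n, 4) ordered
        (nu, keq, sigma, kkin) per component, correction_grads whatever the
        correction's own param_vjp returns (None for parameter-free ones).
        """
        omega = self.rate_cotangent(w)
        r, aux = self._kinetics(state)
        g = np.ones_like(r) if correction is None \
            else correction.values(state, self)
        corr_grads = None
        if want_correction and correction is not None:
            corr_grads = correction.param_vjp(state, self, omega * r)
        mech = None
        if want_mech:
            cot_r = omega * g                                      # (N, n)
            free, spow, cmpow = aux["free_pos"], aux["spow"], aux["cmpow"]
            cm, c, q = aux["cm"], aux["c"], aux["q"]
            spow_m1 = np.where(free[:, None] > 0,
                               free[:, None] ** (self.nu[None, :] - 1.0), 0.0)
            dr_dfree = self.keq * self.nu * spow_m1 * c / self.kkin
            logfree = np.where(free > 0, np.log(np.maximum(free, 1e-300)), 0.0)
            logcm = np.log(cm)
            g_keq = np.sum(cot_r * spow * c / self.kkin, axis=0)
            g_kkin = np.sum(cot_r * (-r / self.kkin[None, :]), axis=0)
            sfactor = np.sum(cot_r * dr_dfree, axis=1)              # (N,)
            g_sigma = -(sfactor[:, None] * q).sum(axis=0)
            own = (self.keq * spow * c * logfree[:, None]
                   - q * cmpow * logcm[:, None]) / self.kkin
            rt = r * g
            g_nu = (np.sum(cot_r * own, axis=0)
                    - (sfactor[:, None] * q).sum(axis=0)
                    + np.sum(w[:, [self.i_qm]] * (-rt), axis=0))
            mech = np.column_stack([g_nu, g_keq, g_sigma, g_kkin])
        return mech, corr_grads

    def features(self, state: np.ndarray) -> np.ndarray:
        """Normalized correction-network inputs: [cm, c~_1.., q~_1..] with
        c~ = c/cinj and q~ = q/cinj per adsorbate; qm is excluded and the
        modifier passes through unscaled."""
        if self.cinj is None:
            raise ValueError("feature normalization needs injection concentrations")
        feat = np.empty((self.n_nodes, 2 * self.n_comp + 1))
        feat[:, 0] = state[:, self.i_cm]
        feat[:, 1:1 + self.n_comp] = state[:, self.c_slice] / self.cinj
        feat[:, 1 + self.n_comp:] = state[:, self.q_slice] / self.cinj
        return feat

    def feature_scales(self) -> np.ndarray:
        """d(feature)/d(state column) diagonal, matching features()."""
        return np.concatenate([[1.0], 1.0 / self.cinj, 1.0 / self.cinj])
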