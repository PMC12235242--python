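"""Nodal discontinuous-Galerkin discretization of the 1-D column.

A uniform mesh of K elements with degree-np Lagrange polynomials on
Legendre-Gauss-Lobatto (LGL) nodes. Convection uses an upwind numerical
flux, diffusion a local-DG (first-order system) formulation with central
fluxes. The Danckwerts inlet condition is imposed weakly by prescribing
the total (convective + dispersive) flux at z=0 as u/eps_t * c_in, which
is its exact flux form; the outlet uses a zero-dispersive-flux (Neumann)
condition with convective outflow.

The semi-discrete transport operator is affine in the field for fixed
boundary data, so it is assembled once per (velocity, dispersion) pair as
a matrix A and an inlet-injection vector g:

    dc/dt|transport = A @ c + c_in * g
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def lgl_nodes(order: int) -> np.ndarray:
    """Legendre-Gauss-Lobatto nodes on [-1, 1] for polynomial degree `order`."""
    if order == 1:
        return np.array([-1.0, 1.0])
    # interior nodes are roots of P'_order
    leg = np.polynomial.legendre.Legendre.basis(order)
    interior = leg.deriv().roots()
    return np.concatenate([[-1.0], np.sort(interior.real), [1.0]])


def _orthonormal_legendre_vandermonde(r: np.ndarray, order: int):
    """Vandermonde V[i,j] = Ptilde_j(r_i) and its derivative counterpart."""
    n = order + 1
    V = np.zeros((len(r), n))
    Vr = np.zeros((len(r), n))
    for j in range(n):
        coef = np.zeros(j + 1)
        coef[j] = 1.0
        scale = np.sqrt((2 * j + 1) / 2.0)  # orthonormal on [-1, 1]
        V[:, j] = scale * np.polynomial.legendre.legval(r, coef)
        Vr[:, j] = scale * np.polynomial.legendre.legval(
            r, np.polynomial.legendre.legder(coef))
    return V, Vr


@dataclass
class DGMesh:
    """Uniform nodal DG mesh of the column [0, L]."""

    n_elements: int
    poly_order: int
    length: float
    nodes: np.ndarray          # all K*(np+1) axial node positions
    element_width: float
    Dr: np.ndarray             # reference differentiation matrix
    lift: np.ndarray           # M^{-1} restricted to the two faces, (np+1, 2)

    @property
    def n_nodes(self) -> int:
        return self.n_elements * (self.poly_order + 1)

    @property
    def outlet_index(self) -> int:
        return self.n_nodes - 1

    def derivative(self, field: np.ndarray) -> np.ndarray:
        """Element-local derivative of a nodal field (exact up to degree np)."""
        c = np.asarray(field, dtype=float).reshape(self.n_elements, -1)
        return ((2.0 / self.element_width) * c @ self.Dr.T).ravel()

    def __repr__(self) -> str:  # log-friendly summary
        return (f"DGMesh(K={self.n_elements}, np={self.poly_order}, "
                f"L={self.length:g} m, {self.n_nodes} nodes)")


def build_mesh(n_elements: int, poly_order: int, length: float) -> DGMesh:
    """Build a uniform LGL nodal DG mesh with K elements of degree np."""
    if n_elements < 1 or poly_order < 1:
        raise ValueError("need at least one element of degree >= 1")
    if length <= 0:
        raise ValueError("column length must be positive")
    r = lgl_nodes(poly_order)
    V, Vr = _orthonormal_legendre_vandermonde(r, poly_order)
    Dr = Vr @ np.linalg.inv(V)
    # reference mass matrix M = inv(V V^T); lift = M^{-1} E = V V^T E
    VVt = V @ V.T
    lift = np.column_stack([VVt[:, 0], VVt[:, -1]])
    he = length / n_elements
    edges = np.arange(n_elements)[:, None] * he
    nodes = (edges + (r[None, :] + 1.0) * he / 2.0).ravel()
    return DGMesh(n_elements, poly_order, length, nodes, he, Dr, lift)


def _dg_apply(mesh: DGMesh, field: np.ndarray, v: float, Dapp: float,
              inlet_value: float) -> np.ndarray:
    """Apply -v dc/dz + Dapp d2c/dz2 with weak Danckwerts/Neumann BCs.

    v is the interstitial velocity u/eps_t (the flux balanced at the inlet
    is v*c - Dapp*dc/dz = v*c_in, which is the Danckwerts condition).
    """
    K, Np = mesh.n_elements, mesh.poly_order + 1
    c = np.asarray(field, dtype=float).reshape(K, Np)
    scale = 2.0 / mesh.element_width
    lift = mesh.lift

    # auxiliary gradient variable S ~ dc/dz (local DG, central flux for c)
    cl, cr = c[:, 0], c[:, -1]                      # face traces per element
    cstar_l = np.empty(K)
    cstar_r = np.empty(K)
    cstar_l[0] = cl[0]                              # boundary: interior trace
    cstar_r[-1] = cr[-1]
    inner = 0.5 * (cr[:-1] + cl[1:])                # central flux inside
    cstar_r[:-1] = inner
    cstar_l[1:] = inner
    jump = np.stack([-(cl - cstar_l), (cr - cstar_r)], axis=1)  # n*(c - c*)
    S = scale * (c @ mesh.Dr.T - jump @ lift.T)

    # total flux F = v c - Dapp S; numerical fluxes:
    Fl = v * cl - Dapp * S[:, 0]
    Fr = v * cr - Dapp * S[:, -1]
    Fstar_l = np.empty(K)
    Fstar_r = np.empty(K)
    # interior: upwind convection (flow to +z) + central dispersive flux
    Fstar_inner = v * cr[:-1] - Dapp * 0.5 * (S[:-1, -1] + S[1:, 0])
    Fstar_r[:-1] = Fstar_inner
    Fstar_l[1:] = Fstar_inner
    Fstar_l[0] = v * inlet_value                    # Danckwerts total flux
    Fstar_r[-1] = v * cr[-1]                        # Neumann: no disp. outflux
    F = v * c - Dapp * S
    fjump = np.stack([-(Fl - Fstar_l), (Fr - Fstar_r)], axis=1)
    rhs = scale * (-(F @ mesh.Dr.T) + fjump @ lift.T)
    return rhs.ravel()


def dg_convection_diffusion(mesh: DGMesh, field: np.ndarray, u: float,
                            eps_t: float, Dapp: float,
                            inlet_value: float) -> np.ndarray:
    """Semi-discrete -(u/eps_t) dc/dz + Dapp d2c/dz2 for one nodal field."""
    field = np.asarray(field, dtype=float)
    if field.shape != (mesh.n_nodes,):
        raise ValueError(f"field must have {mesh.n_nodes} nodes")
    return _dg_apply(mesh, field, u / eps_t, Dapp, inlet_value)


class TransportOperator:
    """Assembled affine transport operator for one method step.

    rhs = A @ c + inlet_value * g, with A the linear DG operator and g the
    inlet-injection vector. A and g depend on (u, Dapp) only, so one
    instance is shared by the modifier and all adsorbates within a step.
    """

    def __init__(self, mesh: DGMesh, u: float, eps_t: float, Dapp: float):
        self.mesh = mesh
        self.u = u
        self.eps_t = eps_t
        self.Dapp = Dapp
        n = mesh.n_nodes
        A = np.empty((n, n))
        e = np.zeros(n)
        for j in range(n):
            e[j] = 1.0
            A[:, j] = _dg_apply(mesh, e, u / eps_t, Dapp, 0.0)
            e[j] = 0.0
        self.A = A
        self.g = _dg_apply(mesh, np.zeros(n), u / eps_t, Dapp, 1.0)

    def apply(self, field: np.ndarray, inlet_value: float) -> np.ndarray:
        return self.A @ field + inlet_value * self.g
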