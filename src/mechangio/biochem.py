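"""Explicit (forward-Euler, mass-lumped) FE solver for the tissue
biochemistry: TAF τ, oxygen ξ, MMP μ (reaction–diffusion) and the ECM
density ε (pointwise ODE).

All species are normalised; diffusion acts in the reference (Lagrangian)
frame with natural zero-flux boundaries, so with sources and decay switched
off the lumped-mass integral of each species is conserved to round-off.
TAF production is evaluated nodally (it depends on the nodal oxygen field);
oxygen and MMP production depend on the per-element vascular densities ρ_v,
ρ_t and are distributed to nodes with consistent FE weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .mesh import Mesh, gauss_points, shape_functions, shape_gradients
from .params import BiochemParams, SECONDS_PER_DAY


@dataclass
class TissueFields:
    """Nodal fields (all dimensionless, ≥ 0; ε ∈ (0,1])."""

    taf: np.ndarray
    oxy: np.ndarray
    mmp: np.ndarray
    ecm: np.ndarray

    def copy(self) -> "TissueFields":
        return TissueFields(self.taf.copy(), self.oxy.copy(),
                            self.mmp.copy(), self.ecm.copy())


def initial_fields(mesh: Mesh) -> TissueFields:
    """τ = ξ = μ = 0 everywhere except ξ = 1 in the healthy tissue;
    ε = 1 in the entire domain."""
    n = mesh.n_nodes
    oxy = np.where(mesh.node_in_tumour, 0.0, 1.0)
    return TissueFields(taf=np.zeros(n), oxy=oxy, mmp=np.zeros(n),
                        ecm=np.ones(n))


def taf_production(oxy, in_tumour, params: BiochemParams):
    """TAF production rate Q(ξ) = λ_τ exp(−2ξ/ξ̄) inside Ω^T, 0 elsewhere."""
    oxy = np.asarray(oxy, dtype=float)
    q = params.lambda_taf * np.exp(-2.0 * oxy / params.oxy_scale)
    return np.where(np.asarray(in_tumour, dtype=bool), q, 0.0)


def mmp_production(rho_t, in_tumour, params: BiochemParams):
    """MMP production F = λ_μ-c + λ_μ-v ρ_t in Ω^T; λ_μ-v ρ_t elsewhere."""
    rho_t = np.asarray(rho_t, dtype=float)
    base = params.lambda_mmp_v * rho_t
    return base + np.where(np.asarray(in_tumour, dtype=bool),
                           params.lambda_mmp_c, 0.0)


def step_ecm(ecm, mmp, dt, host_mask, params: BiochemParams):
    """Forward-Euler ε ← ε(1 − δ_ε μ Δt) on host nodes, floored > 0."""
    ecm = np.asarray(ecm, dtype=float)
    mmp = np.asarray(mmp, dtype=float)
    if np.any(ecm < 0) or np.any(mmp < 0):
        raise ValueError("negative ECM density or MMP concentration")
    out = ecm.copy()
    factor = 1.0 - params.delta_ecm * mmp[host_mask] * dt
    out[host_mask] = np.maximum(ecm[host_mask] * factor, params.ecm_floor)
    return out


def stable_timestep(mesh: Mesh, params: BiochemParams,
                    solid_dt_days: float = 1.0 / 24.0) -> float:
    """Stable explicit step: the diffusive CFL-type bound
    Δt = safety·h_min²/(2·dim·D_max), additionally capped by the fastest
    reaction (safety/δ_max, keeping the decay update positive) and by the
    solid-solver step for degenerate diffusionless systems.  Days."""
    bounds = [solid_dt_days]
    d_max = params.d_max()
    if d_max > 0:
        h = mesh.min_edge_length
        bounds.append(params.cfl_safety * h * h / (2.0 * 3.0 * d_max))
    delta_max = max(params.delta_taf, params.delta_oxy, params.delta_mmp)
    if delta_max > 0:
        bounds.append(params.cfl_safety / delta_max)
    return min(bounds)


class BiochemSolver:
    """Precomputes lumped mass and stiffness operators on the mesh."""

    def __init__(self, mesh: Mesh, params: BiochemParams):
        self.mesh = mesh
        self.params = params
        pts, w = gauss_points()
        dN = shape_gradients(pts)                        # (8qp, 8a, 3)
        xc = mesh.elem_coords                            # (nel, 8, 3)
        J = np.einsum("qaj,eai->eqij", dN, xc)
        detJ = np.linalg.det(J)                          # (nel, 8qp)
        Jinv = np.linalg.inv(J)
        # dN/dX (nel, qp, a, 3)
        self.dNdX = np.einsum("qaj,eqji->eqai", dN, Jinv)
        self.detJw = detJ * w                            # (nel, qp)
        N = shape_functions(pts)                         # (qp, a)
        # element lumped masses ∫_e N_a  → (nel, 8)
        self.elem_mass = np.einsum("qa,eq->ea", N, self.detJw)
        n = mesh.n_nodes
        self.mass = np.zeros(n)
        np.add.at(self.mass, mesh.elems, self.elem_mass)
        # stiffness ∫ ∇N_a · ∇N_b
        Ke = np.einsum("eqai,eqbi,eq->eab", self.dNdX, self.dNdX, self.detJw)
        rows = np.repeat(mesh.elems, 8, axis=1).ravel()
        cols = np.tile(mesh.elems, (1, 8)).ravel()
        K = sparse.coo_matrix((Ke.ravel(), (rows, cols)),
                              shape=(n, n)).tocsr()
        # low-order M-matrix transport operator: positive off-diagonal
        # entries (trilinear corner couplings) are dropped and the diagonal
        # restored so row sums stay zero — keeps the explicit update both
        # conservative and positivity-preserving under the CFL bound
        K = K.tocoo()
        off = K.row != K.col
        data = K.data.copy()
        data[off] = np.minimum(data[off], 0.0)
        data[~off] = 0.0
        Klo = sparse.coo_matrix((data, (K.row, K.col)), shape=(n, n)).tocsr()
        diag = -np.asarray(Klo.sum(axis=1)).ravel()
        self.K = (Klo + sparse.diags(diag)).tocsr()
        self.node_in_tumour = mesh.node_in_tumour
        self.host_nodes = ~self.node_in_tumour
        self.clipped_mass = 0.0
        self.total_steps = 0

    # ---- operators -----------------------------------------------------
    def element_rate_to_nodes(self, rate_e: np.ndarray) -> np.ndarray:
        """Distribute a per-element volumetric rate to nodes with consistent
        FE weights (lumped)."""
        s = np.zeros(self.mesh.n_nodes)
        np.add.at(s, self.mesh.elems, self.elem_mass * rate_e[:, None])
        return s / self.mass

    def step_reaction_diffusion(self, field, D, source, decay, dt):
        """One explicit step of df/dt = D ∆f + source − decay·f with
        zero-flux boundaries; small negative undershoots clipped to zero."""
        field = np.asarray(field, dtype=float)
        out = field + dt * (-D * (self.K @ field) / self.mass
                            + source - decay * field)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(
                "non-finite value in reaction–diffusion update")
        neg = out < 0
        if neg.any():
            self.clipped_mass += float(-(out[neg] * self.mass[neg]).sum())
            total = float((np.abs(out) * self.mass).sum())
            if total > 0 and self.clipped_mass > 1e-6 * total:
                raise FloatingPointError(
                    "clipped negative mass exceeds 1e-6 of total — "
                    "time step too large")
            out[neg] = 0.0
        return out

    def integral(self, field) -> float:
        """Lumped-mass domain integral ∫_Ω f dV."""
        return float(np.dot(self.mass, field))

    # ---- coupled update ------------------------------------------------
    def step(self, fields: TissueFields, rho_v_elem: np.ndarray,
             rho_t_elem: np.ndarray, dt: float) -> TissueFields:
        p = self.params
        q_taf = taf_production(fields.oxy, self.node_in_tumour, p)
        src_oxy = self.element_rate_to_nodes(p.lambda_oxy * rho_v_elem)
        f_mmp = mmp_production(rho_t_elem, self.mesh.tumour_elems, p)
        src_mmp = self.element_rate_to_nodes(f_mmp)
        taf = self.step_reaction_diffusion(fields.taf, p.D_taf, q_taf,
                                           p.delta_taf, dt)
        oxy = self.step_reaction_diffusion(fields.oxy, p.D_oxy, src_oxy,
                                           p.delta_oxy, dt)
        mmp = self.step_reaction_diffusion(fields.mmp, p.D_mmp, src_mmp,
                                           p.delta_mmp, dt)
        ecm = step_ecm(fields.ecm, fields.mmp, dt, self.host_nodes, p)
        self.total_steps += 1
        return TissueFields(taf=taf, oxy=oxy, mmp=mmp, ecm=ecm)

    def advance(self, fields: TissueFields, rho_v_elem, rho_t_elem,
                total_dt: float, dt: float) -> TissueFields:
        """Sub-cycle :meth:`step` over ``total_dt`` in stable increments."""
        n_sub = max(1, int(np.ceil(total_dt / dt - 1e-12)))
        sub = total_dt / n_sub
        for _ in range(n_sub):
            fields = self.step(fields, rho_v_elem, rho_t_elem, sub)
        return fields

    # ---- gradients ------------------------------------------------------
    def gradients_qp(self, field) -> np.ndarray:
        """Field gradients at all quadrature points, shape (nel, 8, 3)."""
        vals = np.asarray(field, dtype=float)[self.mesh.elems]  # (nel, 8a)
        return np.einsum("eqai,ea->eqi", self.dNdX, vals)

    def element_gradient(self, field) -> np.ndarray:
        """Quadrature-volume-weighted mean gradient per element (nel, 3)."""
        g = self.gradients_qp(field)
        w = self.detJw
        return np.einsum("eqi,eq->ei", g, w) / w.sum(axis=1)[:, None]
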