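"""Quasi-static nonlinear FE solver for tissue mechanics with oxygen-driven
multiplicative growth and ECM-integrity-scaled hyperelasticity.

Kinematics follow the multiplicative decomposition F = F_e·F_g.  The growth
part combines an isotropic volumetric stretch λ_g(ϑ_g(ξ)) with directional
stretches along the (unit-normalised) oxygen and ECM gradients.  The
constitutive law is a generalised polynomial stored-energy function of the
deviatoric invariants of the elastic right Cauchy–Green tensor, with the
isochoric part scaled by the matrix integrity factor ζ ∈ (0,1] and an
unscaled volumetric penalty κ(J−1)²/2.  Equilibrium ∂/∂X·(F·S) = 0 is
solved by Newton–Raphson with load stepping on the growth tensor.

Stress measures: ``S`` here is the second Piola–Kirchhoff stress conjugate
to the elastic Green–Lagrange strain (the tensor used for tissue hydrostatic
pressure and mechanotaxis); the equilibrium residual uses its pull-back to
the reference configuration, J_g F_g⁻¹ S F_g⁻ᵀ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import Mesh, gauss_points, shape_gradients, shape_functions
from .params import SolidParams, MaterialParams, GrowthTriplet, MMHG_PER_KPA

_EYE = np.eye(3)


# ---------------------------------------------------------------------------
# growth laws
# ---------------------------------------------------------------------------
def growth_volume_strain(oxy, triplet: GrowthTriplet):
    """Gompertz-type volumetric growth strain
    ϑ(ξ) = α exp(−β exp(−γξ)) − α exp(−β); ϑ(0) = 0."""
    oxy = np.asarray(oxy, dtype=float)
    a, b, g = triplet.alpha, triplet.beta, triplet.gamma
    return a * np.exp(-b * np.exp(-g * oxy)) - a * np.exp(-b)


def stretch_from_strain(theta):
    """λ = √(2ϑ + 1) from the Green–Lagrange volume strain."""
    theta = np.asarray(theta, dtype=float)
    arg = 2.0 * theta + 1.0
    if np.any(arg <= 0):
        raise ValueError("growth strain ϑ ≤ −1/2 gives no real stretch")
    return np.sqrt(arg)


def _unit_or_zero(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(n > 1e-12, v / np.where(n > 0, n, 1.0), 0.0)
    return u


def growth_tensor(theta_g, theta_g_oxy, theta_g_ecm, grad_oxy, grad_ecm,
                  grad_scale: float = 1e-2):
    """F_g = λ_g I + (λ_g-ξ − λ_g) n̂_ξ⊗n̂_ξ + (λ_g-ε − λ_g) n̂_ε⊗n̂_ε.

    Gradient arguments are normalised to unit vectors before the dyadic
    products; a vanishing gradient drops its directional term.  The drop is
    smoothed: each directional term is weighted by |∇|²/(|∇|² +
    grad_scale²) so that numerically tiny gradients (whose direction is
    noise) fade out instead of flipping the anisotropy axis from point to
    point.  ``grad_scale`` is small against genuine interface gradients
    (~1/mm).  Broadcasts over leading axes.
    """
    lam = stretch_from_strain(theta_g)[..., None, None]
    lam_o = stretch_from_strain(theta_g_oxy)[..., None, None]
    lam_e = stretch_from_strain(theta_g_ecm)[..., None, None]

    def taper(g):
        mag2 = np.sum(np.asarray(g, dtype=float) ** 2, axis=-1)
        return (mag2 / (mag2 + grad_scale ** 2))[..., None, None]

    n_o = _unit_or_zero(grad_oxy)
    n_e = _unit_or_zero(grad_ecm)
    dyad_o = n_o[..., :, None] * n_o[..., None, :]
    dyad_e = n_e[..., :, None] * n_e[..., None, :]
    return (lam * _EYE + taper(grad_oxy) * (lam_o - lam) * dyad_o
            + taper(grad_ecm) * (lam_e - lam) * dyad_e)


# ---------------------------------------------------------------------------
# constitutive law (batched over leading axes)
# ---------------------------------------------------------------------------
def strain_energy(C_e, zeta, mat: MaterialParams):
    """W̄(C_e) with ζ-scaled isochoric terms and unscaled κ(J−1)²/2."""
    C_e = np.asarray(C_e, dtype=float)
    detC = np.linalg.det(C_e)
    J = np.sqrt(detC)
    I1 = np.trace(C_e, axis1=-2, axis2=-1)
    C2 = C_e @ C_e
    I2 = 0.5 * (I1 ** 2 - np.trace(C2, axis1=-2, axis2=-1))
    i1 = J ** (-2.0 / 3.0) * I1 - 3.0
    i2 = J ** (-4.0 / 3.0) * I2 - 3.0
    iso = (mat.c10 * i1 + mat.c20 * i1 ** 2 + mat.c01 * i2
           + mat.c02 * i2 ** 2 + mat.c11 * i1 * i2)
    return zeta * iso + 0.5 * mat.kappa * (J - 1.0) ** 2


def pk2_stress(C_e, zeta, mat: MaterialParams):
    """S = 2 ∂W̄/∂C_e (second Piola–Kirchhoff, elastic configuration).

    Inadmissible states (det C ≤ 0) yield NaNs, which the Newton driver
    detects and converts into load-step cutbacks.
    """
    C_e = np.asarray(C_e, dtype=float)
    Cinv = np.linalg.inv(C_e)
    detC = np.linalg.det(C_e)
    with np.errstate(invalid="ignore"):
        J = np.sqrt(detC)[..., None, None]
    I1 = np.trace(C_e, axis1=-2, axis2=-1)[..., None, None]
    C2 = C_e @ C_e
    I2 = (0.5 * (I1[..., 0, 0] ** 2
                 - np.trace(C2, axis1=-2, axis2=-1)))[..., None, None]
    Jf = J
    i1 = (Jf[..., 0, 0] ** (-2.0 / 3.0) * I1[..., 0, 0] - 3.0)
    i2 = (Jf[..., 0, 0] ** (-4.0 / 3.0) * I2[..., 0, 0] - 3.0)
    zeta = np.asarray(zeta, dtype=float)
    w1 = (zeta * (mat.c10 + 2.0 * mat.c20 * i1 + mat.c11 * i2))[..., None, None]
    w2 = (zeta * (mat.c01 + 2.0 * mat.c02 * i2 + mat.c11 * i1))[..., None, None]
    dI1b = Jf ** (-2.0 / 3.0) * (_EYE - (I1 / 3.0) * Cinv)
    dI2b = Jf ** (-4.0 / 3.0) * (I1 * _EYE - C_e - (2.0 * I2 / 3.0) * Cinv)
    S = 2.0 * (w1 * dI1b + w2 * dI2b) + mat.kappa * (Jf - 1.0) * Jf * Cinv
    return S


def elastic_stress(F, F_g, zeta, mat: MaterialParams):
    """S(F, F_g, ζ): 2nd PK stress in the elastic (intermediate) setting."""
    F = np.asarray(F, dtype=float)
    Fg_inv = np.linalg.inv(np.asarray(F_g, dtype=float))
    F_e = F @ Fg_inv
    C_e = np.swapaxes(F_e, -1, -2) @ F_e
    return pk2_stress(C_e, zeta, mat)


def cauchy_stress(F, F_g, zeta, mat: MaterialParams):
    """Cauchy stress σ = J_e⁻¹ F_e S F_eᵀ."""
    F = np.asarray(F, dtype=float)
    Fg_inv = np.linalg.inv(np.asarray(F_g, dtype=float))
    F_e = F @ Fg_inv
    C_e = np.swapaxes(F_e, -1, -2) @ F_e
    S = pk2_stress(C_e, zeta, mat)
    Je = np.linalg.det(F_e)[..., None, None]
    return (F_e @ S @ np.swapaxes(F_e, -1, -2)) / Je


def hydrostatic_pressure_from_stress(stress):
    """THP = −tr(σ)/3: positive under compression."""
    return -np.trace(np.asarray(stress, dtype=float),
                     axis1=-2, axis2=-1) / 3.0


def traction_direction(S, prev_dir):
    """Unit eigenvector of the algebraically smallest eigenvalue of S,
    signed so the mechanotaxis term −k_m t does not oppose the previous
    direction; isotropic (degenerate) stress falls back to −prev_dir."""
    S = np.asarray(S, dtype=float)
    single = S.ndim == 2
    Sb = S[None] if single else S
    prev = np.atleast_2d(np.asarray(prev_dir, dtype=float))
    w, v = np.linalg.eigh(Sb)
    t = v[..., :, 0]
    degen = (w[..., -1] - w[..., 0]) <= 1e-12 * np.maximum(
        1.0, np.abs(w).max(axis=-1))
    proj = np.einsum("...i,...i->...", t, prev)
    t = np.where((proj > 0)[..., None], -t, t)
    have_prev = np.linalg.norm(prev, axis=-1) > 1e-12
    fall = degen & have_prev
    t = np.where(fall[..., None], -_unit_or_zero(prev), t)
    return t[0] if single else t


# ---------------------------------------------------------------------------
# FE solver
# ---------------------------------------------------------------------------
_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


@dataclass
class SolidState:
    """Converged solid solution and derived per-quadrature-point data."""

    u: np.ndarray                    # (n_nodes, 3) displacements, mm
    F: np.ndarray                    # (nel, 8, 3, 3)
    F_g: np.ndarray
    S: np.ndarray                    # elastic 2nd PK stress (kPa)
    cauchy: np.ndarray               # Cauchy stress (kPa)
    J: np.ndarray                    # det F
    zeta: np.ndarray                 # (nel, 8)
    thp_elem_kpa: np.ndarray = field(default=None)
    thp_node_kpa: np.ndarray = field(default=None)


class NonConvergenceError(RuntimeError):
    pass


class SolidSolver:
    def __init__(self, mesh: Mesh, params: SolidParams):
        self.mesh = mesh
        self.params = params
        pts, w = gauss_points()
        dN = shape_gradients(pts)
        xc = mesh.elem_coords
        J0 = np.einsum("qaj,eai->eqij", dN, xc)
        self.detJw = np.linalg.det(J0) * w              # (nel, 8)
        J0inv = np.linalg.inv(J0)
        self.dNdX = np.einsum("qaj,eqji->eqai", dN, J0inv)  # (nel, 8q, 8a, 3)
        self.tumour = mesh.tumour_elems
        nel = mesh.n_elems
        # global dof indices per element (24)
        edofs = (3 * mesh.elems[:, :, None]
                 + np.arange(3)[None, None, :]).reshape(nel, 24)
        self.edofs = edofs
        self.Krows = np.repeat(edofs, 24, axis=1).ravel()
        self.Kcols = np.tile(edofs, (1, 24)).ravel()
        self.ndof = 3 * mesh.n_nodes
        # default Dirichlet: pinned inlet/outlet planes
        pinned = np.where(mesh.tagged_face_nodes)[0]
        self.default_fixed = (3 * pinned[:, None]
                              + np.arange(3)[None, :]).ravel()

    # ---- pointwise stress over the two materials -----------------------
    def _stress_all(self, C_e, zeta):
        S = np.empty_like(C_e)
        for mask, mat in ((~self.tumour, self.params.host),
                          (self.tumour, self.params.tumour)):
            if mask.any():
                S[mask] = pk2_stress(C_e[mask], zeta[mask], mat)
        return S

    def _deformation(self, u, Fg_inv):
        ue = u.reshape(-1, 3)[self.mesh.elems]          # (nel, 8a, 3)
        gradu = np.einsum("eai,eqaj->eqij", ue, self.dNdX)
        F = _EYE + gradu
        F_e = F @ Fg_inv
        C_e = np.swapaxes(F_e, -1, -2) @ F_e
        return F, F_e, C_e

    def _sref(self, C_e, zeta, Fg_inv, Jg):
        S_e = self._stress_all(C_e, zeta)
        S_ref = Jg[..., None, None] * (
            Fg_inv @ S_e @ np.swapaxes(Fg_inv, -1, -2))
        return S_e, S_ref

    def _internal_force(self, F, S_ref):
        P = F @ S_ref
        fe = np.einsum("eqiJ,eqaJ,eq->eai", P, self.dNdX, self.detJw)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edofs, fe.reshape(len(fe), 24))
        return f

    def _material_tangent(self, C_e, zeta, Fg_inv, Jg):
        """D = dS_ref,voigt/dE_voigt by central differences on the total
        Green–Lagrange strain (E measured in the reference setting).

        All 12 perturbed states are stacked along the quadrature axis and
        evaluated in a single batched stress call.  The step balances
        truncation against roundoff so the tangent is accurate to ~1e-9
        relative, which Newton needs to reach the 1e-8 residual tolerance.
        """
        h = 1e-5
        nel, q = C_e.shape[:2]
        D = np.empty((nel, q, 6, 6))
        Fg = np.linalg.inv(Fg_inv)
        C_ref = np.swapaxes(Fg, -1, -2) @ C_e @ Fg
        pieces = []
        for k, (i, j) in enumerate(_VOIGT):
            # perturb so each Voigt strain component (engineering shear)
            # changes by exactly h: δC = 2δE
            dC = np.zeros((3, 3))
            if i == j:
                dC[i, i] = 2.0
            else:
                dC[i, j] = dC[j, i] = 1.0
            pieces.append(C_ref + h * dC)
            pieces.append(C_ref - h * dC)
        C_big = np.concatenate(pieces, axis=1)            # (nel, 12q, 3, 3)
        Fg_inv_big = np.concatenate([Fg_inv] * 12, axis=1)
        zeta_big = np.concatenate([zeta] * 12, axis=1)
        Jg_big = np.concatenate([Jg] * 12, axis=1)
        Ce_big = np.swapaxes(Fg_inv_big, -1, -2) @ C_big @ Fg_inv_big
        S_big = Jg_big[..., None, None] * (
            Fg_inv_big @ self._stress_all(Ce_big, zeta_big)
            @ np.swapaxes(Fg_inv_big, -1, -2))
        for k in range(6):
            Sp = S_big[:, (2 * k) * q:(2 * k + 1) * q]
            Sm = S_big[:, (2 * k + 1) * q:(2 * k + 2) * q]
            dS = (Sp - Sm) / (2.0 * h)
            for r, (a, b) in enumerate(_VOIGT):
                D[..., r, k] = dS[..., a, b]
        # symmetrise (FD noise)
        return 0.5 * (D + np.swapaxes(D, -1, -2))

    def _b_matrix(self, F):
        """Strain-displacement matrix, (nel, q, 6, 24): δE_voigt = B δu."""
        nel, q = F.shape[:2]
        dN = self.dNdX                                   # (nel,q,8,3)
        B = np.zeros((nel, q, 6, 8, 3))
        for r, (I, Jj) in enumerate(_VOIGT):
            if I == Jj:
                B[:, :, r] = np.einsum("eqk,eqa->eqak", F[..., :, I],
                                       dN[..., I])
            else:
                B[:, :, r] = (np.einsum("eqk,eqa->eqak", F[..., :, I],
                                        dN[..., Jj])
                              + np.einsum("eqk,eqa->eqak", F[..., :, Jj],
                                          dN[..., I]))
        return B.reshape(nel, q, 6, 24)

    def _assemble(self, F, S_ref, D):
        B = self._b_matrix(F)
        DB = np.einsum("eqrs,eqsB->eqrB", D, B, optimize=True)
        Kmat = np.einsum("eqrA,eqrB,eq->eAB", B, DB, self.detJw,
                         optimize=True)
        # geometric stiffness: (dNa·S·dNb) δ_ij
        g = np.einsum("eqaJ,eqJI,eqbI,eq->eab", self.dNdX, S_ref, self.dNdX,
                      self.detJw, optimize=True)
        Kgeo = np.einsum("eab,ij->eaibj", g, _EYE).reshape(len(g), 24, 24)
        Ke = Kmat + Kgeo
        K = sparse.coo_matrix((Ke.ravel(), (self.Krows, self.Kcols)),
                              shape=(self.ndof, self.ndof)).tocsc()
        return K

    def _newton(self, Fg_qp, zeta_qp, u0, fixed_dofs, fixed_vals):
        p = self.params
        Fg_inv = np.linalg.inv(Fg_qp)
        Jg = np.linalg.det(Fg_qp)
        u = u0.copy().ravel()
        u[fixed_dofs] = fixed_vals
        free = np.setdiff1d(np.arange(self.ndof), fixed_dofs,
                            assume_unique=False)
        ref_scale = None
        lu = None
        best_res = np.inf
        stalled = 0
        for it in range(p.newton_maxit):
            F, F_e, C_e = self._deformation(u, Fg_inv)
            if np.any(np.linalg.det(F_e) <= 0):
                raise NonConvergenceError("non-positive elastic Jacobian")
            S_e, S_ref = self._sref(C_e, zeta_qp, Fg_inv, Jg)
            r = self._internal_force(F, S_ref)
            res = np.linalg.norm(r[free])
            if ref_scale is None:
                stress_scale = float(np.abs(S_ref).max())
                ref_scale = max(res, stress_scale * self.detJw.sum() ** (1 / 3),
                                1e-12)
            if res < p.newton_rtol * ref_scale:
                return u.reshape(-1, 3)
            # stagnation guard: hand control back to load stepping when a
            # fresh-tangent iteration repeatedly fails to improve
            if res < 0.9995 * best_res:
                best_res = res
                stalled = 0
            else:
                stalled += 1
                if stalled >= 10:
                    raise NonConvergenceError(
                        f"Newton stagnated at residual {res:.3e} "
                        f"(scale {ref_scale:.3e})")
            D = self._material_tangent(C_e, zeta_qp, Fg_inv, Jg)
            if not np.all(np.isfinite(D)):
                # near-degenerate element: a ±h perturbation crossed det=0
                raise NonConvergenceError(
                    "non-finite tangent (element close to inversion)")
            K = self._assemble(F, S_ref, D)
            Kff = K[free][:, free]
            try:
                lu = splu(Kff, permc_spec="MMD_AT_PLUS_A")
            except RuntimeError as exc:
                raise NonConvergenceError(
                    f"singular tangent factorisation: {exc}") from exc
            du = np.zeros(self.ndof)
            du[free] = -lu.solve(r[free])
            if not np.all(np.isfinite(du)):
                raise NonConvergenceError("non-finite Newton increment")
            # backtracking line search on the residual norm; steps that
            # invert any element are never accepted
            step = 1.0
            accepted = False
            for _ in range(12):
                u_try = u + step * du
                Ft, Fet, Ct = self._deformation(u_try, Fg_inv)
                if np.all(np.linalg.det(Fet) > 0):
                    _, Srt = self._sref(Ct, zeta_qp, Fg_inv, Jg)
                    rt = self._internal_force(Ft, Srt)
                    if np.linalg.norm(rt[free]) < res * (1 - 1e-4 * step) \
                            or step <= 0.25:
                        accepted = True
                        break
                step *= 0.5
            if not accepted:
                raise NonConvergenceError("line search found no admissible "
                                          "step")
            u = u + step * du
            if np.linalg.norm(step * du[free]) < p.newton_utol * max(
                    1.0, np.linalg.norm(u[free])):
                return u.reshape(-1, 3)
        raise NonConvergenceError(
            f"Newton did not converge in {p.newton_maxit} iterations "
            f"(residual {res:.3e}, scale {ref_scale:.3e})")

    def solve(self, Fg_qp: np.ndarray, zeta_qp: np.ndarray,
              u0: Optional[np.ndarray] = None,
              fixed_dofs: Optional[np.ndarray] = None,
              fixed_vals: Optional[np.ndarray] = None,
              Fg_prev: Optional[np.ndarray] = None) -> SolidState:
        """Solve equilibrium for the given growth tensor and integrity
        fields (per quadrature point); returns the converged state.

        Default boundary conditions: zero displacement on the two
        inlet/outlet planes, traction-free elsewhere.  When the full-step
        Newton fails, the growth tensor is load-stepped from ``Fg_prev``
        (the previously converged growth state that ``u0`` equilibrates;
        identity by default) toward ``Fg_qp``.
        """
        p = self.params
        if u0 is None:
            u0 = np.zeros((self.mesh.n_nodes, 3))
        if fixed_dofs is None:
            fixed_dofs = self.default_fixed
            fixed_vals = np.zeros(len(fixed_dofs))
        fixed_dofs = np.asarray(fixed_dofs, dtype=int)
        fixed_vals = np.zeros(len(fixed_dofs)) if fixed_vals is None \
            else np.asarray(fixed_vals, dtype=float)
        if Fg_prev is None:
            Fg_prev = np.broadcast_to(_EYE, Fg_qp.shape)
        n_steps = 1
        for attempt in range(p.max_cutbacks + 1):
            try:
                u = u0.copy()
                for s in range(1, n_steps + 1):
                    alpha = s / n_steps
                    Fg_s = Fg_prev + alpha * (Fg_qp - Fg_prev)
                    u = self._newton(Fg_s, zeta_qp, u, fixed_dofs, fixed_vals)
                break
            except NonConvergenceError:
                if attempt == p.max_cutbacks:
                    raise
                n_steps *= 2
        Fg_inv = np.linalg.inv(Fg_qp)
        Jg = np.linalg.det(Fg_qp)
        F, F_e, C_e = self._deformation(u.ravel(), Fg_inv)
        S_e = self._stress_all(C_e, zeta_qp)
        Je = np.linalg.det(F_e)
        sig = (F_e @ S_e @ np.swapaxes(F_e, -1, -2)) / Je[..., None, None]
        state = SolidState(u=u, F=F, F_g=Fg_qp, S=S_e, cauchy=sig,
                           J=np.linalg.det(F), zeta=zeta_qp)
        basis = sig if p.cauchy_pressure else S_e
        thp_qp = hydrostatic_pressure_from_stress(basis)      # (nel, 8) kPa
        w = self.detJw
        state.thp_elem_kpa = (thp_qp * w).sum(axis=1) / w.sum(axis=1)
        state.thp_node_kpa = self.project_elem_to_nodes(state.thp_elem_kpa)
        return state

    def project_elem_to_nodes(self, elem_vals: np.ndarray) -> np.ndarray:
        """Volume-weighted projection of element values to mesh nodes."""
        vol = self.detJw.sum(axis=1)
        num = np.zeros(self.mesh.n_nodes)
        den = np.zeros(self.mesh.n_nodes)
        np.add.at(num, self.mesh.elems,
                  (elem_vals * vol)[:, None] / 8.0 * np.ones(8))
        np.add.at(den, self.mesh.elems, vol[:, None] / 8.0 * np.ones(8))
        return num / np.maximum(den, 1e-300)

    def thp_at_points(self, state: SolidState, elem_ids, locals_,
                      mmhg: bool = True) -> np.ndarray:
        """THP interpolated at embedded points via trilinear weights."""
        vals = state.thp_node_kpa[self.mesh.elems[elem_ids]]    # (k, 8)
        N = shape_functions(locals_)
        out = np.einsum("ka,ka->k", N, vals)
        return out * MMHG_PER_KPA if mmhg else out
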