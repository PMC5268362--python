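"""Quasi-steady coupled vascular/interstitial/transvascular flow.

One symmetric sparse linear system is solved for all pressure unknowns:
vascular node pressures p_vsc (Poiseuille conductances along segments),
interstitial pressures p_int on the tissue mesh nodes (Darcy conductances
along element edges), and Starling exchange between each functional
vascular node and the eight vertices of its host element (a conductance
star weighted by the trilinear shape functions, so the exchange flux is
K_vsc·A_vsc·(p_eff − p_int) with p_int interpolated at the vascular node).

Dirichlet anchors: inlet nodes 25 mm-Hg, outlet nodes 10 mm-Hg, collapsed
vascular nodes 0, tissue nodes on the inlet/outlet planes 0.1 mm-Hg.
Pressures in mm-Hg, lengths in mm, flows in mm³/s, velocities in mm/s,
wall shear stress in mm-Hg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import Mesh, shape_functions
from .network import VascularNetwork, STATE_COLLAPSED
from .params import FluidParams

UM_PER_MM = 1000.0


def segment_conductance(radius_mm, length_mm, mu_blood):
    """Poiseuille conductance πR⁴/(8 μ_B L)."""
    radius_mm = np.asarray(radius_mm, dtype=float)
    return np.pi * radius_mm ** 4 / (8.0 * mu_blood * length_mm)


def wall_conductivity(r_pore_mm, gamma_pore, mu_blood, thickness_mm):
    """Starling wall hydraulic conductivity K_vsc = γ_p r_p²/(8 μ_B h)."""
    r_pore_mm = np.asarray(r_pore_mm, dtype=float)
    return gamma_pore * r_pore_mm ** 2 / (8.0 * mu_blood * thickness_mm)


def effective_pressure(p_vsc, pi_vsc, pi_int, sigma_osmotic):
    """p_eff = p_vsc − (π_vsc − π_int)·σ_o."""
    return np.asarray(p_vsc, dtype=float) - (pi_vsc - pi_int) * sigma_osmotic


@dataclass
class FlowSolution:
    p_vsc: np.ndarray          # (n_vnodes,)
    p_int: np.ndarray          # (n_tnodes,)
    seg_flow: np.ndarray       # (n_segments,) signed a→b, mm³/s (0 if cleaved)
    seg_velocity: np.ndarray   # (n_segments,) |v|, mm/s
    seg_wss: np.ndarray        # (n_segments,) τ_f, mm-Hg
    node_velocity: np.ndarray  # (n_vnodes,) mean |v| of attached segments
    node_wss: np.ndarray       # (n_vnodes,) mean τ_f of attached segments
    node_transvascular: np.ndarray  # (n_vnodes,) Starling flux, mm³/s
    edge_velocity: np.ndarray  # (n_edges,) interstitial |v|, mm/s
    edges: np.ndarray          # (n_edges, 2) tissue node pairs
    p_int_at_vnodes: np.ndarray  # interpolated IFP at vascular nodes

    def well_perfused_nodes(self, threshold: float) -> np.ndarray:
        return self.node_velocity >= threshold


class SingularFlowSystemError(RuntimeError):
    pass


def _element_vascular_geometry(network: VascularNetwork, mesh: Mesh,
                               lengths: np.ndarray, params: FluidParams):
    """Per-element vascular surface density S_vsc and mean radius R̄ from the
    current network (config defaults for vessel-free elements)."""
    half_len = np.zeros(network.n_nodes)
    fseg = network.functional_segments()
    np.add.at(half_len, network.segments[fseg, 0], 0.5 * lengths[fseg])
    np.add.at(half_len, network.segments[fseg, 1], 0.5 * lengths[fseg])
    R_mm = network.radius_um / UM_PER_MM
    surf = 2.0 * np.pi * R_mm * half_len          # per-node wall area, mm²
    S = np.zeros(mesh.n_elems)
    Rsum = np.zeros(mesh.n_elems)
    cnt = np.zeros(mesh.n_elems)
    ok = (network.host_elem >= 0) & network.functional_nodes()
    np.add.at(S, network.host_elem[ok], surf[ok])
    np.add.at(Rsum, network.host_elem[ok], R_mm[ok])
    np.add.at(cnt, network.host_elem[ok], 1.0)
    vols = mesh.element_volumes()
    S_vsc = np.where(cnt > 0, S / vols, params.S_vsc_default)
    R_bar = np.where(cnt > 0, Rsum / np.maximum(cnt, 1),
                     params.R_bar_default_um / UM_PER_MM)
    return S_vsc, R_bar, half_len


def solve_coupled_pressures(network: VascularNetwork, mesh: Mesh,
                            params: FluidParams,
                            displacements: Optional[np.ndarray] = None
                            ) -> FlowSolution:
    """Assemble and solve the coupled pressure system; derive per-segment
    flow, velocity and wall shear stress and per-edge interstitial velocity.
    Lengths use the deformed configuration when ``displacements`` is given.
    """
    nv = network.n_nodes
    nt = mesh.n_nodes
    n = nv + nt
    pos = network.current_positions(mesh, displacements)
    lengths = network.segment_lengths(pos)
    if np.any(lengths <= 0):
        raise ValueError("non-positive segment length")
    tissue_pos = mesh.nodes if displacements is None \
        else mesh.nodes + displacements

    b = np.zeros(n)
    pair_i, pair_j, pair_g = [], [], []

    def add_conds(i, j, g):
        pair_i.append(np.asarray(i, dtype=int))
        pair_j.append(np.asarray(j, dtype=int))
        pair_g.append(np.asarray(g, dtype=float))

    # ---- vascular Poiseuille edges ------------------------------------
    fseg = network.functional_segments()
    R_seg = 0.5 * (network.radius_um[network.segments[:, 0]]
                   + network.radius_um[network.segments[:, 1]]) / UM_PER_MM
    g_seg = np.where(fseg,
                     segment_conductance(R_seg, lengths, params.mu_blood),
                     0.0)
    sel = g_seg > 0
    add_conds(network.segments[sel, 0], network.segments[sel, 1], g_seg[sel])

    # ---- interstitial Darcy edges -------------------------------------
    edges, incident = mesh.element_edges()
    S_vsc, R_bar, half_len = _element_vascular_geometry(
        network, mesh, lengths, params)
    K_elem = np.where(mesh.tumour_elems, params.K_int_tumour,
                      params.K_int_host)
    A_int_elem = 2.0 * np.pi * R_bar / S_vsc
    edge_len = np.linalg.norm(tissue_pos[edges[:, 0]]
                              - tissue_pos[edges[:, 1]], axis=1)
    KA_prod = K_elem * A_int_elem
    eidx = np.concatenate([np.full(len(inc), k)
                           for k, inc in enumerate(incident)])
    eelm = np.concatenate([np.asarray(inc, dtype=int) for inc in incident])
    KA_sum = np.zeros(len(edges))
    KA_cnt = np.zeros(len(edges))
    np.add.at(KA_sum, eidx, KA_prod[eelm])
    np.add.at(KA_cnt, eidx, 1.0)
    KA_edge = KA_sum / np.maximum(KA_cnt, 1.0)
    g_edge = KA_edge / edge_len
    add_conds(nv + edges[:, 0], nv + edges[:, 1], g_edge)

    # ---- transvascular Starling stars ---------------------------------
    func = network.functional_nodes()
    hosted = func & (network.host_elem >= 0)
    K_vsc = wall_conductivity(network.pore_um / UM_PER_MM, params.gamma_pore,
                              params.mu_blood,
                              network.thickness_um / UM_PER_MM)
    A_vsc = 2.0 * np.pi * (network.radius_um / UM_PER_MM) * half_len
    g_node = K_vsc * A_vsc
    osmotic_shift = (params.pi_vsc - params.pi_int) * params.sigma_osmotic
    Nw = shape_functions(network.local)            # (nv, 8)
    hv = np.where(hosted & (g_node > 0))[0]
    if len(hv):
        verts = mesh.elems[network.host_elem[hv]]         # (k, 8)
        w = Nw[hv]                                        # (k, 8)
        gw = (g_node[hv][:, None] * w).ravel()
        vi = np.repeat(hv, 8)
        vj = nv + verts.ravel()
        keep = gw > 0
        add_conds(vi[keep], vj[keep], gw[keep])
        np.add.at(b, vj[keep], -gw[keep] * osmotic_shift)
        np.add.at(b, vi[keep], gw[keep] * osmotic_shift)

    pi = np.concatenate(pair_i)
    pj = np.concatenate(pair_j)
    pg = np.concatenate(pair_g)
    rows = np.concatenate([pi, pj, pi, pj])
    cols = np.concatenate([pi, pj, pj, pi])
    vals = np.concatenate([pg, pg, -pg, -pg])
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    # ---- Dirichlet anchors --------------------------------------------
    collapsed = network.state == STATE_COLLAPSED
    dir_idx, dir_val = [], []
    for mask, val in ((network.is_inlet & ~collapsed, params.p_inlet),
                      (network.is_outlet & ~collapsed, params.p_outlet),
                      (collapsed, 0.0)):
        ids = np.where(mask)[0]
        dir_idx.extend(ids.tolist())
        dir_val.extend([val] * len(ids))
    t_ids = np.where(mesh.tagged_face_nodes)[0]
    dir_idx.extend((nv + t_ids).tolist())
    dir_val.extend([params.p_boundary_int] * len(t_ids))
    dir_idx = np.asarray(dir_idx, dtype=int)
    dir_val = np.asarray(dir_val, dtype=float)
    if len(dir_idx) == 0:
        raise SingularFlowSystemError("no Dirichlet anchor in flow system")

    free = np.ones(n, dtype=bool)
    free[dir_idx] = False
    # guard against floating vascular components (no anchor, no exchange)
    diag = A.diagonal()
    float_rows = free & (diag <= 0)
    if np.any(float_rows[:nv]):
        raise SingularFlowSystemError(
            f"{int(float_rows[:nv].sum())} vascular nodes have no path to "
            "any anchor and no wall exchange — singular system")
    x = np.zeros(n)
    x[dir_idx] = dir_val
    fidx = np.where(free)[0]
    Aff = A[fidx][:, fidx].tocsc()
    rhs = b[fidx] - A[fidx][:, dir_idx] @ dir_val
    try:
        lu = splu(Aff)
        x[fidx] = lu.solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - singular factorization
        raise SingularFlowSystemError(str(exc)) from exc
    # iterative refinement: the conductance range spans many orders of
    # magnitude; the flux scale lives in the Dirichlet-eliminated rhs
    scale = max(np.abs(rhs).max() if len(rhs) else 0.0,
                np.abs(b).max(), 1e-12)
    for _ in range(3):
        resid = rhs - Aff @ x[fidx]
        if np.abs(resid).max() <= 1e-10 * scale:
            break
        x[fidx] += lu.solve(resid)
    resid = A @ x - b
    resid[dir_idx] = 0.0
    if np.abs(resid).max() > 1e-6 * scale:
        raise SingularFlowSystemError(
            f"flow solve residual {np.abs(resid).max():.3e} exceeds tolerance")

    p_vsc = x[:nv]
    p_int = x[nv:]
    p_vsc = np.where(collapsed, 0.0, p_vsc)

    # ---- derived quantities -------------------------------------------
    a_ids = network.segments[:, 0]
    b_ids = network.segments[:, 1]
    dp = p_vsc[a_ids] - p_vsc[b_ids]
    Q = np.where(fseg, g_seg * dp, 0.0)
    area = np.pi * R_seg ** 2
    v_seg = np.where(fseg & (area > 0), np.abs(Q) / area, 0.0)
    wss = np.where(fseg, R_seg * np.abs(dp) / lengths, 0.0)
    node_v = np.zeros(nv)
    node_w = np.zeros(nv)
    node_cnt = np.zeros(nv)
    np.add.at(node_v, a_ids[fseg], v_seg[fseg])
    np.add.at(node_v, b_ids[fseg], v_seg[fseg])
    np.add.at(node_w, a_ids[fseg], wss[fseg])
    np.add.at(node_w, b_ids[fseg], wss[fseg])
    np.add.at(node_cnt, a_ids[fseg], 1.0)
    np.add.at(node_cnt, b_ids[fseg], 1.0)
    node_v = node_v / np.maximum(node_cnt, 1.0)
    node_w = node_w / np.maximum(node_cnt, 1.0)
    p_at_v = np.zeros(nv)
    ok = network.host_elem >= 0
    p_at_v[ok] = np.einsum("ka,ka->k", Nw[ok],
                           p_int[mesh.elems[network.host_elem[ok]]])
    q_trv = np.where(hosted,
                     g_node * (effective_pressure(
                         p_vsc, params.pi_vsc, params.pi_int,
                         params.sigma_osmotic) - p_at_v),
                     0.0)
    # interstitial velocity v_int = −K Δp/L per edge (magnitude reported)
    K_sum = np.zeros(len(edges))
    np.add.at(K_sum, eidx, K_elem[eelm])
    K_edge = K_sum / np.maximum(KA_cnt, 1.0)
    dpe = p_int[edges[:, 0]] - p_int[edges[:, 1]]
    edge_v = np.abs(K_edge * dpe / edge_len)
    return FlowSolution(
        p_vsc=p_vsc, p_int=p_int, seg_flow=Q, seg_velocity=v_seg,
        seg_wss=wss, node_velocity=node_v, node_wss=node_w,
        node_transvascular=q_trv,
        edge_velocity=edge_v, edges=edges, p_int_at_vnodes=p_at_v)


def mass_balance(network: VascularNetwork, flow: FlowSolution
                 ) -> tuple[float, float, float]:
    """(total inflow at inlets, total outflow at outlets, net filtration).

    Global conservation requires inflow = outflow + filtration.
    """
    inflow = 0.0
    outflow = 0.0
    for (a, b), Q in zip(network.segments, flow.seg_flow):
        if network.is_inlet[a]:
            inflow += Q       # positive a→b leaves the inlet
        if network.is_inlet[b]:
            inflow -= Q
        if network.is_outlet[b]:
            outflow += Q
        if network.is_outlet[a]:
            outflow -= Q
    filtration = float(flow.node_transvascular[
        ~(network.is_inlet | network.is_outlet)].sum())
    return float(inflow), float(outflow), filtration
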