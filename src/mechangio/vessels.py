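"""Vascular network dynamics: mechano-chemically guided sprouting,
stochastic branching, anastomosis, shear-driven wall remodelling and
pressure-induced compression/collapse.

Tip guidance combines chemotaxis (∇τ), haptotaxis (∇ε) and mechanotaxis
(−k_m t, t the eigenvector of the smallest principal stress); tips advance
only where the TAF concentration exceeds the sprouting threshold τ*.  Wall
remodelling expands the lumen from R_min toward R_max on a time scale t_m
set by the local wall shear stress; compression follows a quadratic
pressure–strain constitutive law and collapse is permanent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .mesh import Mesh, shape_functions
from .network import (VascularNetwork, STATE_NORMAL, STATE_COMPRESSED,
                      STATE_COLLAPSED)
from .params import (TaxisParams, TipKineticsParams, BranchingParams,
                     BranchingClassParams, RemodellingParams, CollapseParams)
from .solid import traction_direction

UM_PER_MM = 1000.0


# ---------------------------------------------------------------------------
# elementary constitutive laws
# ---------------------------------------------------------------------------
def sprout_direction(grad_taf, grad_ecm, traction, prev_dir,
                     params: TaxisParams):
    """ê = ℓ/‖ℓ‖ with ℓ = k_τ∇τ + k_ε∇ε − k_m t; falls back to the
    previous direction for a vanishing ℓ."""
    ell = (params.k_taf * np.asarray(grad_taf, dtype=float)
           + params.k_ecm * np.asarray(grad_ecm, dtype=float)
           - params.k_mech * np.asarray(traction, dtype=float))
    n = np.linalg.norm(ell, axis=-1, keepdims=True)
    prev = np.asarray(prev_dir, dtype=float)
    small = n[..., 0] < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(small[..., None], prev, ell / np.where(n > 0, n, 1.0))
    return e


def tip_speed(radius_um, params: TipKineticsParams):
    """v_v = v_0 + v_1 exp(−R/R̃), clamped to v_max for R below the cutoff
    (and capped at v_max always).  mm/day."""
    R = np.asarray(radius_um, dtype=float)
    v = params.v0 + params.v1 * np.exp(-R / params.R_tilde_um)
    v = np.where(R < params.R_cutoff_um, params.v_max, v)
    return np.minimum(v, params.v_max)


def wss_threshold_mmhg(radius_um, coeff_mmhg_m: float = 2.4e-8):
    """Radius-dependent WSS threshold τ̄_f = coeff/R (R in metres)."""
    return coeff_mmhg_m / (np.asarray(radius_um, dtype=float) * 1e-6)


def remodelling_time(wss_mmhg, tau_bar_mmhg, params: RemodellingParams):
    """t_m(τ_f): t_m-T above threshold, smoothly rising to t_m-0 at τ_f = 0."""
    tf = np.asarray(wss_mmhg, dtype=float)
    tb = np.asarray(tau_bar_mmhg, dtype=float)
    dtm = params.t_m0_days - params.t_mT_days
    ratio2 = np.clip(tf ** 2 / tb ** 2, 0.0, 1.0 - 1e-12)
    slow = params.t_mT_days + dtm * np.exp(1.0 - 1.0 / (1.0 - ratio2))
    return np.where(tf >= tb, params.t_mT_days, slow)


def lumen_radius(t_bar, is_tip, params: RemodellingParams):
    """Gompertz lumen growth R(t̄) = R_min + A_R exp(−B_R exp(−C_R t̄));
    tip nodes stay at R_min."""
    t_bar = np.asarray(t_bar, dtype=float)
    A = params.R_max_um - params.R_min_um
    grown = params.R_min_um + A * np.exp(
        -params.B_R * np.exp(-params.C_R * t_bar))
    return np.where(np.asarray(is_tip, dtype=bool), params.R_min_um, grown)


def wall_thickness(t_bar, params: RemodellingParams):
    """Monotone linear thickening h_min → h_max over one remodelling time."""
    t = np.clip(np.asarray(t_bar, dtype=float), 0.0, 1.0)
    return params.h_min_um + t * (params.h_max_um - params.h_min_um)


def pore_radius(t_bar, params: RemodellingParams):
    """Cubic pore-size decay r_p^max → r_p^min, constant r_p^min for t̄ ≥ 1."""
    t = np.asarray(t_bar, dtype=float)
    rmin, rmax = params.r_pore_min_um, params.r_pore_max_um
    Ar = 2.0 * (rmax - rmin)
    Br = 3.0 * (rmin - rmax)
    poly = Ar * t ** 3 + Br * t ** 2 + rmax
    return np.where(t >= 1.0, rmin, poly)


def pressure_ratio(p_int, p_h, p_vsc, sentinel: float = 1e6):
    """p̄ = (p_int + p_h)/p_vsc; a vanishing p_vsc with positive numerator
    maps to a large sentinel (treated as ≥ p_c), otherwise 0."""
    num = np.asarray(p_int, dtype=float) + np.asarray(p_h, dtype=float)
    den = np.asarray(p_vsc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 1e-12, num / np.where(den > 0, den, 1.0),
                     np.where(num > 0, sentinel, 0.0))
    return r


def wall_strain(p_bar, p_c, e_c):
    """Invert p̄ = 1 + (2p_c−2)(e/e_c) − (p_c−1)(e/e_c)² for the radial
    strain e_r (smaller root); e_r = 0 for p̄ ≤ 1, e_r = e_c for p̄ ≥ p_c."""
    p_bar = np.asarray(p_bar, dtype=float)
    p_c = np.asarray(p_c, dtype=float)
    a = p_c - 1.0
    disc = np.maximum((2.0 * a) ** 2 - 4.0 * a * (p_bar - 1.0), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (2.0 * a - np.sqrt(disc)) / (2.0 * a)
    e = np.where(p_bar <= 1.0, 0.0, np.where(p_bar >= p_c, 1.0, x)) * e_c
    return e


def stiffness_from_pc(p_c, e_c):
    """E_w-max = 2(p_c − 1)/e_c."""
    return 2.0 * (np.asarray(p_c, dtype=float) - 1.0) / e_c


def pc_from_stiffness(E_w, e_c):
    """p_c = 1 + E_w-max·e_c/2 (inverse of the linear stiffness relation)."""
    return 1.0 + np.asarray(E_w, dtype=float) * e_c / 2.0


def _gaussian_mode_scaled(x, median, sd):
    """Gaussian density scaled by its mode so the component lies in [0,1]."""
    z = (np.asarray(x, dtype=float) - median) / sd
    return np.exp(-0.5 * z * z)


def branching_probability(age_days, dist_um, cls: BranchingClassParams):
    """Bounded branching probability: weighted sum of two mode-normalised
    Gaussians in node age and network distance to the nearest branch."""
    return (cls.w_age * _gaussian_mode_scaled(age_days, cls.age_median_days,
                                              cls.age_sd_days)
            + cls.w_dist * _gaussian_mode_scaled(dist_um, cls.dist_median_um,
                                                 cls.dist_sd_um))


# ---------------------------------------------------------------------------
# per-step tissue cues sampled at vascular nodes / their host elements
# ---------------------------------------------------------------------------
@dataclass
class TissueCues:
    """Everything the vascular step needs from the continuum solvers."""

    taf_at_nodes: np.ndarray        # τ at vascular nodes
    grad_taf_elem: np.ndarray       # (nel, 3)
    grad_ecm_elem: np.ndarray       # (nel, 3)
    stress_elem: Optional[np.ndarray]  # (nel, 3, 3) mean elastic 2nd PK
    thp_at_nodes: np.ndarray        # mm-Hg (compression positive)
    p_int_at_nodes: np.ndarray      # mm-Hg interpolated IFP
    p_vsc: np.ndarray               # mm-Hg from the flow solve
    node_wss: np.ndarray            # mm-Hg
    node_velocity: np.ndarray       # mm/s


def interpolate_nodal(mesh: Mesh, nodal_field: np.ndarray,
                      network: VascularNetwork) -> np.ndarray:
    """Trilinear interpolation of a tissue nodal field at vascular nodes."""
    out = np.zeros(network.n_nodes)
    ok = network.host_elem >= 0
    N = shape_functions(network.local[ok])
    out[ok] = np.einsum("ka,ka->k", N,
                        nodal_field[mesh.elems[network.host_elem[ok]]])
    return out


@dataclass
class StepEvents:
    extensions: int = 0
    branches: int = 0
    anastomoses: int = 0
    collapses: int = 0
    frozen: int = 0


class VesselStepper:
    """Advances the discrete network by one vascular time step Δt_v."""

    def __init__(self, mesh: Mesh, taxis: TaxisParams,
                 tip: TipKineticsParams, branching: BranchingParams,
                 remodelling: RemodellingParams, collapse: CollapseParams):
        self.mesh = mesh
        self.taxis = taxis
        self.tip = tip
        self.branching = branching
        self.remodelling = remodelling
        self.collapse = collapse
        self.bbox_lo = mesh.nodes.min(axis=0)
        self.bbox_hi = mesh.nodes.max(axis=0)

    # ---- helpers -------------------------------------------------------
    def node_pc(self, network: VascularNetwork, t_now: float,
                node_wss: np.ndarray) -> np.ndarray:
        """Per-node critical collapse pressure from the wall stiffness,
        which rises linearly with the remodelling level t̄ (pre-existing
        parents sit at the maximum)."""
        c = self.collapse
        level = self._remodel_level(network, t_now, node_wss)
        E_w = c.E_wall_min + level * (c.E_wall_max - c.E_wall_min)
        return pc_from_stiffness(E_w, c.e_crit)

    def _remodel_level(self, network, t_now, node_wss):
        r = self.remodelling
        tau_bar = wss_threshold_mmhg(np.maximum(network.radius_base_um, 1e-6),
                                     r.wss_coeff)
        t_m = remodelling_time(node_wss, tau_bar, r)
        level = np.clip((t_now - network.birth_time) / t_m, 0.0, 1.0)
        level[network.birth_time <= 0.0] = 1.0  # pre-existing parents
        return level

    def _direction_at(self, network, ids, cues: TissueCues):
        host = network.host_elem[ids]
        gt = cues.grad_taf_elem[host]
        ge = cues.grad_ecm_elem[host]
        prev = network.direction[ids]
        if cues.stress_elem is not None and self.taxis.k_mech > 0:
            t = traction_direction(cues.stress_elem[host], prev)
        else:
            t = np.zeros_like(prev)
        return sprout_direction(gt, ge, t, prev, self.taxis)

    def _spawn(self, network, parent_id, direction, t_now, dt_v,
               events: StepEvents, make_parent_nontip: bool):
        """Create one new node extending from ``parent_id`` along
        ``direction``; handles domain clamping and host lookup."""
        r = self.remodelling
        speed = float(tip_speed(network.radius_um[parent_id], self.tip))
        d = speed * dt_v * direction
        new_pos = network.pos[parent_id] + d
        clipped = np.clip(new_pos, self.bbox_lo, self.bbox_hi)
        frozen = not np.allclose(clipped, new_pos, atol=0.0)
        new_pos = clipped
        seg_len = float(np.linalg.norm(new_pos - network.pos[parent_id]))
        if seg_len <= 1e-12:
            network.frozen[parent_id] = True
            events.frozen += 1
            return None
        eids, locs, ok = self.mesh.locate_many(new_pos[None])
        nid = network.add_nodes(
            pos=new_pos[None], birth_time=t_now, is_tip=True,
            radius_um=r.R_min_um, thickness_um=r.h_min_um,
            pore_um=r.r_pore_max_um, direction=direction[None],
            host_elem=int(eids[0]), local=locs[0][None],
            frozen=frozen or not ok[0])[0]
        if make_parent_nontip:
            network.is_tip[parent_id] = False
        network.add_segments([[parent_id, nid]], seg_len)
        if frozen or not ok[0]:
            events.frozen += 1
        return int(nid)

    # ---- sub-steps ------------------------------------------------------
    def extend_tips(self, network, cues, t_now, dt_v, p_bar, p_c,
                    events) -> list[int]:
        new_ids = []
        order = np.where(network.active_tips())[0]
        for i in order:
            if cues.taf_at_nodes[i] < self.taxis.taf_threshold:
                continue
            if p_bar[i] >= p_c[i]:
                continue
            e = self._direction_at(network, np.array([i]), cues)[0]
            if np.linalg.norm(e) < 1e-12:
                continue
            nid = self._spawn(network, int(i), e, t_now, dt_v, events,
                              make_parent_nontip=True)
            if nid is not None:
                events.extensions += 1
                new_ids.append(nid)
        return new_ids

    def branch_distance_um(self, network) -> np.ndarray:
        """Network geodesic (along segments, μm) to the nearest branching
        node (degree ≥ 3); falls back to the distance to the nearest
        inlet/outlet when no branch exists in the component."""
        fmask = network.functional_segments()
        adj = network.adjacency(segment_mask=fmask,
                                weights=network.rest_length)
        deg = np.zeros(network.n_nodes, dtype=int)
        np.add.at(deg, network.segments[fmask, 0], 1)
        np.add.at(deg, network.segments[fmask, 1], 1)
        sources = np.where(deg >= 3)[0]
        dist = np.full(network.n_nodes, np.inf)
        if len(sources):
            dist = dijkstra(adj, directed=False, indices=sources,
                            min_only=True)
        no_branch = ~np.isfinite(dist)
        if no_branch.any():
            origins = np.where(network.is_inlet | network.is_outlet)[0]
            if len(origins):
                d2 = dijkstra(adj, directed=False, indices=origins,
                              min_only=True)
                dist = np.where(no_branch, d2, dist)
        dist[~np.isfinite(dist)] = 1e9 / UM_PER_MM
        return dist * UM_PER_MM

    def maybe_branch(self, network, cues, t_now, dt_v, p_bar, p_c, rng,
                     events) -> list[int]:
        r = self.remodelling
        # only nodes that existed when the cues were sampled may branch
        n0 = len(cues.taf_at_nodes)
        eligible = (network.functional_nodes()[:n0] & ~network.frozen[:n0]
                    & (cues.taf_at_nodes >= self.taxis.taf_threshold)
                    & (p_bar[:n0] < p_c[:n0]))
        ids = np.where(eligible)[0]
        if len(ids) == 0:
            return []
        dist_um = self.branch_distance_um(network)
        age = t_now - network.birth_time
        hypo = cues.node_velocity < r.v_well_mm_s
        p = np.where(
            hypo[ids],
            branching_probability(age[ids], dist_um[ids],
                                  self.branching.hypo),
            branching_probability(age[ids], dist_um[ids],
                                  self.branching.well))
        draws = rng.random(len(ids))          # consumed in node-id order
        new_ids = []
        min_angle = np.deg2rad(self.branching.min_branch_angle_deg)
        for i, prob, u in zip(ids, p, draws):
            if u >= prob:
                continue
            e = self._direction_at(network, np.array([i]), cues)[0]
            if np.linalg.norm(e) < 1e-12:
                continue
            parent_dir = network.direction[i]
            e = _enforce_min_angle(e, parent_dir, min_angle)
            nid = self._spawn(network, int(i), e, t_now, dt_v, events,
                              make_parent_nontip=False)
            if nid is not None:
                events.branches += 1
                new_ids.append(nid)
        return new_ids

    def try_anastomose(self, network, events) -> int:
        """Connect active tips to the nearest functional non-neighbouring
        node within the capture distance; fused tips stop being tips."""
        cap = self.taxis.anastomosis_um / UM_PER_MM
        func = network.functional_nodes()
        cand_ids = np.where(func)[0]
        if len(cand_ids) < 3:
            return 0
        tree = cKDTree(network.pos[cand_ids])
        adj = {}
        for a, b in network.segments:
            adj.setdefault(int(a), set()).add(int(b))
            adj.setdefault(int(b), set()).add(int(a))
        made = 0
        for tip_id in np.where(network.active_tips())[0]:
            # exclude the tip itself and its 1- and 2-hop neighbourhood
            near = set([int(tip_id)])
            for nb in adj.get(int(tip_id), ()):  # 1 hop
                near.add(nb)
                near.update(adj.get(nb, ()))     # 2 hops
            found = tree.query_ball_point(network.pos[tip_id], cap)
            best, best_d = -1, np.inf
            for k in found:
                j = int(cand_ids[k])
                if j in near:
                    continue
                d = float(np.linalg.norm(network.pos[j]
                                         - network.pos[tip_id]))
                if d < best_d and d > 1e-12:
                    best, best_d = j, d
            if best >= 0 and best_d <= cap:
                network.add_segments([[int(tip_id), best]], best_d)
                network.is_tip[tip_id] = False
                network.is_tip[best] = False
                made += 1
        events.anastomoses += made
        return made

    def remodel(self, network, t_now, node_wss) -> None:
        """Update radius/thickness/pore size of every post-natal node from
        its WSS-dependent remodelling age; pre-existing parents (t_g = 0)
        never remodel."""
        r = self.remodelling
        new = network.birth_time > 0.0
        if not new.any():
            return
        tau_bar = wss_threshold_mmhg(np.maximum(network.radius_base_um, 1e-6),
                                     r.wss_coeff)
        t_m = remodelling_time(node_wss, tau_bar, r)
        t_bar = np.clip((t_now - network.birth_time) / t_m, 0.0, None)
        R = lumen_radius(t_bar, network.is_tip, r)
        h = wall_thickness(t_bar, r)
        rp = pore_radius(t_bar, r)
        upd = new & (network.state != STATE_COLLAPSED)
        network.radius_base_um[upd] = R[upd]
        network.radius_um[upd] = R[upd]
        network.thickness_um[upd] = h[upd]
        network.pore_um[upd] = rp[upd]

    def apply_compression_and_collapse(self, network, p_int_at_nodes,
                                       thp_at_nodes, p_vsc, t_now,
                                       node_wss, events) -> int:
        """Compress (1 < p̄ < p_c) or collapse (p̄ ≥ p_c) vessel walls and
        prune dead components that lost every path to an inlet/outlet.
        Returns the number of newly collapsed nodes."""
        c = self.collapse
        p_c = self.node_pc(network, t_now, node_wss)
        p_bar = pressure_ratio(p_int_at_nodes, thp_at_nodes, p_vsc)
        was_collapsed = network.state == STATE_COLLAPSED
        p_bar = np.where(was_collapsed, 0.0, p_bar)
        e_r = wall_strain(p_bar, p_c, c.e_crit)
        compress = (p_bar > 1.0) & (p_bar < p_c) & ~was_collapsed
        new_collapse = (p_bar >= p_c) & ~was_collapsed
        # reversible compression acts on the remodelled base radius
        R_eff = network.radius_base_um / (1.0 + e_r)
        if c.plastic_compression:
            R_eff = np.minimum(R_eff, network.radius_um)
        network.radius_um = np.where(
            was_collapsed, network.radius_um,
            np.where(compress, R_eff, network.radius_base_um))
        network.state = np.where(
            was_collapsed, STATE_COLLAPSED,
            np.where(new_collapse, STATE_COLLAPSED,
                     np.where(compress, STATE_COMPRESSED,
                              STATE_NORMAL))).astype(np.int8)
        network.radius_um[new_collapse] = (
            network.radius_base_um[new_collapse] / c.lambda_collapse)
        # prune: functional components with no inlet/outlet are dead ends
        fmask = network.functional_segments()
        if fmask.any():
            adj = network.adjacency(segment_mask=fmask)
            _, labels = connected_components(adj, directed=False)
            has_anchor = np.zeros(labels.max() + 1, dtype=bool)
            anchors = (network.is_inlet | network.is_outlet) & \
                network.functional_nodes()
            has_anchor[np.unique(labels[anchors])] = True
            orphan = ~has_anchor[labels] & network.functional_nodes()
            # isolated nodes (degree 0, e.g. all segments collapsed around)
            deg = np.zeros(network.n_nodes, dtype=int)
            np.add.at(deg, network.segments[fmask, 0], 1)
            np.add.at(deg, network.segments[fmask, 1], 1)
            orphan |= (deg == 0) & network.functional_nodes() & \
                ~(network.is_inlet | network.is_outlet)
            if orphan.any():
                network.state[orphan] = STATE_COLLAPSED
                network.radius_um[orphan] = (
                    network.radius_base_um[orphan] / c.lambda_collapse)
        n_new = int((network.state == STATE_COLLAPSED).sum()
                    - was_collapsed.sum())
        events.collapses += n_new
        return n_new

    # ---- full step -------------------------------------------------------
    def step(self, network: VascularNetwork, cues: TissueCues, t_now: float,
             dt_v: float, rng: np.random.Generator) -> StepEvents:
        events = StepEvents()
        p_c = self.node_pc(network, t_now, cues.node_wss)
        p_bar = pressure_ratio(cues.p_int_at_nodes, cues.thp_at_nodes,
                               cues.p_vsc)
        p_bar = np.where(network.state == STATE_COLLAPSED, np.inf, p_bar)
        self.extend_tips(network, cues, t_now, dt_v, p_bar, p_c, events)
        self.maybe_branch(network, cues, t_now, dt_v, p_bar, p_c, rng,
                          events)
        self.try_anastomose(network, events)
        # cues arrays cover only the pre-step nodes; pad for the new ones
        node_wss = _pad(cues.node_wss, network.n_nodes)
        self.remodel(network, t_now + dt_v, node_wss)
        # new nodes have no flow solution yet: an infinite p_vsc stand-in
        # gives p̄ = 0, deferring their assessment to the post-flow re-update
        self.apply_compression_and_collapse(
            network, _pad(cues.p_int_at_nodes, network.n_nodes),
            _pad(cues.thp_at_nodes, network.n_nodes),
            _pad(cues.p_vsc, network.n_nodes, fill=np.inf), t_now + dt_v,
            node_wss, events)
        return events


def _pad(arr, n, fill=0.0):
    out = np.full(n, fill, dtype=float)
    k = min(len(arr), n)
    out[:k] = arr[:k]
    return out


def _enforce_min_angle(e, parent_dir, min_angle):
    """Rotate ``e`` away from the parent direction to at least the minimum
    branch angle (in the plane spanned by both)."""
    p = np.asarray(parent_dir, dtype=float)
    pn = np.linalg.norm(p)
    if pn < 1e-12:
        return e
    p = p / pn
    cosang = float(np.clip(np.dot(e, p), -1.0, 1.0))
    if np.arccos(cosang) >= min_angle:
        return e
    w = e - cosang * p
    wn = np.linalg.norm(w)
    if wn < 1e-12:
        # e parallel to parent: pick a deterministic perpendicular
        axis = np.zeros(3)
        axis[int(np.argmin(np.abs(p)))] = 1.0
        w = np.cross(p, axis)
        wn = np.linalg.norm(w)
    w = w / wn
    return np.cos(min_angle) * p + np.sin(min_angle) * w
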