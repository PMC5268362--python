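"""Discrete 1D vascular network embedded (non-conformingly) in the tissue mesh.

Nodes carry position (reference mm), birth time, lumen radius, wall
thickness, pore radius, functional state and their host tissue element;
segments are straight two-node edges.  The initial condition is a square
lattice of straight, parallel, unbranched capillaries spanning the domain
between the inlet and outlet planes, with the tumour region avascular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .mesh import Mesh, shape_functions

STATE_NORMAL = 0
STATE_COMPRESSED = 1
STATE_COLLAPSED = 2
STATE_NAMES = {STATE_NORMAL: "normal", STATE_COMPRESSED: "compressed",
               STATE_COLLAPSED: "collapsed"}
_STATE_IDS = {v: k for k, v in STATE_NAMES.items()}


@dataclass
class ElementVascularDensity:
    """Per-element tip count N_t (=ρ_t) and binary functional density ρ_v."""

    N_t: np.ndarray
    N_v: np.ndarray
    rho_t: np.ndarray
    rho_v: np.ndarray


@dataclass
class VascularNetwork:
    pos: np.ndarray                  # (n, 3) reference coordinates, mm
    birth_time: np.ndarray           # (n,) days (t_g; 0 for parents)
    is_tip: np.ndarray               # (n,) bool
    is_inlet: np.ndarray             # (n,) bool
    is_outlet: np.ndarray            # (n,) bool
    frozen: np.ndarray               # (n,) bool — clamped at the boundary Γ
    radius_um: np.ndarray            # (n,) effective lumen radius R
    radius_base_um: np.ndarray       # (n,) remodelled radius before compression
    thickness_um: np.ndarray         # (n,) wall thickness h
    pore_um: np.ndarray              # (n,) pore radius r_p
    state: np.ndarray                # (n,) int8
    host_elem: np.ndarray            # (n,) int, −1 when frozen outside
    local: np.ndarray                # (n, 3) local coords in host element
    direction: np.ndarray            # (n, 3) last extension direction
    segments: np.ndarray             # (m, 2) int
    rest_length: np.ndarray          # (m,) mm, reference segment length

    # ---- bookkeeping ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.pos)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.segments[:, 0], 1)
        np.add.at(deg, self.segments[:, 1], 1)
        return deg

    def functional_nodes(self) -> np.ndarray:
        return self.state != STATE_COLLAPSED

    def functional_segments(self) -> np.ndarray:
        ok = self.functional_nodes()
        return ok[self.segments[:, 0]] & ok[self.segments[:, 1]]

    def active_tips(self) -> np.ndarray:
        return (self.is_tip & ~self.frozen & self.functional_nodes())

    def adjacency(self, segment_mask: Optional[np.ndarray] = None,
                  weights: Optional[np.ndarray] = None) -> sparse.csr_matrix:
        segs = self.segments if segment_mask is None else \
            self.segments[segment_mask]
        if weights is None:
            w = np.ones(len(segs))
        else:
            w = weights if segment_mask is None else weights[segment_mask]
        n = self.n_nodes
        a = sparse.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([segs[:, 0], segs[:, 1]]),
              np.concatenate([segs[:, 1], segs[:, 0]]))), shape=(n, n))
        return a.tocsr()

    def add_nodes(self, pos, birth_time, is_tip, radius_um, thickness_um,
                  pore_um, direction, host_elem, local,
                  frozen=None) -> np.ndarray:
        """Append a batch of nodes; returns their new ids."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        k = len(pos)
        new_ids = np.arange(self.n_nodes, self.n_nodes + k)
        self.pos = np.vstack([self.pos, pos])
        self.birth_time = np.append(self.birth_time,
                                    np.broadcast_to(birth_time, k))
        self.is_tip = np.append(self.is_tip, np.broadcast_to(is_tip, k))
        self.is_inlet = np.append(self.is_inlet, np.zeros(k, dtype=bool))
        self.is_outlet = np.append(self.is_outlet, np.zeros(k, dtype=bool))
        self.frozen = np.append(
            self.frozen,
            np.zeros(k, dtype=bool) if frozen is None
            else np.broadcast_to(frozen, k))
        self.radius_um = np.append(self.radius_um,
                                   np.broadcast_to(radius_um, k))
        self.radius_base_um = np.append(self.radius_base_um,
                                        np.broadcast_to(radius_um, k))
        self.thickness_um = np.append(self.thickness_um,
                                      np.broadcast_to(thickness_um, k))
        self.pore_um = np.append(self.pore_um, np.broadcast_to(pore_um, k))
        self.state = np.append(self.state,
                               np.full(k, STATE_NORMAL, dtype=np.int8))
        self.host_elem = np.append(self.host_elem,
                                   np.broadcast_to(host_elem, k))
        self.local = np.vstack([self.local,
                                np.atleast_2d(np.asarray(local, dtype=float))])
        self.direction = np.vstack(
            [self.direction, np.atleast_2d(np.asarray(direction, dtype=float))])
        return new_ids

    def add_segments(self, pairs, rest_length) -> None:
        pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
        if np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("segment endpoints must be distinct")
        self.segments = np.vstack([self.segments, pairs])
        self.rest_length = np.append(self.rest_length,
                                     np.broadcast_to(rest_length, len(pairs)))

    # ---- geometry under tissue deformation -----------------------------
    def current_positions(self, mesh: Mesh,
                          displacements: Optional[np.ndarray] = None
                          ) -> np.ndarray:
        """Deformed node positions x = X + u(X) (trilinear interpolation of
        the tissue displacement at each node's host element)."""
        if displacements is None:
            return self.pos.copy()
        x = self.pos.copy()
        ok = self.host_elem >= 0
        N = shape_functions(self.local[ok])                 # (k, 8)
        u_elem = displacements[mesh.elems[self.host_elem[ok]]]  # (k, 8, 3)
        x[ok] += np.einsum("ka,kai->ki", N, u_elem)
        return x

    def segment_lengths(self, positions: Optional[np.ndarray] = None
                        ) -> np.ndarray:
        p = self.pos if positions is None else positions
        d = p[self.segments[:, 0]] - p[self.segments[:, 1]]
        return np.linalg.norm(d, axis=1)

    def rehost(self, mesh: Mesh) -> None:
        """(Re)compute host element and local coordinates for every node."""
        eids, locs, ok = mesh.locate_many(self.pos)
        self.host_elem = np.where(ok, eids, -1)
        self.local = locs
        self.frozen |= ~ok


def update_densities(network: VascularNetwork, mesh: Mesh,
                     well_perfused: Optional[np.ndarray] = None
                     ) -> ElementVascularDensity:
    """Per-element tip density ρ_t = N_t and binary vascular density ρ_v.

    ρ_v = 1 iff the element contains at least one *well-perfused*,
    functional vascular node; collapsed/hypo-perfused/absent → 0.
    ``well_perfused`` is the per-node classification from the flow solution
    (defaults to all-functional when no flow has been solved yet).
    """
    N_t = np.zeros(mesh.n_elems, dtype=int)
    N_v = np.zeros(mesh.n_elems, dtype=int)
    hosted = network.host_elem >= 0
    tips = network.active_tips() & hosted
    np.add.at(N_t, network.host_elem[tips], 1)
    if well_perfused is None:
        well_perfused = network.functional_nodes()
    well = well_perfused & network.functional_nodes() & hosted
    np.add.at(N_v, network.host_elem[well], 1)
    return ElementVascularDensity(
        N_t=N_t, N_v=N_v, rho_t=N_t.astype(float),
        rho_v=(N_v > 0).astype(float))


def build_initial_network(mesh: Mesh, spacing: float, radius_um: float,
                          thickness_um: float, pore_um: float
                          ) -> VascularNetwork:
    """Square lattice of straight parallel capillaries along x, spanning the
    inlet → outlet planes; lines conflicting with the tumour sphere are
    pushed radially (in the cross-section plane) just outside it, keeping
    the tumour avascular.  Lines are discretised into segments no longer
    than the mesh minimum edge (the mesh-compatibility length).
    """
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    span = hi - lo
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > min(span[1], span[2]):
        raise ValueError("spacing larger than the domain cross-section")
    centre = 0.5 * (lo + hi)
    # clearance radius covering all tumour elements entirely
    if mesh.tumour_elems.any():
        xc = mesh.elem_coords[mesh.tumour_elems]
        cen = xc.mean(axis=1)
        half_diag = 0.5 * np.linalg.norm(xc.max(axis=1) - xc.min(axis=1),
                                         axis=1)
        r_clear = float(np.max(np.linalg.norm(cen - centre, axis=1)
                               + half_diag))
    else:
        r_clear = 0.0
    n_y = int(np.floor(span[1] / spacing))
    n_z = int(np.floor(span[2] / spacing))
    ys = lo[1] + spacing / 2 + spacing * np.arange(n_y)
    zs = lo[2] + spacing / 2 + spacing * np.arange(n_z)
    compat = mesh.min_edge_length
    n_seg = max(1, int(np.ceil(span[0] / compat)))
    xs = np.linspace(lo[0], hi[0], n_seg + 1)

    net = VascularNetwork(
        pos=np.empty((0, 3)), birth_time=np.empty(0), is_tip=np.empty(0, bool),
        is_inlet=np.empty(0, bool), is_outlet=np.empty(0, bool),
        frozen=np.empty(0, bool), radius_um=np.empty(0),
        radius_base_um=np.empty(0), thickness_um=np.empty(0),
        pore_um=np.empty(0), state=np.empty(0, np.int8),
        host_elem=np.empty(0, int), local=np.empty((0, 3)),
        direction=np.empty((0, 3)), segments=np.empty((0, 2), int),
        rest_length=np.empty(0))

    margin = 0.1 * spacing
    for y in ys:
        for z in zs:
            dy, dz = y - centre[1], z - centre[2]
            r_yz = np.hypot(dy, dz)
            if r_yz < r_clear:
                if r_yz < 1e-12:
                    dy, dz = 1.0, 0.0
                    r_yz = 1.0
                scale = (r_clear + margin) / r_yz
                y_l = centre[1] + dy * scale
                z_l = centre[2] + dz * scale
            else:
                y_l, z_l = y, z
            line = np.column_stack(
                [xs, np.full_like(xs, y_l), np.full_like(xs, z_l)])
            ids = net.add_nodes(
                pos=line, birth_time=0.0, is_tip=False, radius_um=radius_um,
                thickness_um=thickness_um, pore_um=pore_um,
                direction=np.tile([1.0, 0.0, 0.0], (len(line), 1)),
                host_elem=-1, local=np.zeros((len(line), 3)))
            net.is_inlet[ids[0]] = True
            net.is_outlet[ids[-1]] = True
            pairs = np.column_stack([ids[:-1], ids[1:]])
            net.add_segments(pairs, np.diff(xs))
    net.rehost(mesh)
    net.frozen[:] = False  # parents span the full domain by construction
    return net


# ---- CSV I/O ----------------------------------------------------------
SEGMENT_CSV_HEADER = ["node_a", "node_b", "xa", "ya", "za", "xb", "yb", "zb",
                      "radius_um", "state"]


def write_segment_csv(network: VascularNetwork, path,
                      positions: Optional[np.ndarray] = None) -> None:
    """Flat per-segment table (spec'd external interface): endpoint ids and
    coordinates, mean lumen radius and worst endpoint state per segment.
    A companion ``<path stem>_nodes.csv`` carries the full node attributes
    so that a written network can be re-read identically."""
    p = self_pos = network.pos if positions is None else positions
    a = network.segments[:, 0]
    b = network.segments[:, 1]
    df = pd.DataFrame({
        "node_a": a, "node_b": b,
        "xa": p[a, 0], "ya": p[a, 1], "za": p[a, 2],
        "xb": p[b, 0], "yb": p[b, 1], "zb": p[b, 2],
        "radius_um": 0.5 * (network.radius_um[a] + network.radius_um[b]),
        "state": [STATE_NAMES[int(s)] for s in
                  np.maximum(network.state[a], network.state[b])],
    })
    df.to_csv(path, index=False, float_format="%.17g")
    nodes = pd.DataFrame({
        "x": self_pos[:, 0], "y": self_pos[:, 1], "z": self_pos[:, 2],
        "birth_time": network.birth_time,
        "is_tip": network.is_tip.astype(int),
        "is_inlet": network.is_inlet.astype(int),
        "is_outlet": network.is_outlet.astype(int),
        "frozen": network.frozen.astype(int),
        "radius_um": network.radius_um,
        "radius_base_um": network.radius_base_um,
        "thickness_um": network.thickness_um,
        "pore_um": network.pore_um,
        "state": network.state.astype(int),
        "dir_x": network.direction[:, 0],
        "dir_y": network.direction[:, 1],
        "dir_z": network.direction[:, 2],
    })
    nodes.to_csv(_nodes_path(path), index=False, float_format="%.17g")


def _nodes_path(path):
    import os
    stem, ext = os.path.splitext(str(path))
    return f"{stem}_nodes{ext or '.csv'}"


def read_segment_csv(path, mesh: Optional[Mesh] = None) -> VascularNetwork:
    """Re-read a network written by :func:`write_segment_csv`."""
    import os
    segs = pd.read_csv(path)
    npath = _nodes_path(path)
    if not os.path.exists(npath):
        raise FileNotFoundError(f"companion node table {npath} not found")
    nodes = pd.read_csv(npath)
    n = len(nodes)
    net = VascularNetwork(
        pos=nodes[["x", "y", "z"]].to_numpy(),
        birth_time=nodes["birth_time"].to_numpy(),
        is_tip=nodes["is_tip"].to_numpy().astype(bool),
        is_inlet=nodes["is_inlet"].to_numpy().astype(bool),
        is_outlet=nodes["is_outlet"].to_numpy().astype(bool),
        frozen=nodes["frozen"].to_numpy().astype(bool),
        radius_um=nodes["radius_um"].to_numpy(),
        radius_base_um=nodes["radius_base_um"].to_numpy(),
        thickness_um=nodes["thickness_um"].to_numpy(),
        pore_um=nodes["pore_um"].to_numpy(),
        state=nodes["state"].to_numpy().astype(np.int8),
        host_elem=np.full(n, -1, dtype=int),
        local=np.zeros((n, 3)),
        direction=nodes[["dir_x", "dir_y", "dir_z"]].to_numpy(),
        segments=segs[["node_a", "node_b"]].to_numpy().astype(int),
        rest_length=np.empty(0))
    d = net.pos[net.segments[:, 0]] - net.pos[net.segments[:, 1]]
    net.rest_length = np.linalg.norm(d, axis=1)
    if mesh is not None:
        net.rehost(mesh)
    return net


def vessel_chain_labels(network: VascularNetwork,
                        segment_mask: Optional[np.ndarray] = None
                        ) -> np.ndarray:
    """Label every segment with a 'vessel' id: maximal branch-free chains.

    Two segments belong to the same vessel when they share an interior node
    of degree 2 (junctions, inlets and outlets split chains).  Returns −1
    for masked-out segments.
    """
    m = network.n_segments
    mask = np.ones(m, dtype=bool) if segment_mask is None else segment_mask
    parent = np.arange(m)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    deg = np.zeros(network.n_nodes, dtype=int)
    np.add.at(deg, network.segments[mask, 0], 1)
    np.add.at(deg, network.segments[mask, 1], 1)
    incident: dict[int, list[int]] = {}
    for s in np.where(mask)[0]:
        for nd in network.segments[s]:
            incident.setdefault(int(nd), []).append(int(s))
    splitting = network.is_inlet | network.is_outlet
    for nd, segs in incident.items():
        if deg[nd] == 2 and not splitting[nd] and len(segs) == 2:
            ra, rb = find(segs[0]), find(segs[1])
            if ra != rb:
                parent[ra] = rb
    labels = np.full(m, -1, dtype=int)
    roots = {}
    for s in np.where(mask)[0]:
        r = find(s)
        labels[s] = roots.setdefault(r, len(roots))
    return labels


def nearest_other_vessel_distances(network: VascularNetwork,
                                   sample_spacing: float = 0.05,
                                   positions: Optional[np.ndarray] = None
                                   ) -> np.ndarray:
    """For points sampled along every functional segment, the centreline
    distance to the nearest sample on a *different* vessel (different
    branch-free chain).  Used by the inter-capillary distance metric."""
    fmask = network.functional_segments()
    labels = vessel_chain_labels(network, fmask)
    p = network.pos if positions is None else positions
    pts, comp = [], []
    for s in np.where(fmask)[0]:
        a, b = network.segments[s]
        seg = p[b] - p[a]
        L = np.linalg.norm(seg)
        k = max(2, int(np.ceil(L / sample_spacing)) + 1)
        t = np.linspace(0, 1, k)[:, None]
        pts.append(p[a] + t * seg)
        comp.append(np.full(k, labels[s]))
    if not pts:
        return np.empty(0)
    pts = np.concatenate(pts)
    comp = np.concatenate(comp)
    if len(np.unique(comp)) < 2:
        return np.full(len(pts), np.nan)
    out = np.full(len(pts), np.nan)
    tree = cKDTree(pts)
    k = min(len(pts), 64)
    todo = np.arange(len(pts))
    while len(todo) and k <= len(pts):
        dist, idx = tree.query(pts[todo], k=k)
        unresolved = []
        for row, i in enumerate(todo):
            other = comp[idx[row]] != comp[i]
            if other.any():
                out[i] = dist[row][other][0]
            else:
                unresolved.append(i)
        todo = np.asarray(unresolved, dtype=int)
        if k == len(pts):
            break
        k = min(len(pts), k * 4)
    return out
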