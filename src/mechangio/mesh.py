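"""Hexahedral tissue mesh: generation, Gmsh ASCII I/O, point location.

The tissue continuum is discretised with trilinear (8-node) hexahedra.
Coordinates are physical millimetres in the reference (Lagrangian)
configuration; node and element indices are 0-based; local element
coordinates live in [−1, 1]³ with the standard VTK/Gmsh hexahedron node
ordering.  Element labels split the domain into tumour (Ω^T) and host (Ω^H);
two opposite boundary faces are tagged as the inlet/outlet planes of the
vascular system (Γ^V), the remaining boundary is Γ^T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

# VTK/Gmsh hexahedron local node order → sign pattern in (ξ, η, ζ)
_SIGNS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

# local edges of a hexahedron (12)
HEX_EDGES = [(0, 1), (1, 2), (2, 3), (3, 0),
             (4, 5), (5, 6), (6, 7), (7, 4),
             (0, 4), (1, 5), (2, 6), (3, 7)]

_GP1 = 1.0 / np.sqrt(3.0)


class OutOfDomainError(Exception):
    """A queried point lies outside every element of the mesh."""


class MeshFormatError(ValueError):
    """Malformed or unsupported mesh file."""


def shape_functions(local: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(ξ,η,ζ); ``local`` shape (..., 3)."""
    local = np.asarray(local, dtype=float)
    terms = 1.0 + local[..., None, :] * _SIGNS  # (..., 8, 3)
    return 0.125 * terms.prod(axis=-1)


def shape_gradients(local: np.ndarray) -> np.ndarray:
    """dN_a/dξ_j at ``local``; returns shape (..., 8, 3)."""
    local = np.asarray(local, dtype=float)
    t = 1.0 + local[..., None, :] * _SIGNS  # (..., 8, 3)
    g = np.empty(t.shape)
    g[..., 0] = 0.125 * _SIGNS[:, 0] * t[..., 1] * t[..., 2]
    g[..., 1] = 0.125 * _SIGNS[:, 1] * t[..., 0] * t[..., 2]
    g[..., 2] = 0.125 * _SIGNS[:, 2] * t[..., 0] * t[..., 1]
    return g


def gauss_points() -> tuple[np.ndarray, np.ndarray]:
    """2×2×2 Gauss quadrature on [−1,1]³: (points (8,3), weights (8,))."""
    pts = _SIGNS * _GP1
    return pts, np.ones(8)


@dataclass
class Mesh:
    """Hexahedral mesh with tumour/host labels and tagged boundary faces."""

    nodes: np.ndarray            # (n_nodes, 3) mm, reference configuration
    elems: np.ndarray            # (n_elems, 8) int
    tumour_elems: np.ndarray     # (n_elems,) bool
    inlet_nodes: np.ndarray      # (n_nodes,) bool — nodes on the inlet plane
    outlet_nodes: np.ndarray     # (n_nodes,) bool
    # rectilinear-grid acceleration data (None for imported general meshes):
    # per-axis node coordinate arrays (len n_i + 1 each)
    grid_axes: Optional[tuple] = None
    grid_n: Optional[tuple] = None       # (nx, ny, nz) elements per axis
    _tree: Optional[cKDTree] = field(default=None, repr=False)
    _edges_cache: Optional[tuple] = field(default=None, repr=False)

    # ---- basic derived data -------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    @property
    def elem_coords(self) -> np.ndarray:
        return self.nodes[self.elems]  # (nel, 8, 3)

    @property
    def centroids(self) -> np.ndarray:
        return self.elem_coords.mean(axis=1)

    @property
    def min_edge_length(self) -> float:
        xc = self.elem_coords
        lengths = [np.linalg.norm(xc[:, a] - xc[:, b], axis=1)
                   for a, b in HEX_EDGES]
        return float(np.min(lengths))

    @property
    def tagged_face_nodes(self) -> np.ndarray:
        """Nodes on Γ^V (the two inlet/outlet planes)."""
        return self.inlet_nodes | self.outlet_nodes

    @property
    def node_in_tumour(self) -> np.ndarray:
        """Node attached to at least one tumour element (Ω^T includes Γ^I)."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[np.unique(self.elems[self.tumour_elems])] = True
        return mask

    def element_volumes(self, displacements: Optional[np.ndarray] = None
                        ) -> np.ndarray:
        """Quadrature element volumes; with ``displacements`` the deformed ones."""
        xc = self.elem_coords
        if displacements is not None:
            xc = xc + displacements[self.elems]
        pts, w = gauss_points()
        dN = shape_gradients(pts)                       # (8qp, 8, 3)
        J = np.einsum("qaj,eai->eqij", dN, xc)          # (nel, 8, 3, 3)
        detJ = np.linalg.det(J)
        return (detJ * w).sum(axis=1)

    def jacobian_positive(self) -> bool:
        xc = self.elem_coords
        pts, _ = gauss_points()
        dN = shape_gradients(pts)
        J = np.einsum("qaj,eai->eqij", dN, xc)
        return bool(np.all(np.linalg.det(J) > 0))

    # ---- point location -----------------------------------------------
    def _invert_trilinear(self, elem_id: int, point: np.ndarray
                          ) -> Optional[np.ndarray]:
        """Newton inversion of the trilinear map for one element; returns
        local coords if the point lies inside (|ξ_i| ≤ 1 + 1e-9), else None."""
        xc = self.nodes[self.elems[elem_id]]
        loc = np.zeros(3)
        for _ in range(30):
            N = shape_functions(loc)
            r = N @ xc - point
            if np.abs(r).max() < 1e-13:
                break
            # dX_i/dξ_j = Σ_a dN_a/dξ_j x_ai
            J = np.einsum("aj,ai->ij", shape_gradients(loc), xc)
            loc = loc - np.linalg.solve(J, r)
        if np.abs(loc).max() <= 1.0 + 1e-9:
            return np.clip(loc, -1.0, 1.0)
        return None

    def locate(self, point) -> tuple[int, np.ndarray]:
        """Find the element containing ``point`` and its local coordinates.

        Points on shared faces resolve to the lowest adjacent element id.
        Raises :class:`OutOfDomainError` when outside every element.
        """
        point = np.asarray(point, dtype=float)
        if self.grid_axes is not None:
            eid, loc, ok = self.locate_many(point[None])
            if not ok[0]:
                raise OutOfDomainError(f"point {point} outside domain")
            return int(eid[0]), loc[0]
        if self._tree is None:
            self._tree = cKDTree(self.centroids)
        k = min(27, self.n_elems)
        _, cand = self._tree.query(point, k=k)
        cand = np.atleast_1d(cand)
        for eid in sorted(int(c) for c in cand):
            loc = self._invert_trilinear(eid, point)
            if loc is not None:
                return eid, loc
        raise OutOfDomainError(f"point {point} outside all candidate elements")

    def locate_many(self, points: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised :meth:`locate`; returns (elem_ids, locals, inside_mask).

        Outside points get elem_id −1 and are flagged False.
        """
        points = np.asarray(points, dtype=float)
        n_pts = len(points)
        eids = np.full(n_pts, -1, dtype=int)
        locs = np.zeros((n_pts, 3))
        ok = np.zeros(n_pts, dtype=bool)
        if self.grid_axes is not None:
            n = np.asarray(self.grid_n)
            idx = np.empty((n_pts, 3), dtype=int)
            locs_all = np.empty((n_pts, 3))
            inside = np.ones(n_pts, dtype=bool)
            for d in range(3):
                ax = self.grid_axes[d]
                x = points[:, d]
                inside &= (x >= ax[0] - 1e-9) & (x <= ax[-1] + 1e-9)
                i = np.searchsorted(ax, x, side="right") - 1
                # exact interior faces resolve to the lower cell
                on_face = (i >= 1) & (i <= n[d]) & \
                    (x == ax[np.clip(i, 0, n[d])])
                i = np.where(on_face, i - 1, i)
                i = np.clip(i, 0, n[d] - 1)
                idx[:, d] = i
                h = ax[i + 1] - ax[i]
                locs_all[:, d] = np.clip(2.0 * (x - ax[i]) / h - 1.0,
                                         -1.0, 1.0)
            eids_all = idx[:, 0] + n[0] * (idx[:, 1] + n[1] * idx[:, 2])
            eids[inside] = eids_all[inside]
            locs[inside] = locs_all[inside]
            return eids, locs, inside
        for i, p in enumerate(points):
            try:
                eids[i], locs[i] = self.locate(p)
                ok[i] = True
            except OutOfDomainError:
                pass
        return eids, locs, ok

    # ---- interstitial edge graph --------------------------------------
    def element_edges(self) -> tuple[np.ndarray, list]:
        """Unique mesh edges and, per edge, the incident element ids.

        Returns (edges (n_edges, 2) int sorted node pairs, incident lists).
        """
        if self._edges_cache is not None:
            return self._edges_cache
        pairs = []
        for a, b in HEX_EDGES:
            e = self.elems[:, [a, b]]
            pairs.append(np.sort(e, axis=1))
        all_pairs = np.concatenate(pairs, axis=0)            # (12*nel, 2)
        elem_ids = np.tile(np.arange(self.n_elems), 12)
        edges, inv = np.unique(all_pairs, axis=0, return_inverse=True)
        incident = [[] for _ in range(len(edges))]
        for k, e in zip(inv, elem_ids):
            incident[k].append(int(e))
        self._edges_cache = (edges, incident)
        return self._edges_cache


def graded_axis(edge_length: float, h_centre: float,
                growth: float = 1.6, h_max: Optional[float] = None
                ) -> np.ndarray:
    """Symmetric node coordinates on [0, edge] refined toward the centre:
    cells of size ``h_centre`` at the middle, geometrically coarsening
    outward by ``growth`` (capped at ``h_max``)."""
    half = edge_length / 2.0
    if h_max is None:
        h_max = edge_length / 6.0
    sizes = []
    pos = 0.0
    h = h_centre
    while pos < half - 1e-12:
        h_use = min(h, h_max)
        sizes.append(h_use)
        pos += h_use
        h *= growth
    # rescale proportionally so the half-axis is filled exactly (avoids a
    # sliver cell at the boundary that would dominate the CFL limit)
    sizes = np.asarray(sizes) * (half / np.sum(sizes))
    right = half + np.cumsum(sizes)
    left = half - np.cumsum(sizes)[::-1]
    ax = np.concatenate([left, [half], right])
    ax[0] = 0.0
    ax[-1] = edge_length
    return ax


def mesh_from_axes(ax_x, ax_y, ax_z, tumour_diameter: float) -> Mesh:
    """Rectilinear hexahedral mesh from per-axis node coordinates; elements
    with centroid inside the centred sphere are labelled tumour; the x=min
    and x=max faces are the inlet and outlet planes."""
    axes = tuple(np.asarray(a, dtype=float) for a in (ax_x, ax_y, ax_z))
    nx, ny, nz = (len(a) - 1 for a in axes)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(order="F"), Y.ravel(order="F"),
                             Z.ravel(order="F")])

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    I = I.ravel(order="F")
    J = J.ravel(order="F")
    K = K.ravel(order="F")
    elems = np.column_stack([
        nid(I, J, K), nid(I + 1, J, K), nid(I + 1, J + 1, K), nid(I, J + 1, K),
        nid(I, J, K + 1), nid(I + 1, J, K + 1), nid(I + 1, J + 1, K + 1),
        nid(I, J + 1, K + 1)]).astype(int)
    lo = nodes.min(axis=0)
    hi = nodes.max(axis=0)
    centre = 0.5 * (lo + hi)
    centroids = nodes[elems].mean(axis=1)
    tumour = (np.linalg.norm(centroids - centre, axis=1)
              < tumour_diameter / 2.0)
    inlet = nodes[:, 0] < lo[0] + 1e-12
    outlet = nodes[:, 0] > hi[0] - 1e-12
    return Mesh(nodes=nodes, elems=elems, tumour_elems=tumour,
                inlet_nodes=inlet, outlet_nodes=outlet,
                grid_axes=axes, grid_n=(nx, ny, nz))


def generate_cube_mesh(edge_length: float, n_per_side: int,
                       tumour_diameter: float,
                       elongation_limit: Optional[float] = None,
                       h_centre: Optional[float] = None,
                       growth: float = 1.6) -> Mesh:
    """Hexahedral mesh of a cube with a centred spherical tumour.

    Uniform n_per_side³ grid by default; with ``h_centre`` the grid is
    centre-refined (geometric coarsening outward, resolving the tumour and
    its oxygen boundary layer).  Elements whose centroid lies inside the
    centred sphere of the given diameter are labelled tumour.  The faces
    x=0 and x=edge_length are tagged as the inlet and outlet planes.
    Refuses meshes violating the elongation-compatibility rule when
    ``elongation_limit`` (maximum tip extension per vascular step, mm)
    is given.
    """
    if n_per_side < 4:
        raise ValueError("n_per_side must be ≥ 4")
    if tumour_diameter >= edge_length / 2:
        raise ValueError("tumour diameter must be < half the cube edge")
    if h_centre is None:
        ax = np.linspace(0.0, edge_length, n_per_side + 1)
    else:
        ax = graded_axis(edge_length, h_centre, growth)
    mesh = mesh_from_axes(ax, ax, ax, tumour_diameter)
    if elongation_limit is not None and \
            mesh.min_edge_length < elongation_limit - 1e-12:
        raise ValueError(
            f"element edge {mesh.min_edge_length:.4g} mm violates the "
            f"elongation-compatibility rule "
            f"(must be ≥ {elongation_limit:.4g} mm)")
    return mesh


# ---- boundary faces (for Gmsh physical surfaces) ----------------------
_HEX_FACES = [(0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
              (2, 3, 7, 6), (0, 4, 7, 3), (1, 2, 6, 5)]


def _boundary_quads(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """All boundary quads and a tag per quad: 0 inlet, 1 outlet, 2 wall."""
    faces = []
    for f in _HEX_FACES:
        faces.append(mesh.elems[:, list(f)])
    faces = np.concatenate(faces, axis=0)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True,
                               return_counts=True)
    bfaces = faces[idx[counts == 1]]
    tags = np.full(len(bfaces), 2, dtype=int)
    inlet = mesh.inlet_nodes[bfaces].all(axis=1)
    outlet = mesh.outlet_nodes[bfaces].all(axis=1)
    tags[inlet] = 0
    tags[outlet] = 1
    return bfaces, tags


# ---- Gmsh ASCII I/O ---------------------------------------------------
_PHYS = {1: "host", 2: "tumour", 3: "inlet", 4: "outlet", 5: "wall"}


def write_gmsh(mesh: Mesh, path, version: str = "2.2") -> None:
    """Write the mesh as Gmsh ASCII (v2.2 or v4.1) with physical groups
    host/tumour (volumes) and inlet/outlet/wall (surfaces)."""
    if version not in ("2.2", "4.1"):
        raise ValueError("supported Gmsh versions: 2.2, 4.1")
    bfaces, btags = _boundary_quads(mesh)
    vol_phys = np.where(mesh.tumour_elems, 2, 1)
    surf_phys = btags + 3
    with open(path, "w") as fh:
        if version == "2.2":
            fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
            fh.write("$PhysicalNames\n5\n")
            for tag in (3, 4, 5):
                fh.write(f'2 {tag} "{_PHYS[tag]}"\n')
            for tag in (1, 2):
                fh.write(f'3 {tag} "{_PHYS[tag]}"\n')
            fh.write("$EndPhysicalNames\n$Nodes\n")
            fh.write(f"{mesh.n_nodes}\n")
            for i, p in enumerate(mesh.nodes):
                fh.write(f"{i + 1} {p[0]:.16g} {p[1]:.16g} {p[2]:.16g}\n")
            fh.write("$EndNodes\n$Elements\n")
            fh.write(f"{len(bfaces) + mesh.n_elems}\n")
            k = 1
            for q, ph in zip(bfaces, surf_phys):
                ns = " ".join(str(v + 1) for v in q)
                fh.write(f"{k} 3 2 {ph} {ph} {ns}\n")
                k += 1
            for e, ph in zip(mesh.elems, vol_phys):
                ns = " ".join(str(v + 1) for v in e)
                fh.write(f"{k} 5 2 {ph} {ph} {ns}\n")
                k += 1
            fh.write("$EndElements\n")
            return
        # ---- v4.1 ----
        lo = mesh.nodes.min(axis=0)
        hi = mesh.nodes.max(axis=0)
        box = f"{lo[0]:.16g} {lo[1]:.16g} {lo[2]:.16g} " \
              f"{hi[0]:.16g} {hi[1]:.16g} {hi[2]:.16g}"
        fh.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n5\n")
        for tag in (3, 4, 5):
            fh.write(f'2 {tag} "{_PHYS[tag]}"\n')
        for tag in (1, 2):
            fh.write(f'3 {tag} "{_PHYS[tag]}"\n')
        fh.write("$EndPhysicalNames\n")
        fh.write("$Entities\n0 0 3 2\n")
        for tag in (3, 4, 5):
            fh.write(f"{tag} {box} 1 {tag} 0\n")
        for tag in (1, 2):
            fh.write(f"{tag} {box} 1 {tag} 0\n")
        fh.write("$EndEntities\n$Nodes\n")
        fh.write(f"1 {mesh.n_nodes} 1 {mesh.n_nodes}\n")
        fh.write(f"3 1 0 {mesh.n_nodes}\n")
        for i in range(mesh.n_nodes):
            fh.write(f"{i + 1}\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.16g} {p[1]:.16g} {p[2]:.16g}\n")
        fh.write("$EndNodes\n$Elements\n")
        # element tags preserve the original ordering (quads first, then
        # hexes) even though blocks are grouped by physical group
        nq = len(bfaces)
        blocks = []
        for tag in (3, 4, 5):
            sel = np.where(surf_phys == tag)[0]
            if len(sel):
                blocks.append((2, tag, 3, bfaces[sel], sel + 1))
        for tag in (1, 2):
            sel = np.where(vol_phys == tag)[0]
            if len(sel):
                blocks.append((3, tag, 5, mesh.elems[sel], nq + sel + 1))
        total = sum(len(b[3]) for b in blocks)
        fh.write(f"{len(blocks)} {total} 1 {total}\n")
        for dim, tag, etype, conn, ids in blocks:
            fh.write(f"{dim} {tag} {etype} {len(conn)}\n")
            for k, row in zip(ids, conn):
                ns = " ".join(str(v + 1) for v in row)
                fh.write(f"{k} {ns}\n")
        fh.write("$EndElements\n")


def load_mesh(path) -> Mesh:
    """Read a Gmsh ASCII mesh (v2.2 or v4.1) with hexahedral volume cells.

    Volume physical groups named (or tagged) host/tumour become element
    labels; surface groups inlet/outlet tag the boundary planes.
    """
    with open(path) as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != "$MeshFormat":
        raise MeshFormatError(f"{path}: not a Gmsh ASCII file")
    version = lines[1].split()[0]
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(lines):
        if lines[i].startswith("$") and not lines[i].startswith("$End"):
            name = lines[i][1:]
            j = i + 1
            while j < len(lines) and lines[j] != f"$End{name}":
                j += 1
            if j >= len(lines):
                raise MeshFormatError(f"{path}: unterminated section {name}")
            sections[name] = lines[i + 1:j]
            i = j + 1
        else:
            i += 1
    phys_names = {}
    for ln in sections.get("PhysicalNames", [])[1:]:
        parts = ln.split(maxsplit=2)
        if len(parts) == 3:
            phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip('"')
    if version.startswith("2"):
        node_lines = sections["Nodes"]
        n_nodes = int(node_lines[0])
        ids = np.empty(n_nodes, dtype=int)
        coords = np.empty((n_nodes, 3))
        for k, ln in enumerate(node_lines[1:1 + n_nodes]):
            p = ln.split()
            ids[k] = int(p[0])
            coords[k] = [float(p[1]), float(p[2]), float(p[3])]
        elem_lines = sections["Elements"]
        hexes, hex_phys, hex_ids, quads, quad_phys = [], [], [], [], []
        for ln in elem_lines[1:]:
            p = ln.split()
            etype = int(p[1])
            ntags = int(p[2])
            phys = int(p[3]) if ntags >= 1 else 0
            conn = [int(v) for v in p[3 + ntags:]]
            if etype == 5:
                hexes.append(conn)
                hex_phys.append(phys)
                hex_ids.append(int(p[0]))
            elif etype == 3:
                quads.append(conn)
                quad_phys.append(phys)
            elif etype in (1, 2, 15):
                continue
            else:
                raise MeshFormatError(
                    f"{path}: unsupported (non-hexahedral) volume cell type {etype}")
    elif version.startswith("4"):
        node_lines = sections["Nodes"]
        hdr = node_lines[0].split()
        n_blocks, n_nodes = int(hdr[0]), int(hdr[1])
        ids = np.empty(n_nodes, dtype=int)
        coords = np.empty((n_nodes, 3))
        pos = 1
        filled = 0
        for _ in range(n_blocks):
            bh = node_lines[pos].split()
            nb = int(bh[3])
            pos += 1
            blk_ids = [int(node_lines[pos + k]) for k in range(nb)]
            pos += nb
            for k in range(nb):
                p = node_lines[pos + k].split()
                ids[filled + k] = blk_ids[k]
                coords[filled + k] = [float(p[0]), float(p[1]), float(p[2])]
            pos += nb
            filled += nb
        # map entity tag → physical tag from $Entities
        ent_phys: dict[tuple, int] = {}
        ent = sections.get("Entities")
        if ent:
            counts = [int(v) for v in ent[0].split()]
            pos_e = 1
            for dim, cnt in enumerate(counts):
                for _ in range(cnt):
                    p = ent[pos_e].split()
                    tag = int(p[0])
                    nbox = 4 if dim == 0 else 7
                    nphys = int(p[nbox])
                    if nphys >= 1:
                        ent_phys[(dim, tag)] = int(p[nbox + 1])
                    pos_e += 1
        elem_lines = sections["Elements"]
        hdr = elem_lines[0].split()
        n_blocks = int(hdr[0])
        pos = 1
        hexes, hex_phys, hex_ids, quads, quad_phys = [], [], [], [], []
        for _ in range(n_blocks):
            bh = elem_lines[pos].split()
            dim, tag, etype, nb = (int(bh[0]), int(bh[1]), int(bh[2]),
                                   int(bh[3]))
            pos += 1
            phys = ent_phys.get((dim, tag), tag)
            for k in range(nb):
                p = elem_lines[pos + k].split()
                conn = [int(v) for v in p[1:]]
                if etype == 5:
                    hexes.append(conn)
                    hex_phys.append(phys)
                    hex_ids.append(int(p[0]))
                elif etype == 3:
                    quads.append(conn)
                    quad_phys.append(phys)
                elif etype in (1, 2, 15):
                    continue
                else:
                    raise MeshFormatError(
                        f"{path}: unsupported volume cell type {etype}")
            pos += nb
    else:
        raise MeshFormatError(f"{path}: unsupported Gmsh version {version}")
    if not hexes:
        raise MeshFormatError(f"{path}: no hexahedral cells found")
    order = np.argsort(ids)
    remap = np.empty(ids.max() + 1, dtype=int)
    remap[ids[order]] = np.arange(len(ids))
    nodes = coords[order]
    # restore the original element ordering from the element tags
    horder = np.argsort(np.asarray(hex_ids))
    elems = remap[np.asarray(hexes, dtype=int)][horder]
    phys_of_elem = np.asarray(hex_phys)[horder]

    def _is(name, tag, dim):
        return phys_names.get((dim, tag), "") == name or tag == \
            {"host": 1, "tumour": 2, "inlet": 3, "outlet": 4, "wall": 5}[name]

    tumour = np.array([_is("tumour", t, 3) for t in phys_of_elem])
    inlet = np.zeros(len(nodes), dtype=bool)
    outlet = np.zeros(len(nodes), dtype=bool)
    for q, t in zip(quads, quad_phys):
        if _is("inlet", t, 2):
            inlet[remap[np.asarray(q)]] = True
        elif _is("outlet", t, 2):
            outlet[remap[np.asarray(q)]] = True
    if not (inlet.any() and outlet.any()):
        raise MeshFormatError(f"{path}: missing inlet/outlet physical surfaces")
    mesh = Mesh(nodes=nodes, elems=elems, tumour_elems=tumour,
                inlet_nodes=inlet, outlet_nodes=outlet)
    # detect a rectilinear grid to re-enable fast point location
    ax_x = np.unique(nodes[:, 0])
    ax_y = np.unique(nodes[:, 1])
    ax_z = np.unique(nodes[:, 2])
    nguess = (len(ax_x) - 1, len(ax_y) - 1, len(ax_z) - 1)
    if min(nguess) > 0 and np.prod(nguess) == len(elems) and \
            (np.prod([len(a) for a in (ax_x, ax_y, ax_z)])
             == len(nodes)):
        test = generate_cube_like(nguess)
        if test.shape == elems.shape and np.array_equal(
                np.sort(test, axis=1), np.sort(elems, axis=1)):
            mesh.grid_axes = (ax_x, ax_y, ax_z)
            mesh.grid_n = tuple(int(v) for v in nguess)
    return mesh


def generate_cube_like(n):
    """Connectivity a rectilinear grid of extent ``n`` would have if nodes
    are ordered lexicographically (x fastest)."""
    nx, ny, nz = (int(v) for v in n)

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    I = I.ravel(order="F")
    J = J.ravel(order="F")
    K = K.ravel(order="F")
    return np.column_stack([
        nid(I, J, K), nid(I + 1, J, K), nid(I + 1, J + 1, K), nid(I, J + 1, K),
        nid(I, J, K + 1), nid(I + 1, J, K + 1), nid(I + 1, J + 1, K + 1),
        nid(I, J + 1, K + 1)]).astype(int)
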