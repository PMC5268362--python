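"""Summary metrics of the simulated vasculature and tissue fields:
vascular surface density, inter-capillary distance, vascular distance-map
scaling parameters (λ_v, δ_v-max), perfusion-state fractions,
diameter–length and velocity–diameter histograms, and radial profiles of
scalar fields along azimuthal rays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .flow import FlowSolution
from .mesh import Mesh
from .network import VascularNetwork, STATE_COLLAPSED, \
    nearest_other_vessel_distances

UM_PER_MM = 1000.0


def vascular_density(network: VascularNetwork,
                     positions: Optional[np.ndarray] = None,
                     region_volume: Optional[float] = None) -> float:
    """Un-normalised vascular density: Σ 2πR·L over functional segments
    divided by the region volume (defaults to the network bounding box of
    the initial lattice — callers normally pass the tissue volume)."""
    p = network.pos if positions is None else positions
    fmask = network.functional_segments()
    if not fmask.any():
        return 0.0
    L = network.segment_lengths(p)[fmask]
    segs = network.segments[fmask]
    R = 0.5 * (network.radius_um[segs[:, 0]]
               + network.radius_um[segs[:, 1]]) / UM_PER_MM
    surf = float((2.0 * np.pi * R * L).sum())
    if region_volume is None:
        span = p.max(axis=0) - p.min(axis=0)
        region_volume = float(np.prod(np.maximum(span, 1e-12)))
    return surf / region_volume


def intercapillary_distance(network: VascularNetwork,
                            positions: Optional[np.ndarray] = None,
                            sample_spacing: float = 0.05) -> float:
    """Mean distance from points on each vessel to the nearest point on any
    other vessel (centreline convention); NaN for a single vessel."""
    d = nearest_other_vessel_distances(network, sample_spacing, positions)
    if len(d) == 0 or np.all(np.isnan(d)):
        return float("nan")
    return float(np.nanmean(d))


@dataclass
class DistanceMap:
    delta: np.ndarray       # (nx, ny, nz) distance to nearest vessel, mm
    voxel: float
    origin: np.ndarray
    valid: bool             # False when the network was empty


def distance_map(network: VascularNetwork, lo, hi, voxel: float = 0.03,
                 positions: Optional[np.ndarray] = None) -> DistanceMap:
    """Euclidean distance transform δ_v of the voxelised functional network
    over the box [lo, hi]."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    occ = np.zeros(shape, dtype=bool)
    p = network.pos if positions is None else positions
    fmask = network.functional_segments()
    any_seg = False
    for s in np.where(fmask)[0]:
        a, b = network.segments[s]
        seg = p[b] - p[a]
        L = np.linalg.norm(seg)
        k = max(2, int(np.ceil(L / (0.5 * voxel))) + 1)
        t = np.linspace(0.0, 1.0, k)[:, None]
        pts = p[a] + t * seg
        idx = np.floor((pts - lo) / voxel).astype(int)
        inside = np.all(idx >= 0, axis=1) & np.all(idx < shape, axis=1)
        if inside.any():
            any_seg = True
            occ[tuple(idx[inside].T)] = True
    if not any_seg:
        # degenerate: distance to the region boundary as a proxy, flagged
        d = ndimage.distance_transform_edt(
            np.ones(shape), sampling=voxel)
        return DistanceMap(delta=d, voxel=voxel, origin=lo, valid=False)
    d = ndimage.distance_transform_edt(~occ, sampling=voxel)
    return DistanceMap(delta=d, voxel=voxel, origin=lo, valid=True)


def scaling_parameters(dmap: DistanceMap, min_count: int = 5,
                       n_bins: int = 40) -> tuple[float, float]:
    """(λ_v, δ_v-max) of a distance map.

    δ_v-max is the largest distance-to-vessel; λ_v is −1/slope of the
    log-linear regression of voxel frequency vs distance over the decaying
    tail of the histogram (bins beyond the mode with count ≥ min_count).
    Returns NaNs when fewer than 3 usable bins exist.
    """
    if not dmap.valid:
        return float("nan"), float("nan")
    vals = dmap.delta.ravel()
    delta_max = float(vals.max())
    counts, edges = np.histogram(vals, bins=n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    mode = int(np.argmax(counts))
    sel = np.arange(len(counts)) > mode
    sel &= counts >= min_count
    if sel.sum() < 3:
        return float("nan"), delta_max
    x = centres[sel]
    y = np.log(counts[sel].astype(float))
    slope, _ = np.polyfit(x, y, 1)
    lam = -1.0 / slope if slope < 0 else float("nan")
    return float(lam), delta_max


PERFUSION_CLASSES = ("hypo", "perfused", "well", "collapsed")


def perfusion_classification(network: VascularNetwork, flow: FlowSolution,
                             positions: Optional[np.ndarray] = None
                             ) -> dict:
    """Per-segment perfusion classes from the mean blood velocity:
    hypo < 0.1 mm/s, perfused ∈ [0.1, 0.5] mm/s (closed lower edge),
    well > 0.5 mm/s; collapsed segments form their own class.  Fractions
    reported both by segment count and by length."""
    L = network.segment_lengths(positions)
    coll_node = network.state == STATE_COLLAPSED
    seg_coll = coll_node[network.segments[:, 0]] | \
        coll_node[network.segments[:, 1]]
    v = flow.seg_velocity
    cls = np.empty(network.n_segments, dtype=object)
    cls[v < 0.1] = "hypo"
    cls[(v >= 0.1) & (v <= 0.5)] = "perfused"
    cls[v > 0.5] = "well"
    cls[seg_coll] = "collapsed"
    out = {"count": {}, "length": {}}
    n_tot = max(network.n_segments, 1)
    L_tot = max(L.sum(), 1e-300)
    for name in PERFUSION_CLASSES:
        m = cls == name
        out["count"][name] = float(m.sum()) / n_tot
        out["length"][name] = float(L[m].sum()) / L_tot
    return out


def histograms(network: VascularNetwork, flow: FlowSolution,
               positions: Optional[np.ndarray] = None,
               bin_width_um: float = 10.0) -> dict:
    """Diameter–length histogram over functional vessels (normalised length
    per diameter bin: 4–10, 10–20, 20–30 … μm) and mean velocity per bin;
    the collapsed-to-functional length ratio is reported separately."""
    L = network.segment_lengths(positions)
    segs = network.segments
    D_um = (network.radius_um[segs[:, 0]] + network.radius_um[segs[:, 1]])
    coll_node = network.state == STATE_COLLAPSED
    seg_coll = coll_node[segs[:, 0]] | coll_node[segs[:, 1]]
    func = ~seg_coll
    L_func = max(L[func].sum(), 1e-300)
    d_max = D_um[func].max() if func.any() else bin_width_um
    edges = [4.0, 10.0]
    while edges[-1] < d_max:
        edges.append(edges[-1] + bin_width_um)
    edges = np.asarray(edges)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = func & (D_um >= lo) & (D_um < hi)
        length = float(L[m].sum())
        vmean = float((flow.seg_velocity[m] * L[m]).sum() / length) \
            if length > 0 else float("nan")
        rows.append({"d_lo_um": float(lo), "d_hi_um": float(hi),
                     "norm_length": length / L_func,
                     "mean_velocity_mm_s": vmean})
    return {"bins": rows,
            "collapsed_length_ratio": float(L[seg_coll].sum()) / L_func}


def fibonacci_directions(n: int) -> np.ndarray:
    """n deterministic, nearly uniform unit directions on the sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def radial_profiles(nodal_field: np.ndarray, mesh: Mesh,
                    centre=None, n_rays: int = 14,
                    r_max: Optional[float] = None,
                    n_radial: int = 40) -> dict:
    """Sample a tissue nodal field along ``n_rays`` azimuthal rays from the
    tumour centre; bin by radius and return mean ± s.d. per radius."""
    from .mesh import shape_functions

    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    if centre is None:
        centre = 0.5 * (lo + hi)
    centre = np.asarray(centre, dtype=float)
    if r_max is None:
        r_max = float((hi - lo).min() / 2.0)
    radii = np.linspace(0.0, r_max * (1 - 1e-9), n_radial)
    dirs = fibonacci_directions(n_rays)
    pts = (centre[None, None, :]
           + radii[None, :, None] * dirs[:, None, :]).reshape(-1, 3)
    eids, locs, ok = mesh.locate_many(pts)
    vals = np.full(len(pts), np.nan)
    if ok.any():
        N = shape_functions(locs[ok])
        vals[ok] = np.einsum("ka,ka->k", N,
                             nodal_field[mesh.elems[eids[ok]]])
    vals = vals.reshape(n_rays, n_radial)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0)
    return {"radius_mm": radii, "mean": mean, "sd": sd}


def tumour_volume(mesh: Mesh, J_qp: Optional[np.ndarray] = None,
                  detJw: Optional[np.ndarray] = None) -> float:
    """Current tumour volume ∫_{Ω^T} det F dV (reference volume when no
    deformation state is given)."""
    if detJw is None:
        from .mesh import gauss_points, shape_gradients
        pts, w = gauss_points()
        dN = shape_gradients(pts)
        J0 = np.einsum("qaj,eai->eqij", dN, mesh.elem_coords)
        detJw = np.linalg.det(J0) * w
    tm = mesh.tumour_elems
    if J_qp is None:
        return float(detJw[tm].sum())
    return float((detJw[tm] * J_qp[tm]).sum())
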