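"""Multi-timescale coupling driver.

One outer (vascular) step of Δt_v = 6 h comprises: sub-cycled explicit
biochemical updates (CFL-limited, seconds-scale steps), a quasi-static
solid equilibrium solve every hour with the current oxygen-driven growth
tensor and ECM integrity, the vascular network update (taxis-guided tip
extension, stochastic branching, anastomosis, WSS remodelling, compression
check), the coupled flow solve, and a post-flow collapse re-assessment
with a flow re-solve when the topology changed.  Runs are bit-reproducible
under a fixed seed, including across checkpoint/restart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import biochem as bc
from . import metrics as mt
from .flow import solve_coupled_pressures
from .mesh import Mesh, gauss_points, shape_functions, generate_cube_mesh
from .network import VascularNetwork, build_initial_network, update_densities
from .params import SimConfig, validate_config, ConfigError, MMHG_PER_KPA
from .solid import SolidSolver, growth_volume_strain, growth_tensor
from .vessels import VesselStepper, TissueCues, interpolate_nodal

log = logging.getLogger("mechangio")


@dataclass
class EventCounters:
    extensions: int = 0
    branches: int = 0
    anastomoses: int = 0
    collapses: int = 0
    frozen: int = 0

    def absorb(self, ev) -> None:
        self.extensions += ev.extensions
        self.branches += ev.branches
        self.anastomoses += ev.anastomoses
        self.collapses += ev.collapses
        self.frozen += ev.frozen


class Simulation:
    """Full coupled simulation state and time-stepping loop."""

    def __init__(self, config: SimConfig, mesh: Mesh | None = None,
                 _defer_init: bool = False):
        self.config = config
        if mesh is None:
            h_c = config.mesh.h_centre_mm or None
            mesh = generate_cube_mesh(
                config.mesh.edge_length_mm, config.mesh.n_per_side,
                config.mesh.tumour_diameter_mm,
                elongation_limit=config.tip.v_max
                * config.taxis.dt_vascular_days,
                h_centre=h_c, growth=config.mesh.grading_growth)
        problems = validate_config(config, mesh)
        if problems:
            raise ConfigError("; ".join(problems))
        self.mesh = mesh
        self.biochem = bc.BiochemSolver(mesh, config.biochem)
        self.solid = SolidSolver(mesh, config.solid)
        self.stepper = VesselStepper(
            mesh, config.effective_taxis(), config.tip, config.branching,
            config.remodelling, config.collapse)
        self.dt_biochem = bc.stable_timestep(
            mesh, config.biochem, config.solid.dt_solid_hours / 24.0)
        self.dt_solid = config.solid.dt_solid_hours / 24.0
        self.dt_v = config.taxis.dt_vascular_days
        pts, _ = gauss_points()
        self._Nqp = shape_functions(pts)          # (8q, 8a)
        self.history: list[dict] = []
        if _defer_init:
            return
        self._fresh_state()
        self.initial_flow_and_metrics()

    # ------------------------------------------------------------------
    def _fresh_state(self):
        cfg = self.config
        self.t = 0.0
        self.step_count = 0
        self.rng = np.random.Generator(np.random.PCG64(cfg.seed))
        self.network = build_initial_network(
            self.mesh, cfg.network.spacing_mm, cfg.network.parent_radius_um,
            cfg.network.parent_thickness_um, cfg.network.parent_pore_um)
        self.fields = bc.initial_fields(self.mesh)
        nel = self.mesh.n_elems
        self.theta_vol = np.zeros((nel, 8))
        self.theta_oxy = np.zeros((nel, 8))
        self.theta_ecm = np.zeros((nel, 8))
        self.u = np.zeros((self.mesh.n_nodes, 3))
        self.solid_state = None
        self.counters = EventCounters()
        self.baseline_density = None

    def initial_flow_and_metrics(self):
        self.flow = solve_coupled_pressures(self.network, self.mesh,
                                            self.config.fluid, None)
        well = self.flow.well_perfused_nodes(
            self.config.remodelling.v_well_mm_s)
        self.densities = update_densities(self.network, self.mesh, well)
        self.baseline_density = mt.vascular_density(
            self.network, region_volume=self._domain_volume())
        self.history.append(self.metrics_row())

    def _domain_volume(self) -> float:
        span = self.mesh.nodes.max(axis=0) - self.mesh.nodes.min(axis=0)
        return float(np.prod(span))

    # ------------------------------------------------------------------
    def _qp_interp(self, nodal: np.ndarray) -> np.ndarray:
        return np.einsum("qa,ea->eq", self._Nqp,
                         nodal[self.mesh.elems])

    def _update_growth(self, dt_days: float):
        """Ratchet the growth strains from the current oxygen field.

        Growth is permanent (ϑ never decreases) and rate-limited: the
        growth stretch λ_g may rise at most ``growth_rate_per_day``·Δt per
        update, matching the finite speed at which tissue interfaces
        advance (~160 μm/day of diameter gain on a 1 mm seed).
        """
        cfg = self.config.solid
        xi_qp = self._qp_interp(self.fields.oxy)
        tum = self.mesh.tumour_elems
        dlam = cfg.growth_rate_per_day * dt_days

        def ratchet(theta, triplet):
            tgt = growth_volume_strain(xi_qp[tum], triplet)
            lam_prev = np.sqrt(2.0 * theta[tum] + 1.0)
            lam_tgt = np.sqrt(2.0 * np.maximum(tgt, 0.0) + 1.0)
            lam_new = np.minimum(lam_tgt, lam_prev + dlam)
            theta[tum] = np.maximum(theta[tum],
                                    0.5 * (lam_new ** 2 - 1.0))

        ratchet(self.theta_vol, cfg.growth_vol)
        ratchet(self.theta_oxy, cfg.growth_oxy)
        ratchet(self.theta_ecm, cfg.growth_ecm)

    def _solve_solid(self):
        grad_xi = self.biochem.gradients_qp(self.fields.oxy)
        grad_ec = self.biochem.gradients_qp(self.fields.ecm)
        Fg = growth_tensor(self.theta_vol, self.theta_oxy, self.theta_ecm,
                           grad_xi, grad_ec)
        zeta = np.clip(self._qp_interp(self.fields.ecm),
                       self.config.biochem.ecm_floor, 1.0)
        Fg_prev = getattr(self, "_Fg_prev", None)
        self.solid_state = self.solid.solve(Fg, zeta, u0=self.u,
                                            Fg_prev=Fg_prev)
        self._Fg_prev = Fg
        self.u = self.solid_state.u

    def _cues(self) -> TissueCues:
        net = self.network
        n = net.n_nodes
        taf_v = interpolate_nodal(self.mesh, self.fields.taf, net)
        gt = self.biochem.element_gradient(self.fields.taf)
        ge = self.biochem.element_gradient(self.fields.ecm)
        if self.solid_state is not None:
            S_elem = self.solid_state.S.mean(axis=1)
            thp = np.zeros(n)
            ok = net.host_elem >= 0
            thp[ok] = self.solid.thp_at_points(
                self.solid_state, net.host_elem[ok], net.local[ok])
        else:
            S_elem = None
            thp = np.zeros(n)
        flow = self.flow
        return TissueCues(
            taf_at_nodes=taf_v, grad_taf_elem=gt, grad_ecm_elem=ge,
            stress_elem=S_elem, thp_at_nodes=thp,
            p_int_at_nodes=_fit(flow.p_int_at_vnodes, n),
            p_vsc=_fit(flow.p_vsc, n, fill=np.inf),
            node_wss=_fit(flow.node_wss, n),
            node_velocity=_fit(flow.node_velocity, n))

    # ------------------------------------------------------------------
    def run_vascular_step(self) -> EventCounters:
        cfg = self.config
        n_solid = max(1, int(round(self.dt_v / self.dt_solid)))
        sub_dt = self.dt_v / n_solid
        for _ in range(n_solid):
            self.fields = self.biochem.advance(
                self.fields, self.densities.rho_v, self.densities.rho_t,
                sub_dt, self.dt_biochem)
            self._update_growth(sub_dt)
            self._solve_solid()
        cues = self._cues()
        ev = self.stepper.step(self.network, cues, self.t, self.dt_v,
                               self.rng)
        self.network.rehost(self.mesh)
        self.t += self.dt_v
        self.step_count += 1
        self.flow = solve_coupled_pressures(self.network, self.mesh,
                                            cfg.fluid, self.u)
        # re-update: reassess collapse with the fresh pressures
        n = self.network.n_nodes
        thp = np.zeros(n)
        ok = self.network.host_elem >= 0
        if self.solid_state is not None:
            thp[ok] = self.solid.thp_at_points(
                self.solid_state, self.network.host_elem[ok],
                self.network.local[ok])
        changed = self.stepper.apply_compression_and_collapse(
            self.network, self.flow.p_int_at_vnodes, thp, self.flow.p_vsc,
            self.t, self.flow.node_wss, ev)
        if changed:
            self.flow = solve_coupled_pressures(self.network, self.mesh,
                                                cfg.fluid, self.u)
        well = self.flow.well_perfused_nodes(cfg.remodelling.v_well_mm_s)
        self.densities = update_densities(self.network, self.mesh, well)
        self.counters.absorb(ev)
        log.info("day %.2f: +%d ext, +%d branch, +%d anast, +%d collapse "
                 "(%d nodes, %d segments)", self.t, ev.extensions,
                 ev.branches, ev.anastomoses, ev.collapses,
                 self.network.n_nodes, self.network.n_segments)
        return self.counters

    def run(self, days: float | None = None,
            snapshot_prefix: str | None = None) -> list[dict]:
        days = self.config.total_days if days is None else days
        while self.t < days - 1e-9:
            self.run_vascular_step()
            if self.step_count % self.config.output_every_steps == 0 or \
                    self.t >= days - 1e-9:
                self.history.append(self.metrics_row())
                if snapshot_prefix:
                    from .vtkio import write_state
                    write_state(self.mesh, self.fields, self.network,
                                self.flow, f"{snapshot_prefix}_day{self.t:06.2f}",
                                displacements=self.u)
            if self.config.checkpoint_path:
                self.save_checkpoint(self.config.checkpoint_path)
        return self.history

    # ------------------------------------------------------------------
    def metrics_row(self, heavy: bool = True) -> dict:
        cfg = self.config
        pos = self.network.current_positions(self.mesh, self.u)
        dens = mt.vascular_density(self.network, positions=pos,
                                   region_volume=self._domain_volume())
        norm = dens / self.baseline_density if self.baseline_density else 1.0
        tum_nodes = self.mesh.node_in_tumour
        plateau = float(self.flow.p_int[tum_nodes].mean())
        max_ifv = float(self.flow.edge_velocity.max() * 1000.0)  # μm/s
        perf = mt.perfusion_classification(self.network, self.flow, pos)
        J_qp = self.solid_state.J if self.solid_state is not None else None
        vol = mt.tumour_volume(self.mesh, J_qp, self.solid.detJw)
        row = {
            "day": self.t,
            "tumour_volume_mm3": vol,
            "norm_vasc_density": norm,
            "plateau_ifp_mmhg": plateau,
            "max_ifv_um_s": max_ifv,
            "frac_hypo": perf["count"]["hypo"],
            "frac_perfused": perf["count"]["perfused"],
            "frac_well": perf["count"]["well"],
            "frac_collapsed": perf["count"]["collapsed"],
            "n_nodes": self.network.n_nodes,
            "n_segments": self.network.n_segments,
            "extensions": self.counters.extensions,
            "branches": self.counters.branches,
            "anastomoses": self.counters.anastomoses,
            "collapses": self.counters.collapses,
        }
        if heavy:
            row["mean_icd_mm"] = mt.intercapillary_distance(
                self.network, positions=pos, sample_spacing=0.1)
            lo, hi = self._analysis_box(pos)
            dmap = mt.distance_map(self.network, lo, hi, voxel=0.03,
                                   positions=pos)
            lam, dmax = mt.scaling_parameters(dmap)
            row["lambda_v_mm"] = lam
            row["delta_v_max_mm"] = dmax
        return row

    def _analysis_box(self, pos, shell: float = 1.0):
        """Tumour bounding box (deformed) plus a peri-tumoural shell."""
        tum_nodes = np.unique(self.mesh.elems[self.mesh.tumour_elems])
        x = self.mesh.nodes[tum_nodes] + self.u[tum_nodes]
        lo = x.min(axis=0) - shell
        hi = x.max(axis=0) + shell
        dom_lo = self.mesh.nodes.min(axis=0)
        dom_hi = self.mesh.nodes.max(axis=0)
        return np.maximum(lo, dom_lo), np.minimum(hi, dom_hi)

    # ------------------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        net = self.network
        np.savez(
            path,
            config=json.dumps(self.config.to_dict()),
            t=self.t, step_count=self.step_count,
            rng_state=json.dumps(self.rng.bit_generator.state),
            baseline_density=self.baseline_density,
            counters=np.array([self.counters.extensions,
                               self.counters.branches,
                               self.counters.anastomoses,
                               self.counters.collapses,
                               self.counters.frozen]),
            taf=self.fields.taf, oxy=self.fields.oxy, mmp=self.fields.mmp,
            ecm=self.fields.ecm,
            theta_vol=self.theta_vol, theta_oxy=self.theta_oxy,
            theta_ecm=self.theta_ecm, u=self.u,
            net_pos=net.pos, net_birth=net.birth_time, net_tip=net.is_tip,
            net_inlet=net.is_inlet, net_outlet=net.is_outlet,
            net_frozen=net.frozen, net_R=net.radius_um,
            net_Rb=net.radius_base_um, net_h=net.thickness_um,
            net_rp=net.pore_um, net_state=net.state,
            net_host=net.host_elem, net_local=net.local,
            net_dir=net.direction, net_segs=net.segments,
            net_rest=net.rest_length)

    @classmethod
    def from_checkpoint(cls, path) -> "Simulation":
        d = np.load(path, allow_pickle=False)
        config = SimConfig.from_dict(json.loads(str(d["config"])))
        sim = cls(config, _defer_init=True)
        sim.t = float(d["t"])
        sim.step_count = int(d["step_count"])
        sim.rng = np.random.Generator(np.random.PCG64())
        sim.rng.bit_generator.state = json.loads(str(d["rng_state"]))
        sim.baseline_density = float(d["baseline_density"])
        c = d["counters"]
        sim.counters = EventCounters(*(int(v) for v in c))
        sim.fields = bc.TissueFields(d["taf"], d["oxy"], d["mmp"], d["ecm"])
        sim.theta_vol = d["theta_vol"]
        sim.theta_oxy = d["theta_oxy"]
        sim.theta_ecm = d["theta_ecm"]
        sim.u = d["u"]
        sim.network = VascularNetwork(
            pos=d["net_pos"], birth_time=d["net_birth"],
            is_tip=d["net_tip"], is_inlet=d["net_inlet"],
            is_outlet=d["net_outlet"], frozen=d["net_frozen"],
            radius_um=d["net_R"], radius_base_um=d["net_Rb"],
            thickness_um=d["net_h"], pore_um=d["net_rp"],
            state=d["net_state"], host_elem=d["net_host"],
            local=d["net_local"], direction=d["net_dir"],
            segments=d["net_segs"], rest_length=d["net_rest"])
        sim.solid_state = None
        if sim.t > 0:
            sim._solve_solid()
        sim.flow = solve_coupled_pressures(sim.network, sim.mesh,
                                           config.fluid,
                                           sim.u if sim.t > 0 else None)
        well = sim.flow.well_perfused_nodes(config.remodelling.v_well_mm_s)
        sim.densities = update_densities(sim.network, sim.mesh, well)
        return sim


def _fit(arr, n, fill=0.0):
    out = np.full(n, fill, dtype=float)
    k = min(len(arr), n)
    out[:k] = arr[:k]
    return out
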