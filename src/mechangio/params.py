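"""Model parameters and simulation configuration.

Every physical parameter of the coupled model lives here, grouped by the
solver module that consumes it.  Defaults marked ``[paper]`` are printed in
the main text of the source study; defaults marked ``[assumed]`` stand in for
supplementary-table values that are not publicly tabulated and were chosen
once on physiological-realism grounds (see docs/methods.md for the
reasoning).  Units are mm / day / mm-Hg / μm (radii, thicknesses) throughout;
each field documents its own unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

MMHG_PER_KPA = 7.50062  # unit conversion applied once at the vessel-coupling boundary
SECONDS_PER_DAY = 86400.0


@dataclass
class BiochemParams:
    """Reaction–diffusion constants for TAF (τ), oxygen (ξ), MMP (μ), ECM (ε).

    Concentrations are normalised; rates in day⁻¹, diffusivities in mm²/day.
    """

    D_taf: float = 8.64      # [assumed] VEGF-like diffusivity ≈ 1e-6 cm²/s
    D_oxy: float = 8.64      # [assumed] effective tissue oxygen diffusivity
    D_mmp: float = 0.86      # [assumed] large protease, ~10x slower than TAF
    delta_taf: float = 1.0   # [assumed] decay + cellular consumption
    delta_oxy: float = 100.0  # [assumed] consumption; L = sqrt(D/δ) ≈ 0.29 mm
    delta_mmp: float = 2.0   # [assumed]
    delta_ecm: float = 0.3   # [assumed] ECM degradation rate (Eq for ε)
    lambda_taf: float = 10.0  # [assumed] TAF production rate in hypoxic tumour
    lambda_oxy: float = 100.0  # [assumed] = delta_oxy so ξ* = 1 at ρ_v = 1
    lambda_mmp_c: float = 5.0  # [assumed] MMP production by cancer cells
    lambda_mmp_v: float = 1.0  # [assumed] MMP production per tip-EC node
    oxy_scale: float = 1.0   # [assumed] ξ̄, oxygen scale in TAF production
    ecm_floor: float = 0.05  # clipping floor for ε (keeps ζ strictly positive)
    cfl_safety: float = 0.5

    def d_max(self) -> float:
        return max(self.D_taf, self.D_oxy, self.D_mmp)


@dataclass
class MaterialParams:
    """Hyperelastic constants of one tissue type (generalised polynomial)."""

    c10: float = 0.5   # kPa
    c20: float = 0.0
    c01: float = 0.0
    c02: float = 0.0
    c11: float = 0.0
    kappa: float = 25.0  # kPa, near-incompressibility penalty


@dataclass
class GrowthTriplet:
    """(α, β, γ) of the Gompertz-type growth-strain law ϑ(ξ)."""

    alpha: float
    beta: float
    gamma: float


@dataclass
class SolidParams:
    host: MaterialParams = field(
        default_factory=lambda: MaterialParams(c10=1.0, kappa=50.0))   # [assumed]
    tumour: MaterialParams = field(
        default_factory=lambda: MaterialParams(c10=3.0, kappa=150.0))  # [assumed]
    # volumetric growth ϑ_g(ξ); α sets the asymptotic volume gain
    growth_vol: GrowthTriplet = field(
        default_factory=lambda: GrowthTriplet(25.0, 12.0, 3.0))        # [assumed]
    # directional growth strains along ∇ξ and ∇ε (same functional form)
    growth_oxy: GrowthTriplet = field(
        default_factory=lambda: GrowthTriplet(5.0, 12.0, 3.0))         # [assumed]
    growth_ecm: GrowthTriplet = field(
        default_factory=lambda: GrowthTriplet(5.0, 12.0, 3.0))         # [assumed]
    # cap on the growth-stretch rate dλ_g/dt; the quoted tissue-interface
    # speed (~160 μm/day diameter gain on a 1 mm seed) gives 0.16/day
    growth_rate_per_day: float = 0.16  # [paper]
    newton_rtol: float = 1e-8
    newton_utol: float = 1e-10
    newton_maxit: int = 80
    max_cutbacks: int = 6
    dt_solid_hours: float = 1.0  # [paper] "set equal to approximately one hour"
    cauchy_pressure: bool = True  # False → paper-literal −tr(S)/3


@dataclass
class FluidParams:
    mu_blood: float = 3.0e-5          # mm-Hg·s [assumed] ≈ 4 mPa·s whole blood
    K_int_host: float = 4.0e-6        # mm²/(mm-Hg·s) [assumed]
    K_int_tumour: float = 2.0e-5      # mm²/(mm-Hg·s) [assumed]
    gamma_pore: float = 1.0e-3        # pore area fraction of wall [assumed]
    sigma_osmotic: float = 0.82       # reflection coefficient [assumed]
    pi_vsc: float = 20.0              # mm-Hg plasma osmotic pressure [assumed]
    pi_int: float = 15.0              # mm-Hg interstitial osmotic [assumed]
    p_inlet: float = 25.0             # mm-Hg [paper]
    p_outlet: float = 10.0            # mm-Hg [paper]
    p_boundary_int: float = 0.1       # mm-Hg [paper]
    S_vsc_default: float = 0.52       # mm⁻¹ fallback surface density [assumed]
    R_bar_default_um: float = 30.0    # μm fallback neighbourhood radius [assumed]


@dataclass
class TaxisParams:
    k_taf: float = 1.0          # chemotaxis weight [assumed]
    k_ecm: float = 0.2          # haptotaxis weight [assumed]
    k_mech: float = 0.1         # mechanotaxis weight [assumed]
    taf_threshold: float = 0.02  # τ* [paper: sensitivity value with monotone growth]
    anastomosis_um: float = 40.0  # capture distance [paper]
    dt_vascular_days: float = 0.25  # Δt_v = 6 h [paper]


@dataclass
class TipKineticsParams:
    v0: float = 0.025      # mm/day, large-lumen floor speed [assumed]
    v1: float = 0.30       # mm/day, exponential amplitude [assumed]
    R_tilde_um: float = 10.0  # μm decay radius [assumed]
    v_max: float = 0.25    # mm/day [paper: v_v-max·Δt_v = 0.0625 mm]
    R_cutoff_um: float = 2.0  # μm, below which v = v_max [paper]


@dataclass
class BranchingClassParams:
    """Gaussian mixture for one perfusion class (mode-normalised components)."""

    age_median_days: float = 2.0     # [assumed]
    age_sd_days: float = 1.5         # [assumed]
    dist_median_um: float = 400.0    # [assumed]
    dist_sd_um: float = 150.0        # [assumed]
    w_age: float = 0.06
    w_dist: float = 0.06


@dataclass
class BranchingParams:
    hypo: BranchingClassParams = field(
        default_factory=lambda: BranchingClassParams(w_age=0.03,
                                                     w_dist=0.03))
    well: BranchingClassParams = field(
        default_factory=lambda: BranchingClassParams(w_age=0.01,
                                                     w_dist=0.01))
    min_branch_angle_deg: float = 30.0  # [assumed] see docs/methods.md


@dataclass
class RemodellingParams:
    t_m0_days: float = 100.0   # [paper] remodelling time at zero WSS
    t_mT_days: float = 10.0    # [paper] remodelling time above threshold
    wss_coeff: float = 2.4e-8  # mm-Hg·m; τ̄_f = coeff / R(m)  [paper]
    R_min_um: float = 5.0      # [paper] nascent lumen radius
    R_max_um: float = 50.0     # [paper] fully remodelled lumen radius
    B_R: float = 11.0          # [paper]
    C_R: float = 4.4           # [paper]
    h_min_um: float = 0.5      # [assumed]
    h_max_um: float = 3.0      # [assumed]
    r_pore_min_um: float = 0.005  # [assumed] 5 nm, tight mature endothelium
    r_pore_max_um: float = 0.2    # [assumed] 200 nm, leaky nascent vessel
    v_well_mm_s: float = 0.1   # [paper] well-perfused velocity threshold


@dataclass
class CollapseParams:
    e_crit: float = 0.92        # [paper] critical radial strain
    E_wall_min: float = 1.3     # [paper] nascent-vessel stiffness
    E_wall_max: float = 5.22    # [paper] parent-vessel stiffness
    lambda_collapse: float = 1.0e3  # [paper] R scaling at collapse
    plastic_compression: bool = False  # compressed radii recover by default


@dataclass
class NetworkParams:
    spacing_mm: float = 0.6     # [paper] inter-capillary spacing
    parent_radius_um: float = 30.0   # [assumed]
    parent_thickness_um: float = 3.0  # [assumed] = h_max (fully remodelled)
    parent_pore_um: float = 0.005     # [assumed] = r_p^min


@dataclass
class MeshParams:
    edge_length_mm: float = 12.0   # [paper]
    n_per_side: int = 17           # used only for uniform grids
    tumour_diameter_mm: float = 1.0  # [paper]
    # centre refinement: finest element edge at the tumour (0 → uniform grid)
    h_centre_mm: float = 0.25
    grading_growth: float = 1.6


@dataclass
class SimConfig:
    """Full configuration of a coupled simulation."""

    mesh: MeshParams = field(default_factory=MeshParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    biochem: BiochemParams = field(default_factory=BiochemParams)
    solid: SolidParams = field(default_factory=SolidParams)
    fluid: FluidParams = field(default_factory=FluidParams)
    taxis: TaxisParams = field(default_factory=TaxisParams)
    tip: TipKineticsParams = field(default_factory=TipKineticsParams)
    branching: BranchingParams = field(default_factory=BranchingParams)
    remodelling: RemodellingParams = field(default_factory=RemodellingParams)
    collapse: CollapseParams = field(default_factory=CollapseParams)
    total_days: float = 40.0
    seed: int = 0
    taxis_mode: str = "combined"  # or "chemo_only"
    output_every_steps: int = 4
    checkpoint_path: Optional[str] = None

    def effective_taxis(self) -> TaxisParams:
        """Taxis weights after applying the mode switch (chemo_only zeroes
        haptotaxis and mechanotaxis, leaving everything else untouched)."""
        t = dataclasses.replace(self.taxis)
        if self.taxis_mode == "chemo_only":
            t.k_ecm = 0.0
            t.k_mech = 0.0
        return t

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        def build(tp, val):
            if dataclasses.is_dataclass(tp) and isinstance(val, dict):
                kw = {}
                for f in dataclasses.fields(tp):
                    if f.name in val:
                        kw[f.name] = build(_field_type(tp, f.name), val[f.name])
                return tp(**kw)
            return val

        return build(cls, d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_TYPE_MAP = {
    "mesh": MeshParams, "network": NetworkParams, "biochem": BiochemParams,
    "solid": SolidParams, "fluid": FluidParams, "taxis": TaxisParams,
    "tip": TipKineticsParams, "branching": BranchingParams,
    "remodelling": RemodellingParams, "collapse": CollapseParams,
    "host": MaterialParams, "tumour": MaterialParams,
    "growth_vol": GrowthTriplet, "growth_oxy": GrowthTriplet,
    "growth_ecm": GrowthTriplet, "hypo": BranchingClassParams,
    "well": BranchingClassParams,
}


def _field_type(tp, name):
    return _TYPE_MAP.get(name, object)


class ConfigError(ValueError):
    """A configuration invariant is violated."""


def validate_config(cfg: SimConfig, mesh=None) -> list[str]:
    """Check configuration invariants; return a list of failure messages.

    Hard failures include negative rates/diffusivities, mis-ordered
    remodelling bounds, and violation of the mesh-compatibility rule
    (minimum element edge ≥ maximum tip elongation per vascular step).
    """
    problems: list[str] = []
    b = cfg.biochem
    for nm in ("D_taf", "D_oxy", "D_mmp", "delta_taf", "delta_oxy",
               "delta_mmp", "delta_ecm", "lambda_taf", "lambda_oxy",
               "lambda_mmp_c", "lambda_mmp_v"):
        if getattr(b, nm) < 0:
            problems.append(f"biochem.{nm} must be non-negative")
    r = cfg.remodelling
    if not r.t_mT_days < r.t_m0_days:
        problems.append("remodelling.t_mT_days must be < t_m0_days")
    if not r.R_min_um < r.R_max_um:
        problems.append("remodelling.R_min_um must be < R_max_um")
    if not r.r_pore_min_um < r.r_pore_max_um:
        problems.append("remodelling.r_pore_min_um must be < r_pore_max_um")
    c = cfg.collapse
    if not 0 < c.e_crit < 1:
        problems.append("collapse.e_crit must lie in (0,1)")
    if c.E_wall_min <= 0 or c.E_wall_max < c.E_wall_min:
        problems.append("collapse wall stiffness range invalid")
    f = cfg.fluid
    if not 0 <= f.sigma_osmotic <= 1:
        problems.append("fluid.sigma_osmotic must lie in [0,1]")
    if f.mu_blood <= 0 or f.K_int_host <= 0 or f.K_int_tumour <= 0:
        problems.append("fluid conductivities/viscosity must be positive")
    br = cfg.branching
    if br.hypo.w_age < br.well.w_age or br.hypo.w_dist < br.well.w_dist:
        problems.append("branching: hypo-perfused weights must dominate "
                        "well-perfused weights (hypo vessels bifurcate more easily)")
    for cl in (br.hypo, br.well):
        if cl.age_sd_days <= 0 or cl.dist_sd_um <= 0:
            problems.append("branching standard deviations must be positive")
        if cl.w_age + cl.w_dist > 1.0 + 1e-12:
            problems.append("branching mixture weights must sum to ≤ 1")
    if cfg.taxis_mode not in ("combined", "chemo_only"):
        problems.append(f"unknown taxis_mode {cfg.taxis_mode!r}")
    if min(cfg.taxis.k_taf, cfg.taxis.k_ecm, cfg.taxis.k_mech) < 0:
        problems.append("taxis weights must be non-negative")
    # mesh-compatibility rule
    elong = cfg.tip.v_max * cfg.taxis.dt_vascular_days
    if mesh is not None:
        h_min = float(mesh.min_edge_length)
    elif cfg.mesh.h_centre_mm:
        h_min = cfg.mesh.h_centre_mm
    else:
        h_min = cfg.mesh.edge_length_mm / cfg.mesh.n_per_side
    if h_min < elong - 1e-12:
        problems.append(
            f"mesh minimum edge {h_min:.4g} mm is smaller than the maximum "
            f"tip elongation per vascular step {elong:.4g} mm")
    if cfg.mesh.tumour_diameter_mm >= cfg.mesh.edge_length_mm / 2:
        problems.append("tumour diameter must be < half the cube edge")
    return problems
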