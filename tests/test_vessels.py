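import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mechangio.network import STATE_COLLAPSED, STATE_COMPRESSED
from mechangio.params import (BranchingClassParams, BranchingParams,
                              CollapseParams, RemodellingParams, TaxisParams,
                              TipKineticsParams)
from mechangio.vessels import (VesselStepper, branching_probability,
                               lumen_radius, pc_from_stiffness, pore_radius,
                               pressure_ratio, remodelling_time,
                               sprout_direction, stiffness_from_pc,
                               tip_speed, wall_strain, wall_thickness,
                               wss_threshold_mmhg, _enforce_min_angle,
                               StepEvents)
from conftest import make_network


class TestSproutDirection:
    P = TaxisParams(k_taf=1.0, k_ecm=0.5, k_mech=0.3)

    def test_pure_chemotaxis(self):
        p = TaxisParams(k_taf=1.0, k_ecm=0.0, k_mech=0.0)
        e = sprout_direction([2.0, 0, 0], [0, 9, 0], [0, 0, 9],
                             [0, 0, 1], p)
        assert np.allclose(e, [1, 0, 0])

    def test_mechanotaxis_minus_sign(self):
        p = TaxisParams(k_taf=0.0, k_ecm=0.0, k_mech=1.0)
        e = sprout_direction([0, 0, 0], [0, 0, 0], [0, 0, 1.0],
                             [1, 0, 0], p)
        assert np.allclose(e, [0, 0, -1])

    def test_vanishing_drive_returns_previous(self):
        e = sprout_direction([0, 0, 0], [0, 0, 0], [0, 0, 0],
                             [0, 1, 0], self.P)
        assert np.allclose(e, [0, 1, 0])

    @given(st.lists(st.floats(-5, 5), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_unit_norm(self, vals):
        v = np.asarray(vals).reshape(3, 3)
        e = sprout_direction(v[0], v[1], v[2], [1.0, 0, 0], self.P)
        assert np.isclose(np.linalg.norm(e), 1.0)


class TestTipSpeed:
    P = TipKineticsParams()

    def test_large_radius_floor(self):
        assert tip_speed(1e6, self.P) == pytest.approx(self.P.v0)

    def test_at_reference_radius(self):
        v = self.P.v0 + self.P.v1 / np.e
        assert tip_speed(self.P.R_tilde_um, self.P) == pytest.approx(
            min(v, self.P.v_max))

    def test_small_radius_clamped_to_vmax(self):
        assert tip_speed(1.0, self.P) == self.P.v_max
        assert tip_speed(0.5, self.P) == self.P.v_max

    def test_never_exceeds_vmax(self):
        R = np.linspace(0.1, 100, 500)
        assert np.all(tip_speed(R, self.P) <= self.P.v_max + 1e-15)


class TestRemodellingLaws:
    P = RemodellingParams()

    def test_wss_threshold_calibration(self):
        # τ̄_f = 2.4e-8/R mm-Hg (R in metres): 4e-4 at R = 60 μm
        assert wss_threshold_mmhg(60.0) == pytest.approx(4e-4)

    def test_time_endpoints(self):
        tb = 4e-4
        assert remodelling_time(0.0, tb, self.P) == pytest.approx(100.0)
        assert remodelling_time(tb, tb, self.P) == pytest.approx(10.0)
        assert remodelling_time(2 * tb, tb, self.P) == pytest.approx(10.0)

    def test_time_at_threshold_over_sqrt2(self):
        # (1 − 1/2)⁻¹ = 2 → t_m = t_mT + Δt_m/e ≈ 43.1 d
        tb = 4e-4
        t = remodelling_time(tb / np.sqrt(2), tb, self.P)
        assert t == pytest.approx(10.0 + 90.0 / np.e, rel=1e-12)
        assert t == pytest.approx(43.1, abs=0.02)

    def test_lumen_radius_tip_and_growth(self):
        assert lumen_radius(0.7, True, self.P) == self.P.R_min_um
        A = self.P.R_max_um - self.P.R_min_um
        # t̄ = 0 → R_min + A·e⁻¹¹ ≈ R_min
        assert lumen_radius(0.0, False, self.P) == pytest.approx(
            self.P.R_min_um + A * np.exp(-11.0))
        # t̄ = 1 → R_min + A·exp(−11 e^−4.4) ≈ R_min + 0.873·A
        expect = self.P.R_min_um + A * np.exp(-11.0 * np.exp(-4.4))
        assert lumen_radius(1.0, False, self.P) == pytest.approx(expect)
        assert expect == pytest.approx(self.P.R_min_um + 0.873 * A,
                                       rel=1e-3)

    def test_thickness_monotone_linear(self):
        assert wall_thickness(0.0, self.P) == self.P.h_min_um
        assert wall_thickness(1.0, self.P) == self.P.h_max_um
        assert wall_thickness(5.0, self.P) == self.P.h_max_um
        mid = 0.5 * (self.P.h_min_um + self.P.h_max_um)
        assert wall_thickness(0.5, self.P) == pytest.approx(mid)

    def test_pore_radius_cubic(self):
        assert pore_radius(0.0, self.P) == pytest.approx(
            self.P.r_pore_max_um)
        # continuity at t̄ = 1: A_r + B_r + C_r = r_p^min
        assert pore_radius(1.0 - 1e-12, self.P) == pytest.approx(
            self.P.r_pore_min_um, rel=1e-6)
        assert pore_radius(2.0, self.P) == self.P.r_pore_min_um

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_pore_radius_monotone_bounded(self, t):
        r = pore_radius(t, self.P)
        r2 = pore_radius(min(t + 0.05, 1.0), self.P)
        assert self.P.r_pore_min_um - 1e-12 <= r <= \
            self.P.r_pore_max_um + 1e-12
        assert r2 <= r + 1e-12


class TestBranchingProbability:
    CLS = BranchingClassParams(age_median_days=2.0, age_sd_days=1.5,
                               dist_median_um=400.0, dist_sd_um=150.0,
                               w_age=0.3, w_dist=0.3)

    def test_maximal_at_both_modes(self):
        p_mode = branching_probability(2.0, 400.0, self.CLS)
        assert p_mode == pytest.approx(self.CLS.w_age + self.CLS.w_dist)
        grid = [branching_probability(a, d, self.CLS)
                for a in np.linspace(0, 10, 30)
                for d in np.linspace(0, 2000, 30)]
        assert p_mode >= max(grid) - 1e-12

    def test_far_tail_negligible(self):
        # five standard deviations out on both arguments
        p = branching_probability(2.0 + 5 * 1.5, 400.0 + 5 * 150.0,
                                  self.CLS)
        p_max = branching_probability(2.0, 400.0, self.CLS)
        assert p < 1e-4 * p_max

    def test_bounded_in_unit_interval(self):
        assert 0.0 <= branching_probability(0.0, 0.0, self.CLS) <= 1.0

    def test_hypo_dominates_well_under_defaults(self):
        bp = BranchingParams()
        ages = np.linspace(0, 10, 20)
        dists = np.linspace(0, 1500, 20)
        for a in ages:
            for d in dists:
                assert branching_probability(a, d, bp.hypo) >= \
                    branching_probability(a, d, bp.well)


class TestPressureRatioAndCollapse:
    def test_ratio_basic(self):
        assert pressure_ratio(5.0, 5.0, 10.0) == pytest.approx(1.0)
        assert pressure_ratio(0.0, 0.0, 10.0) == 0.0

    def test_vanishing_vascular_pressure_sentinel(self):
        assert pressure_ratio(5.0, 5.0, 0.0) >= 1e5
        assert pressure_ratio(-5.0, 0.0, 0.0) == 0.0

    def test_wall_strain_endpoints(self):
        assert wall_strain(1.0, 3.4, 0.92) == 0.0
        assert wall_strain(0.5, 3.4, 0.92) == 0.0
        assert wall_strain(3.4, 3.4, 0.92) == pytest.approx(0.92)

    def test_wall_strain_quadratic_root_oracle(self):
        """Inversion matches a brute-force root solve of the quadratic
        constitutive law, including the printed case p_c=3.4, e_c=0.92,
        p̄=2.2 → e_r ≈ 0.2695."""
        from scipy.optimize import brentq
        p_c, e_c = 3.4, 0.92
        for p_bar in (1.2, 1.8, 2.2, 3.0, 3.39):
            def law(e):
                x = e / e_c
                return 1 + (2 * p_c - 2) * x - (p_c - 1) * x * x - p_bar
            e_oracle = brentq(law, 0.0, e_c)
            assert wall_strain(p_bar, p_c, e_c) == pytest.approx(
                e_oracle, rel=1e-10)
        assert wall_strain(2.2, 3.4, 0.92) == pytest.approx(0.2695,
                                                            abs=2e-4)

    def test_stiffness_pressure_mapping_baseline(self):
        """E_w-max = 2(p_c−1)/e_c reproduces the printed bounds both ways
        to 3 significant figures."""
        assert stiffness_from_pc(1.6, 0.92) == pytest.approx(1.30,
                                                             abs=0.005)
        assert stiffness_from_pc(3.4, 0.92) == pytest.approx(5.22,
                                                             abs=0.005)
        assert pc_from_stiffness(1.30, 0.92) == pytest.approx(1.6,
                                                              abs=0.0025)
        assert pc_from_stiffness(5.22, 0.92) == pytest.approx(3.4,
                                                              abs=0.0025)


def _stepper(mesh, **taxis_kw):
    taxis = TaxisParams(**taxis_kw)
    return VesselStepper(mesh, taxis, TipKineticsParams(),
                         BranchingParams(), RemodellingParams(),
                         CollapseParams())


class TestCompressionAndCollapse:
    def _line_network(self, tumour_mesh, n=8):
        x = np.linspace(0.5, 4.5, n)
        pos = np.column_stack([x, np.full(n, 2.5), np.full(n, 2.5)])
        net = make_network(pos, [[i, i + 1] for i in range(n - 1)])
        net.is_inlet[0] = True
        net.is_outlet[-1] = True
        net.rehost(tumour_mesh)
        return net

    def test_no_change_below_unity_ratio(self, tumour_mesh):
        net = self._line_network(tumour_mesh)
        stepper = _stepper(tumour_mesh)
        R0 = net.radius_um.copy()
        n = net.n_nodes
        stepper.apply_compression_and_collapse(
            net, np.full(n, 2.0), np.full(n, 2.0), np.full(n, 10.0),
            0.0, np.zeros(n), StepEvents())
        assert np.allclose(net.radius_um, R0)
        assert not (net.state == STATE_COLLAPSED).any()

    def test_compression_reduces_radius_reversibly(self, tumour_mesh):
        net = self._line_network(tumour_mesh)
        stepper = _stepper(tumour_mesh)
        n = net.n_nodes
        p_int = np.full(n, 10.0)
        thp = np.full(n, 10.0)
        pv = np.full(n, 10.0)  # p̄ = 2 < p_c(parents) = 3.4
        ev = StepEvents()
        stepper.apply_compression_and_collapse(net, p_int, thp, pv, 0.0,
                                               np.zeros(n), ev)
        assert np.all(net.state == STATE_COMPRESSED)
        assert np.all(net.radius_um < net.radius_base_um)
        # relax the load: radii recover (elastic compression)
        stepper.apply_compression_and_collapse(
            net, np.zeros(n), np.zeros(n), pv, 0.0, np.zeros(n),
            StepEvents())
        assert np.allclose(net.radius_um, net.radius_base_um)

    def test_mid_vessel_collapse_prunes_distal_run(self, tumour_mesh):
        """Collapse of one mid-vessel node on a line whose far end is a
        dead end collapses the whole distal run."""
        net = self._line_network(tumour_mesh)
        net.is_outlet[-1] = False  # make the far end a dead end
        stepper = _stepper(tumour_mesh)
        n = net.n_nodes
        p_int = np.zeros(n)
        thp = np.zeros(n)
        thp[3] = 60.0  # only node 3 exceeds p_c
        pv = np.full(n, 10.0)
        ev = StepEvents()
        stepper.apply_compression_and_collapse(net, p_int, thp, pv, 0.0,
                                               np.zeros(n), ev)
        assert (net.state[3] == STATE_COLLAPSED)
        assert np.all(net.state[4:] == STATE_COLLAPSED)  # distal run dead
        assert np.all(net.state[:3] != STATE_COLLAPSED)  # inlet side lives

    def test_anastomosis_rescues_distal_run(self, tumour_mesh):
        """The same topology with a second path to the outlet keeps the
        distal run functional."""
        net = self._line_network(tumour_mesh)
        net.is_outlet[-1] = False
        # bypass: connect node 5 back to the inlet-side node 1
        net.add_segments([[5, 1]], np.linalg.norm(net.pos[5] - net.pos[1]))
        stepper = _stepper(tumour_mesh)
        n = net.n_nodes
        thp = np.zeros(n)
        thp[3] = 60.0
        ev = StepEvents()
        stepper.apply_compression_and_collapse(
            net, np.zeros(n), thp, np.full(n, 10.0), 0.0, np.zeros(n), ev)
        assert net.state[3] == STATE_COLLAPSED
        assert np.all(net.state[4:6] != STATE_COLLAPSED)

    def test_collapsed_radius_scaled_down_by_1000(self, tumour_mesh):
        net = self._line_network(tumour_mesh)
        stepper = _stepper(tumour_mesh)
        n = net.n_nodes
        thp = np.full(n, 100.0)
        stepper.apply_compression_and_collapse(
            net, np.zeros(n), thp, np.full(n, 10.0), 0.0, np.zeros(n),
            StepEvents())
        assert np.all(net.state == STATE_COLLAPSED)
        assert np.allclose(net.radius_um, net.radius_base_um / 1e3)


class TestAnastomosis:
    def _tip_near_line(self, tumour_mesh, gap_um):
        pos = [[1.0, 2.5, 2.5], [2.0, 2.5, 2.5], [3.0, 2.5, 2.5],
               # second vessel ending in a tip near node 1
               [2.0, 3.5, 2.5], [2.0, 2.5 + gap_um / 1000.0, 2.5]]
        net = make_network(pos, [[0, 1], [1, 2], [3, 4]])
        net.is_inlet[0] = True
        net.is_outlet[2] = True
        net.is_tip[4] = True
        net.direction[4] = [0, -1, 0]
        net.rehost(tumour_mesh)
        return net

    def test_within_capture_distance_connects(self, tumour_mesh):
        net = self._tip_near_line(tumour_mesh, 39.0)
        stepper = _stepper(tumour_mesh)
        made = stepper.try_anastomose(net, StepEvents())
        assert made == 1
        assert not net.is_tip[4]
        assert net.n_segments == 4

    def test_outside_capture_distance_no_op(self, tumour_mesh):
        net = self._tip_near_line(tumour_mesh, 41.0)
        stepper = _stepper(tumour_mesh)
        assert stepper.try_anastomose(net, StepEvents()) == 0
        assert net.is_tip[4]

    def test_own_parent_excluded(self, tumour_mesh):
        # tip 30 μm from its own parent node: no self-anastomosis
        pos = [[1.0, 2.5, 2.5], [2.0, 2.5, 2.5], [2.0, 2.53, 2.5]]
        net = make_network(pos, [[0, 1], [1, 2]])
        net.is_inlet[0] = True
        net.is_tip[2] = True
        net.rehost(tumour_mesh)
        stepper = _stepper(tumour_mesh)
        assert stepper.try_anastomose(net, StepEvents()) == 0


class TestBranchAngle:
    def test_rotated_away_from_parent(self):
        parent = np.array([1.0, 0.0, 0.0])
        e = np.array([0.999, 0.04, 0.0])
        e /= np.linalg.norm(e)
        out = _enforce_min_angle(e, parent, np.deg2rad(30))
        ang = np.degrees(np.arccos(np.clip(np.dot(out, parent), -1, 1)))
        assert ang == pytest.approx(30.0, abs=1e-9)
        assert np.isclose(np.linalg.norm(out), 1.0)

    def test_wide_angles_untouched(self):
        parent = np.array([1.0, 0.0, 0.0])
        e = np.array([0.0, 1.0, 0.0])
        out = _enforce_min_angle(e, parent, np.deg2rad(30))
        assert np.allclose(out, e)

    def test_parallel_direction_resolved_deterministically(self):
        parent = np.array([1.0, 0.0, 0.0])
        out1 = _enforce_min_angle(parent.copy(), parent, np.deg2rad(30))
        out2 = _enforce_min_angle(parent.copy(), parent, np.deg2rad(30))
        assert np.allclose(out1, out2)
        ang = np.degrees(np.arccos(np.clip(np.dot(out1, parent), -1, 1)))
        assert ang == pytest.approx(30.0, abs=1e-9)
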