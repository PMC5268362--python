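import numpy as np
import pytest

from mechangio import metrics as mt
from mechangio.flow import FlowSolution
from mechangio.network import STATE_COLLAPSED
from conftest import make_network


def fake_flow(net, velocities):
    m = net.n_segments
    z = np.zeros(net.n_nodes)
    return FlowSolution(
        p_vsc=np.zeros(net.n_nodes), p_int=np.empty(0),
        seg_flow=np.zeros(m), seg_velocity=np.asarray(velocities, float),
        seg_wss=np.zeros(m), node_velocity=z, node_wss=z,
        node_transvascular=z, edge_velocity=np.empty(0),
        edges=np.empty((0, 2), int), p_int_at_vnodes=z)


class TestVascularDensity:
    def test_hand_built_three_segment_sum(self):
        pos = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 2]]
        net = make_network(pos, [[0, 1], [1, 2], [2, 3]])
        net.radius_um[:] = 20.0
        expect = 2 * np.pi * 0.02 * (1 + 1 + 2)  # Σ 2πR·L
        d = mt.vascular_density(net, region_volume=10.0)
        assert d == pytest.approx(expect / 10.0, rel=1e-12)

    def test_doubling_radius_doubles_density(self):
        pos = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        net = make_network(pos, [[0, 1], [1, 2]])
        d1 = mt.vascular_density(net, region_volume=1.0)
        net.radius_um *= 2
        assert mt.vascular_density(net, region_volume=1.0) == \
            pytest.approx(2 * d1)

    def test_collapsed_segments_excluded(self):
        pos = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        net = make_network(pos, [[0, 1], [1, 2]])
        d_full = mt.vascular_density(net, region_volume=1.0)
        net.state[2] = STATE_COLLAPSED
        assert mt.vascular_density(net, region_volume=1.0) < d_full


class TestIntercapillaryDistance:
    def test_parallel_lines(self):
        pos = [[0, 0, 0], [2, 0, 0], [0, 0.6, 0], [2, 0.6, 0]]
        net = make_network(pos, [[0, 1], [2, 3]])
        assert mt.intercapillary_distance(net, sample_spacing=0.02) == \
            pytest.approx(0.6, abs=1e-9)

    def test_single_vessel_undefined(self):
        net = make_network([[0, 0, 0], [1, 0, 0]], [[0, 1]])
        assert np.isnan(mt.intercapillary_distance(net))

    def test_matches_brute_force_on_random_vessels(self):
        rng = np.random.default_rng(2)
        pts = []
        segs = []
        chains = []
        for v in range(5):
            a = rng.uniform(0, 3, 3)
            b = rng.uniform(0, 3, 3)
            pts += [a, b]
            segs.append([2 * v, 2 * v + 1])
            chains.append(v)
        net = make_network(pts, segs)
        spacing = 0.05
        d = mt.nearest = None
        from mechangio.network import nearest_other_vessel_distances
        d = nearest_other_vessel_distances(net, sample_spacing=spacing)
        # brute force with the same sampling
        samples, labels = [], []
        for v, (i, j) in enumerate(segs):
            seg = net.pos[j] - net.pos[i]
            L = np.linalg.norm(seg)
            k = max(2, int(np.ceil(L / spacing)) + 1)
            for t in np.linspace(0, 1, k):
                samples.append(net.pos[i] + t * seg)
                labels.append(v)
        samples = np.asarray(samples)
        labels = np.asarray(labels)
        brute = []
        for i, p in enumerate(samples):
            dd = np.linalg.norm(samples - p, axis=1)
            dd[labels == labels[i]] = np.inf
            brute.append(dd.min())
        assert np.allclose(np.sort(d), np.sort(brute), atol=1e-12)


class TestDistanceMap:
    def test_voxel_on_vessel_is_zero(self):
        net = make_network([[0, 0.5, 0.5], [1, 0.5, 0.5]], [[0, 1]])
        dm = mt.distance_map(net, [0, 0, 0], [1, 1, 1], voxel=0.1)
        assert dm.valid
        assert dm.delta.min() == 0.0

    def test_empty_network_flagged_invalid(self):
        net = make_network([[0, 0, 0], [1, 0, 0]], [[0, 1]])
        net.state[:] = STATE_COLLAPSED
        dm = mt.distance_map(net, [0, 0, 0], [1, 1, 1], voxel=0.25)
        assert not dm.valid

    def test_single_vessel_matches_point_to_line_distance(self):
        net = make_network([[0, 1.0, 1.0], [2.0, 1.0, 1.0]], [[0, 1]])
        voxel = 0.05
        dm = mt.distance_map(net, [0, 0, 0], [2, 2, 2], voxel=voxel)
        nx, ny, nz = dm.delta.shape
        ax = dm.origin[0] + (np.arange(nx) + 0.5) * voxel
        ay = dm.origin[1] + (np.arange(ny) + 0.5) * voxel
        az = dm.origin[2] + (np.arange(nz) + 0.5) * voxel
        Y, Z = np.meshgrid(ay, az, indexing="ij")
        analytic = np.sqrt((Y - 1.0) ** 2 + (Z - 1.0) ** 2)
        diag = voxel * np.sqrt(3)
        # compare at a mid-x slice (away from the ends)
        err = np.abs(dm.delta[nx // 2] - analytic)
        assert err.max() <= diag + 1e-12


class TestScalingParameters:
    def test_exponential_distance_distribution_recovered(self):
        """λ_v recovery within 10% on synthetic exponential distances."""
        rng = np.random.default_rng(0)
        lam_true = 0.3
        vals = rng.exponential(lam_true, size=200000)
        dm = mt.DistanceMap(delta=vals.reshape(100, 100, 20), voxel=0.03,
                            origin=np.zeros(3), valid=True)
        lam, dmax = mt.scaling_parameters(dm)
        assert lam == pytest.approx(lam_true, rel=0.1)
        assert dmax == vals.max()

    def test_avascular_pocket_raises_delta_max(self):
        net1 = make_network([[0, 1, 1], [4, 1, 1], [0, 3, 1], [4, 3, 1]],
                            [[0, 1], [2, 3]])
        dm1 = mt.distance_map(net1, [0, 0, 0], [4, 4, 2], voxel=0.1)
        net2 = make_network([[0, 1, 1], [4, 1, 1]], [[0, 1]])
        dm2 = mt.distance_map(net2, [0, 0, 0], [4, 4, 2], voxel=0.1)
        _, dmax1 = mt.scaling_parameters(dm1)
        _, dmax2 = mt.scaling_parameters(dm2)
        assert dmax2 > dmax1

    def test_too_few_bins_gives_nan(self):
        dm = mt.DistanceMap(delta=np.full((2, 2, 2), 0.5), voxel=0.1,
                            origin=np.zeros(3), valid=True)
        lam, _ = mt.scaling_parameters(dm)
        assert np.isnan(lam)


class TestPerfusionClasses:
    def _net3(self):
        pos = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]
        return make_network(pos, [[0, 1], [1, 2], [2, 3]])

    def test_bin_edges(self):
        net = self._net3()
        fl = fake_flow(net, [0.05, 0.3, 0.7])
        out = mt.perfusion_classification(net, fl)
        assert out["count"]["hypo"] == pytest.approx(1 / 3)
        assert out["count"]["perfused"] == pytest.approx(1 / 3)
        assert out["count"]["well"] == pytest.approx(1 / 3)

    def test_exact_threshold_is_perfused(self):
        net = self._net3()
        fl = fake_flow(net, [0.1, 0.5, 0.2])
        out = mt.perfusion_classification(net, fl)
        assert out["count"]["perfused"] == pytest.approx(1.0)
        assert out["count"]["hypo"] == 0.0

    def test_all_collapsed(self):
        net = self._net3()
        net.state[:] = STATE_COLLAPSED
        fl = fake_flow(net, [0.0, 0.0, 0.0])
        out = mt.perfusion_classification(net, fl)
        assert out["count"]["collapsed"] == 1.0

    def test_fractions_sum_to_one(self):
        net = self._net3()
        net.state[3] = STATE_COLLAPSED
        fl = fake_flow(net, [0.05, 0.3, 0.7])
        out = mt.perfusion_classification(net, fl)
        assert sum(out["count"].values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(out["length"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_length_fractions_invariant_to_subdivision(self):
        pos = [[0, 0, 0], [2, 0, 0], [2, 1, 0]]
        net1 = make_network(pos, [[0, 1], [1, 2]])
        fl1 = fake_flow(net1, [0.05, 0.7])
        out1 = mt.perfusion_classification(net1, fl1)
        # subdivide the first segment in two
        pos2 = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]]
        net2 = make_network(pos2, [[0, 1], [1, 2], [2, 3]])
        fl2 = fake_flow(net2, [0.05, 0.05, 0.7])
        out2 = mt.perfusion_classification(net2, fl2)
        for k in ("hypo", "well"):
            assert out1["length"][k] == pytest.approx(out2["length"][k])


class TestHistograms:
    def test_single_bin_and_normalisation(self):
        pos = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        net = make_network(pos, [[0, 1], [1, 2]])
        net.radius_um[:] = 3.0  # diameter 6 μm → first bin
        fl = fake_flow(net, [0.2, 0.4])
        out = mt.histograms(net, fl)
        assert out["bins"][0]["norm_length"] == pytest.approx(1.0)
        total = sum(b["norm_length"] for b in out["bins"])
        assert total == pytest.approx(1.0)

    def test_hand_network_binning(self):
        pos = [[0, 0, 0], [1, 0, 0], [1, 2, 0], [1, 2, 3]]
        net = make_network(pos, [[0, 1], [1, 2], [2, 3]])
        net.radius_um[:] = [4.0, 4.0, 12.0, 12.0]  # D: 8, 16, 24 μm
        fl = fake_flow(net, [0.1, 0.2, 0.3])
        out = mt.histograms(net, fl)
        # lengths 1 (4–10), 2 (10–20), 3 (20–30); total 6
        assert out["bins"][0]["norm_length"] == pytest.approx(1 / 6)
        assert out["bins"][1]["norm_length"] == pytest.approx(2 / 6)
        assert out["bins"][2]["norm_length"] == pytest.approx(3 / 6)

    def test_collapsed_length_ratio(self):
        pos = [[0, 0, 0], [1, 0, 0], [3, 0, 0]]
        net = make_network(pos, [[0, 1], [1, 2]])
        net.state[2] = STATE_COLLAPSED
        fl = fake_flow(net, [0.2, 0.0])
        out = mt.histograms(net, fl)
        assert out["collapsed_length_ratio"] == pytest.approx(2.0)


class TestRadialProfiles:
    def test_constant_field_flat_profile(self, tumour_mesh):
        f = np.full(tumour_mesh.n_nodes, 4.2)
        prof = mt.radial_profiles(f, tumour_mesh)
        assert np.allclose(prof["mean"], 4.2)
        assert np.allclose(prof["sd"], 0.0, atol=1e-12)

    def test_spherically_symmetric_field_low_sd(self, tumour_mesh):
        r = np.linalg.norm(tumour_mesh.nodes - 2.5, axis=1)
        f = np.exp(-r)
        prof = mt.radial_profiles(f, tumour_mesh)
        assert np.nanmax(prof["sd"]) < 0.05 * np.nanmax(prof["mean"])

    def test_identity_profile_for_radius_field(self):
        from mechangio import generate_cube_mesh
        mesh = generate_cube_mesh(5.0, 10, 1.0)  # node at the exact centre
        r = np.linalg.norm(mesh.nodes - 2.5, axis=1)
        prof = mt.radial_profiles(r, mesh, n_radial=25)
        # trilinear interpolation of |r| overestimates by ~h²/(2r) near the
        # centre; compare beyond two elements where that error is a few %
        sel = prof["radius_mm"] >= 1.0
        assert np.allclose(prof["mean"][sel], prof["radius_mm"][sel],
                           rtol=0.05)


class TestTumourVolume:
    def test_reference_volume_without_deformation(self, tumour_mesh):
        v = mt.tumour_volume(tumour_mesh)
        expect = tumour_mesh.element_volumes()[
            tumour_mesh.tumour_elems].sum()
        assert v == pytest.approx(expect)

    def test_uniform_stretch_scales_volume(self, tumour_mesh):
        nel = tumour_mesh.n_elems
        J = np.full((nel, 8), 1.5)
        v = mt.tumour_volume(tumour_mesh, J)
        assert v == pytest.approx(1.5 * mt.tumour_volume(tumour_mesh))
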