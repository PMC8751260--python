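"""Generator contracts: determinism, truth bookkeeping, rendering fidelity."""

import numpy as np
import pytest

from nvuquant import io as nio
from nvuquant import scene_sim as ss
from conftest import render_noiseless, small_network_truth


class TestVesselNetwork:
    def test_same_seed_identical_output(self):
        a = ss.generate_vessel_network((120, 90, 75), seed=3, lattice_shape=(8, 6, 5))
        b = ss.generate_vessel_network((120, 90, 75), seed=3, lattice_shape=(8, 6, 5))
        assert [n.valence for n in a.nodes] == [n.valence for n in b.nodes]
        assert all(
            np.array_equal(x.position, y.position) for x, y in zip(a.nodes, b.nodes)
        )
        assert all(
            np.array_equal(x.polyline, y.polyline) and x.radius == y.radius
            for x, y in zip(a.segments, b.segments)
        )

    def test_low_density_degenerates_to_single_open_tube(self):
        t = ss.generate_vessel_network((60, 40, 10), target_segment_density=5.0, seed=2)
        assert len(t.nodes) == 0
        assert len(t.segments) == 1
        assert t.segments[0].u is None and t.segments[0].v is None
        assert t.connected_component_count == 1

    def test_domain_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            ss.generate_vessel_network((4, 4, 4), target_segment_density=8000.0)

    def test_valence_mix_within_binomial_ci(self):
        # 240-node network at mix 0.5: observed valence-4 fraction inside the
        # 99% binomial interval
        t = ss.generate_vessel_network(
            (120, 90, 75), seed=11, lattice_shape=(8, 6, 5), valence_mix=0.5
        )
        vc = t.valence_counts()
        n34 = vc.get(3, 0) + vc.get(4, 0)
        assert n34 >= 200
        frac = vc.get(4, 0) / n34
        half = 2.576 * np.sqrt(0.25 / n34)
        assert abs(frac - 0.5) <= half

    @pytest.mark.parametrize("seed", [0, 7])
    def test_handshake_identity_on_closed_networks(self, seed):
        # sum over nodes of n * V_n equals twice the internode segment count
        t = ss.generate_vessel_network((120, 90, 75), seed=seed, lattice_shape=(8, 6, 5))
        assert t.open_end_count == 0
        vc = t.valence_counts()
        assert sum(n * c for n, c in vc.items()) == 2 * t.internode_segment_count
        # cyclomatic number from the same bookkeeping
        assert t.cyclomatic_number() == (
            t.internode_segment_count - len(t.nodes) + t.connected_component_count
        )

    def test_node_valence_matches_incident_segments(self):
        t = small_network_truth(5)
        incident = {n.id: 0 for n in t.nodes}
        for s in t.segments:
            for end in (s.u, s.v):
                if end is not None:
                    incident[end] += 1
        for n in t.nodes:
            assert incident[n.id] == n.valence

    def test_polylines_inside_domain_and_radii_positive(self):
        t = small_network_truth(9)
        L = np.array(t.domain_size)
        for s in t.segments:
            assert s.radius > 0
            assert np.all(s.polyline >= 0) and np.all(s.polyline <= L)

    def test_noncapillary_fraction_injects_wide_vessels(self):
        t = ss.generate_vessel_network(
            (120, 90, 75), seed=4, lattice_shape=(8, 6, 5), noncapillary_fraction=0.2
        )
        radii = np.array([s.radius for s in t.segments])
        assert np.any(radii > 5.0) and np.any(radii < 3.0)


class TestPericytes:
    def test_somata_on_wall_and_separated(self):
        t = small_network_truth(1)
        p = ss.generate_pericytes(t, 8, seed=2, min_separation=6.0)
        assert p.total_count == 8
        segs = {s.id: s for s in t.segments}
        for soma in p.somata:
            seg = segs[soma.segment_id]
            # distance from the centerline equals the segment radius (on wall)
            d = min(
                np.linalg.norm(soma.centroid - seg.point_at(f)[0])
                for f in np.linspace(0, 1, 200)
            )
            assert abs(d - seg.radius) < 0.15
        c = p.centroids()
        dist = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 6.0


class TestRenderScene:
    def test_noiseless_halfmax_recovers_tube_mask(self, straight_tube_truth):
        sc = render_noiseless(straight_tube_truth)
        ch = sc.channels["vessel_lectin"]
        m = ch > 0.5 * ch.max()
        truth = sc.vessel_mask_truth
        dice = 2 * (m & truth).sum() / (m.sum() + truth.sum())
        assert dice >= 0.95

    def test_default_z_spacing_is_optical_interval(self, straight_tube_truth):
        sc = ss.render_scene(straight_tube_truth, noise="none")
        assert sc.voxel_spacing[2] == 0.25

    def test_empty_truth_noise_floor_only(self):
        empty = ss.VesselGraphTruth(
            nodes=[], segments=[], domain_size=(20, 20, 10),
            connected_component_count=0,
        )
        quiet = ss.render_scene(empty, noise="none", seed=1)
        assert quiet.channels["vessel_lectin"].max() == 0
        noisy = ss.render_scene(empty, noise="poisson-gaussian", seed=1)
        v = noisy.channels["vessel_lectin"]
        assert v.mean() == pytest.approx(10.0, rel=0.1)  # background floor
        assert v.max() < 60

    def test_out_of_domain_segment_fails_with_id(self):
        seg = ss.TruthSegment(
            7, None, None, np.array([[5.0, 5.0, 5.0], [50.0, 5.0, 5.0]]), 1.5
        )
        t = ss.VesselGraphTruth(
            nodes=[], segments=[seg], domain_size=(20, 20, 10),
            connected_component_count=1,
        )
        with pytest.raises(ValueError, match="segment 7"):
            ss.render_scene(t, noise="none")

    def test_total_aqp4_intensity_monotone_in_coverage(self, straight_tube_truth):
        sums = []
        for cov in (0.2, 0.5, 0.8):
            sc = ss.render_scene(
                straight_tube_truth, None, cov, psf_sigma=0.0, noise="none", seed=3
            )
            sums.append(float(sc.channels["aqp4"].sum()))
        assert sums[0] < sums[1] < sums[2]

    def test_realized_coverage_matches_target(self, straight_tube_truth):
        sc = ss.render_scene(straight_tube_truth, None, 0.6, noise="none", seed=4)
        assert sc.coverage_truth.realized_fraction == pytest.approx(0.6, abs=0.02)


class TestPlaqueSections:
    def test_zero_target_is_blank(self):
        sec = ss.generate_plaque_section((128, 128), 0.0, seed=1)
        assert sec.true_area_fraction == 0.0
        assert not sec.plaque_mask.any()

    def test_target_five_percent_within_half_point(self):
        sec = ss.generate_plaque_section((512, 512), 5.0, seed=2)
        inside = (sec.plaque_mask & sec.roi_mask).sum()
        frac = 100.0 * inside / sec.roi_mask.sum()
        assert sec.true_area_fraction == pytest.approx(frac)
        assert 4.5 <= frac <= 5.5

    def test_seeds_give_different_layouts_same_target(self):
        a = ss.generate_plaque_section((256, 256), 5.0, seed=1)
        b = ss.generate_plaque_section((256, 256), 5.0, seed=2)
        assert not np.array_equal(a.plaque_mask, b.plaque_mask)
        for sec in (a, b):
            assert abs(sec.true_area_fraction - 5.0) <= 0.5

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            ss.generate_plaque_section((64, 64), 101.0)


class TestSerialization:
    def test_truth_round_trip_lossless(self):
        t = small_network_truth(3)
        p = ss.generate_pericytes(t, 5, seed=1)
        c = ss.CoverageTruth(0.6, 0.59, 0.5)
        payload = nio.truth_to_dict(t, p, c)
        t2, p2, c2 = nio.truth_from_dict(payload)
        assert len(t2.nodes) == len(t.nodes)
        for a, b in zip(t.nodes, t2.nodes):
            assert a.valence == b.valence and np.array_equal(a.position, b.position)
        for a, b in zip(t.segments, t2.segments):
            assert np.array_equal(a.polyline, b.polyline) and a.radius == b.radius
        assert p2.total_count == p.total_count
        assert np.array_equal(p2.centroids(), p.centroids())
        assert (c2.coverage_fraction, c2.realized_fraction) == (0.6, 0.59)

    def test_rle_round_trip(self):
        rng = np.random.default_rng(0)
        for shape in [(5, 7), (16, 16), (3, 4, 5)]:
            m = rng.random(shape) < 0.3
            assert np.array_equal(nio.rle_decode(nio.rle_encode(m)), m)
        assert np.array_equal(
            nio.rle_decode(nio.rle_encode(np.ones((4, 4), bool))), np.ones((4, 4), bool)
        )

    def test_scene_save_load(self, tmp_path, straight_tube_truth):
        sc = ss.render_scene(straight_tube_truth, noise="poisson-gaussian", seed=5)
        nio.save_scene(sc, tmp_path, stem="t")
        back = nio.load_scene(tmp_path, stem="t")
        for name in sc.channels:
            assert np.allclose(back.channels[name], sc.channels[name])
        assert back.voxel_spacing == sc.voxel_spacing
        assert len(back.truth.segments) == 1

    def test_plaque_save_load(self, tmp_path):
        sec = ss.generate_plaque_section((128, 128), 3.0, seed=4)
        nio.save_plaque_section(sec, tmp_path)
        back = nio.load_plaque_section(tmp_path)
        assert np.array_equal(back.plaque_mask, sec.plaque_mask)
        assert np.array_equal(back.roi_mask, sec.roi_mask)
        assert back.true_area_fraction == sec.true_area_fraction
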