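"""Vessel segmentation, skeleton-graph extraction, diameters, classification."""

import numpy as np
import pytest

from nvuquant import scene_sim as ss
from nvuquant import vesselgraph as vg
from conftest import render_noiseless, small_network_truth


def extract(scene, method="halfmax", fuse=4.0):
    mask = vg.segment_vessels(
        scene.channels["vessel_lectin"], scene.voxel_spacing, method=method
    )
    return vg.skeletonize_to_graph(mask, junction_fuse_length=fuse), mask


class TestSegmentVessels:
    def test_noiseless_tube_dice(self, straight_tube_truth):
        sc = render_noiseless(straight_tube_truth)
        m = vg.segment_vessels(
            sc.channels["vessel_lectin"], sc.voxel_spacing, method="halfmax"
        )
        truth = sc.vessel_mask_truth
        dice = 2 * (m.mask & truth).sum() / (m.mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_all_zero_stack_warns_empty(self):
        with pytest.warns(UserWarning, match="all-zero"):
            m = vg.segment_vessels(np.zeros((4, 5, 6)), (0.5, 0.5, 0.25))
        assert m.is_empty

    def test_threshold_above_max_gives_empty(self):
        img = np.full((4, 5, 6), 3.0)
        m = vg.segment_vessels(img, (0.5, 0.5, 0.25), method="fixed", threshold=10.0)
        assert m.is_empty

    def test_keep_largest_component(self):
        img = np.zeros((3, 10, 10))
        img[1, 1:3, 1:6] = 100.0  # large blob
        img[1, 7:8, 7:8] = 100.0  # speck
        m = vg.segment_vessels(
            img, (1, 1, 1), method="fixed", threshold=50.0, keep_largest=True
        )
        assert m.mask.sum() == 10


class TestSkeletonGraph:
    def test_straight_tube_is_one_open_segment(self, straight_tube_truth):
        g, _ = extract(render_noiseless(straight_tube_truth))
        assert len(g.nodes) == 0
        assert len(g.segments) == 1
        assert g.open_end_count == 2

    def test_y_junction_single_valence3_node(self, y_junction_truth):
        g, _ = extract(render_noiseless(y_junction_truth))
        assert len(g.nodes) == 1
        assert next(iter(g.nodes.values())).valence == 3
        assert len(g.segments) == 3
        assert g.open_end_count == 3

    def test_square_loop_four_valence3_nodes(self, square_loop_truth):
        g, _ = extract(render_noiseless(square_loop_truth))
        assert len(g.nodes) == 4
        assert sorted(n.valence for n in g.nodes.values()) == [3, 3, 3, 3]
        assert g.handshake_residual() == 0

    def test_empty_mask_gives_empty_graph(self):
        g = vg.skeletonize_to_graph(
            vg.VesselMask(np.zeros((4, 5, 6), bool), (0.5, 0.5, 0.25))
        )
        assert not g.nodes and not g.segments

    @pytest.mark.parametrize("seed", [0, 4, 12])
    def test_noiseless_network_recovery_exact(self, seed):
        truth = small_network_truth(seed)
        sc = render_noiseless(truth, spacing=(0.5, 0.5, 0.25))
        g, _ = extract(sc)
        got = {}
        for n in g.nodes.values():
            got[n.valence] = got.get(n.valence, 0) + 1
        assert got == truth.valence_counts()
        assert len(g.segments) == len(truth.segments)
        assert g.open_end_count == 0
        assert g.handshake_residual() == 0

    @pytest.mark.parametrize("seed", [1, 6, 9])
    def test_noisy_network_recovery_within_ten_percent(self, seed):
        truth = small_network_truth(seed)
        sc = ss.render_scene(truth, psf_sigma=0.3, noise="poisson-gaussian", seed=seed)
        g, _ = extract(sc, method="otsu")
        assert len(g.nodes) == pytest.approx(len(truth.nodes), rel=0.10)
        assert g.handshake_residual() == 0


class TestDiameters:
    def test_tube_radius_two_gives_diameter_four(self, straight_tube_truth):
        sc = render_noiseless(straight_tube_truth)
        g, m = extract(sc)
        vg.estimate_diameters(g, m)
        # within one voxel-equivalent of the true 4 um diameter
        assert g.segments[0].mean_diameter == pytest.approx(4.0, abs=0.5)

    def test_wide_vessel_crosses_capillary_cutoff(self):
        poly = np.array([[8.0, 16.0, 10.0], [56.0, 16.0, 10.0]])
        seg = ss.TruthSegment(0, None, None, poly, 6.0)
        t = ss.VesselGraphTruth(
            nodes=[], segments=[seg], domain_size=(64, 32, 20),
            connected_component_count=1,
        )
        sc = render_noiseless(t)
        g, m = extract(sc)
        vg.estimate_diameters(g, m)
        assert g.segments[0].mean_diameter > 10.0
        vg.classify_capillaries(g)
        assert not g.segments[0].is_capillary

    def test_inconsistent_graph_and_mask_fail(self, straight_tube_truth):
        sc = render_noiseless(straight_tube_truth)
        g, m = extract(sc)
        empty = vg.VesselMask(np.zeros_like(m.mask), m.voxel_spacing)
        with pytest.raises(ValueError, match="outside the vessel mask"):
            vg.estimate_diameters(g, empty)


def toy_one_node_graph(wide_diameter: float) -> vg.VesselGraph:
    """Valence-3 node with two thin arms and one arm of the given diameter."""
    c = np.array([10.0, 10.0, 5.0])
    segs = []
    for i, end in enumerate(
        [np.array([20.0, 10.0, 5.0]), np.array([0.0, 10.0, 5.0]),
         np.array([10.0, 20.0, 5.0])]
    ):
        s = vg.GraphSegment(i, 0, None, np.vstack([c, end]))
        s.mean_diameter = 4.0 if i < 2 else wide_diameter
        segs.append(s)
    g = vg.VesselGraph({0: vg.GraphNode(0, c, 3)}, segs, (0.5, 0.5, 0.5))
    g.recompute_valences()
    return g


class TestClassification:
    def test_all_capillary_leaves_valences_unchanged(self):
        g = toy_one_node_graph(6.0)
        vg.classify_capillaries(g)
        assert g.nodes[0].capillary_valence == 3
        assert not g.dissolved_nodes

    def test_wide_segment_dissolves_node_to_pass_through(self):
        g = toy_one_node_graph(12.0)
        vg.classify_capillaries(g)
        assert g.nodes[0].capillary_valence == 2
        assert g.dissolved_nodes == [0]
        # the two remaining capillary arms now count as one merged segment
        assert g.capillary_segment_count() == 1

    def test_zero_cutoff_means_zero_capillaries(self):
        g = toy_one_node_graph(6.0)
        vg.classify_capillaries(g, max_diameter=0.0)
        assert all(not s.is_capillary for s in g.segments)

    def test_raising_cutoff_never_decreases_capillary_count(self):
        g = toy_one_node_graph(12.0)
        counts = []
        for cutoff in (0.0, 4.0, 10.0, 12.0, 20.0):
            vg.classify_capillaries(g, max_diameter=cutoff)
            counts.append(g.capillary_segment_count())
        assert counts == sorted(counts)


class TestTallies:
    def test_whole_volume_tally_matches_truth(self):
        t = small_network_truth(2)
        tally = vg.tally_valences(t)
        assert tally.counts == {
            3: t.valence_counts().get(3, 0),
            4: t.valence_counts().get(4, 0),
        }

    def test_empty_region_zero_counts(self):
        from nvuquant.stereology import DisectorFrame

        t = small_network_truth(2)
        frame = DisectorFrame(origin=(200.0, 200.0, 0.0), size=(5.0, 5.0, 5.0))
        tally = vg.tally_valences(t, frame)
        assert tally.counts == {3: 0, 4: 0}

    def test_half_domain_tally_within_binomial_ci(self):
        from nvuquant.stereology import DisectorFrame

        t = ss.generate_vessel_network(
            (120, 90, 75), seed=21, lattice_shape=(8, 6, 5), jitter=1.0
        )
        frame = DisectorFrame(origin=(0.0, 0.0, 0.0), size=(60.0, 90.0, 75.0))
        tally = vg.tally_valences(t, frame)
        for n, total in t.valence_counts().items():
            if n not in (3, 4):
                continue
            half = 2.576 * np.sqrt(total * 0.25)
            assert abs(tally.counts[n] - total / 2) <= half

    def test_high_valence_decomposition_preserves_cyclomatic_identity(self):
        from nvuquant.stereology import capillary_count_eq1

        # one 5-valent node fused with a 3-valent neighbor: E=7, V=5 ring-ish
        # construct directly: tally {3:4, 5:1} ~ graph with Sum(n-2)/2 = 3.5
        tally = vg.ValenceTally(counts={3: 4, 4: 0})
        base = capillary_count_eq1(tally)

        class FakeNode:
            def __init__(self, val):
                self.position = np.zeros(3)
                self.valence = val

        class FakeTruth:
            nodes = [FakeNode(3)] * 4 + [FakeNode(5)]
            open_end_count = 0

        got = vg.tally_valences(FakeTruth())
        # the 5-valent node contributes (5-2)/2 = 1.5, i.e. three virtual
        # valence-3 nodes
        assert capillary_count_eq1(got) == base + 1.5

    def test_open_ends_excluded_but_reported(self, y_junction_truth):
        sc = render_noiseless(y_junction_truth)
        g, _ = extract(sc)
        tally = vg.tally_valences(g)
        assert tally.counts == {3: 1, 4: 0}
        assert tally.open_end_count == 3
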