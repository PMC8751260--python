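"""Disector placement, the node-valence capillary count, fractionator scaling."""

import numpy as np
import pytest

from nvuquant import scene_sim as ss
from nvuquant import stereology as st


def design(**kw):
    base = dict(
        ssf=1.0,
        frame_size=(20.0, 10.0),
        a_step=800.0,
        thickness=10.0,
        disector_height=8.0,
        frames_per_section=5,
        sections_per_subject=2,
        step=(40.0, 20.0),
    )
    base.update(kw)
    return st.SamplingDesign(**base)


class TestSamplingDesign:
    def test_fractions_derived(self):
        d = design()
        assert d.a_frame == 200.0
        assert d.asf == pytest.approx(0.25)
        assert d.tsf == pytest.approx(0.8)

    def test_reference_constants(self):
        d = st.SamplingDesign()
        assert d.ssf == pytest.approx(1.0 / 53.5)
        # exact product of the frame dimensions (the conventionally quoted
        # area, 16052.65 um^2, is rounded)
        assert d.a_frame == pytest.approx(143.95 * 111.52)
        assert d.a_frame == pytest.approx(16052.65, abs=1.0)
        assert d.thickness == 25.0

    def test_invalid_height_rejected(self):
        with pytest.raises(ValueError):
            design(disector_height=12.0)

    def test_frame_larger_than_step_rejected(self):
        with pytest.raises(ValueError):
            design(a_step=100.0, step=None)


class TestPlaceDisectors:
    def test_two_sections_of_five_gives_ten_frames(self):
        d = design()
        frames = []
        rng = np.random.default_rng(0)
        for _ in range(d.sections_per_subject):
            frames.extend(st.place_disectors((220.0, 40.0), d, rng))
        assert len(frames) == 10

    def test_same_seed_identical_placement(self):
        d = design()
        a = st.place_disectors((220.0, 40.0), d, 5)
        b = st.place_disectors((220.0, 40.0), d, 5)
        assert [f.origin for f in a] == [f.origin for f in b]

    def test_region_smaller_than_frame_fails(self):
        with pytest.raises(ValueError, match="smaller than the counting frame"):
            st.place_disectors((15.0, 8.0), design(), 0)

    def test_uniform_points_sampled_at_asf_times_tsf(self):
        # geometric probability oracle: over many SUR placements, the mean
        # fraction of uniform points falling inside frames approaches
        # asf * tsf; points stay one frame-extent away from far edges
        d = design(frames_per_section=100)
        rng = np.random.default_rng(42)
        region = (220.0, 40.0)
        pts = np.column_stack(
            [
                rng.uniform(20.0, 200.0, 4000),
                rng.uniform(10.0, 30.0, 4000),
                rng.uniform(0.0, d.thickness, 4000),
            ]
        )
        fracs = []
        for s in range(150):
            frames = st.place_disectors(region, d, s)
            hit = np.zeros(len(pts), dtype=bool)
            for f in frames:
                hit |= f.contains(pts)
            fracs.append(hit.mean())
        expected = d.asf * d.tsf
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert np.mean(fracs) == pytest.approx(expected, abs=max(3 * se, 0.004))


class TestCapillaryCountEq1:
    @pytest.mark.parametrize(
        "tally,expected",
        [({3: 2, 4: 0}, 2.0), ({3: 0, 4: 0}, 1.0), ({3: 2, 4: 1}, 3.0)],
    )
    def test_direct_values(self, tally, expected):
        assert st.capillary_count_eq1(tally) == expected

    def test_three_node_closed_graph_matches_cyclomatic(self):
        # degrees (3, 3, 4): E = (3+3+4)/2 = 5, cyclomatic = 5 - 3 + 1 = 3
        assert st.capillary_count_eq1({3: 2, 4: 1}) == 5 - 3 + 1

    def test_per_valence_variant(self):
        assert st.capillary_count_eq1({3: 2, 4: 1}, plus_one="per_valence") == 4.0
        assert st.capillary_count_eq1({3: 0, 4: 0}, plus_one="per_valence") == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            st.capillary_count_eq1({3: -1})

    @pytest.mark.parametrize("seed", range(25))
    def test_identity_with_cyclomatic_number_random_networks(self, seed):
        g = ss.random_closed_multigraph(20 + 7 * seed, valence_mix=0.4, seed=seed)
        tally = {}
        for _, d in g.degree():
            tally[d] = tally.get(d, 0) + 1
        assert set(tally) <= {3, 4}
        cyclomatic = g.number_of_edges() - g.number_of_nodes() + 1
        assert st.capillary_count_eq1(tally) == cyclomatic


class TestFractionatorTotals:
    def test_reference_arithmetic(self):
        d = st.SamplingDesign(
            ssf=1.0 / 53.5, frame_size=(20.0, 10.0), a_step=400.0,
            thickness=10.0, disector_height=5.0, step=(20.0, 20.0),
        )
        results = [st.DisectorResult(frame=None, n_cap=4.0)]
        est = st.estimate_total_capillaries(results, d)
        assert est.estimate == pytest.approx(4 * 53.5 * 2 * 2)

    def test_all_fractions_one_is_identity(self):
        d = st.SamplingDesign(
            ssf=1.0, frame_size=(20.0, 20.0), a_step=400.0,
            thickness=10.0, disector_height=10.0,
        )
        results = [st.DisectorResult(frame=None, n_cap=v) for v in (1.0, 2.5, 3.0)]
        assert st.estimate_total_capillaries(results, d).estimate == pytest.approx(6.5)

    def test_pericyte_totals(self):
        d = st.SamplingDesign(
            ssf=0.1, frame_size=(10.0, 10.0), a_step=1000.0,
            thickness=10.0, disector_height=1.0, step=(100.0, 10.0),
        )
        zero = [st.DisectorResult(frame=None, q=0)]
        assert st.estimate_total_pericytes(zero, d).estimate == 0.0
        ten = [st.DisectorResult(frame=None, q=10)]
        assert st.estimate_total_pericytes(ten, d).estimate == pytest.approx(10000.0)

    def test_missing_counts_rejected(self):
        d = design()
        with pytest.raises(ValueError):
            st.estimate_total_capillaries([st.DisectorResult(frame=None)], d)

    def test_scale_equivariance_of_reparameterization(self):
        # doubling frames per section with halved A_step doubles asf; on a
        # uniform specimen each frame still sees the same expected count, and
        # the scaled total is unchanged
        d1 = design(frames_per_section=5, a_step=800.0, step=(40.0, 20.0))
        d2 = design(frames_per_section=10, a_step=400.0, step=(20.0, 20.0))
        counts1 = [2.0] * 5
        counts2 = [2.0] * 10  # twice the frames, same per-frame expectation
        e1 = st.estimate_total_capillaries(
            [st.DisectorResult(frame=None, n_cap=c) for c in counts1], d1
        )
        e2 = st.estimate_total_capillaries(
            [st.DisectorResult(frame=None, n_cap=c) for c in counts2], d2
        )
        assert e1.estimate == pytest.approx(e2.estimate)


class TestFrameCounting:
    frame = st.DisectorFrame(origin=(10.0, 10.0, 0.0), size=(10.0, 10.0, 8.0))

    def test_no_detections_zero(self):
        assert st.count_pericytes_in_frame(self.frame, []) == 0

    def test_exclusion_faces_reject_inclusion_faces_accept(self):
        on_left = np.array([[10.0, 15.0, 4.0]])  # -x face: excluded
        on_right = np.array([[20.0, 15.0, 4.0]])  # +x face: included
        on_bottom = np.array([[15.0, 10.0, 4.0]])  # -y face: excluded
        on_top = np.array([[15.0, 20.0, 4.0]])  # +y face: included
        assert st.count_pericytes_in_frame(self.frame, on_left) == 0
        assert st.count_pericytes_in_frame(self.frame, on_bottom) == 0
        assert st.count_pericytes_in_frame(self.frame, on_right) == 1
        assert st.count_pericytes_in_frame(self.frame, on_top) == 1

    def test_shared_face_counted_exactly_once(self):
        left = st.DisectorFrame(origin=(0.0, 10.0, 0.0), size=(10.0, 10.0, 8.0))
        pt = np.array([[10.0, 15.0, 4.0]])  # on the face shared by both frames
        total = st.count_pericytes_in_frame(left, pt) + st.count_pericytes_in_frame(
            self.frame, pt
        )
        assert total == 1


class TestPericytesPerCapillary:
    def _est(self, value):
        d = design()
        return st.TotalEstimate("x", value, [value], d)

    def test_equal_totals_ratio_one(self):
        assert st.pericytes_per_capillary(self._est(5.0), self._est(5.0)) == 1.0

    def test_reference_ratio(self):
        assert st.pericytes_per_capillary(self._est(856.0), self._est(428.0)) == 2.0

    def test_zero_capillaries_is_error(self):
        with pytest.raises(ZeroDivisionError):
            st.pericytes_per_capillary(self._est(5.0), self._est(0.0))
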