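"""Shared synthetic fixtures: canonical shapes with known network topology."""

from __future__ import annotations

import numpy as np
import pytest

from nvuquant import scene_sim as ss


def render_noiseless(truth, spacing=(0.25, 0.25, 0.25)):
    return ss.render_scene(truth, psf_sigma=0.0, noise="none", voxel_spacing=spacing)


@pytest.fixture(scope="session")
def straight_tube_truth():
    """One open tube, radius 2 um, along x: 0 nodes, 1 segment."""
    poly = np.array([[4.0, 10.0, 6.0], [36.0, 10.0, 6.0]])
    seg = ss.TruthSegment(0, None, None, poly, 2.0)
    return ss.VesselGraphTruth(
        nodes=[], segments=[seg], domain_size=(40.0, 20.0, 12.0),
        connected_component_count=1,
    )


@pytest.fixture(scope="session")
def y_junction_truth():
    """One valence-3 node with three open arms."""
    c = np.array([20.0, 20.0, 6.0])
    segs = []
    for i, (dx, dy) in enumerate([(1, 0), (-0.7, 0.7), (-0.7, -0.7)]):
        d = np.array([dx, dy, 0.0]) / np.hypot(dx, dy)
        segs.append(ss.TruthSegment(i, 0, None, np.vstack([c, c + 14 * d]), 1.5))
    return ss.VesselGraphTruth(
        nodes=[ss.TruthNode(0, c, 3)], segments=segs,
        domain_size=(40.0, 40.0, 12.0), connected_component_count=1,
    )


@pytest.fixture(scope="session")
def square_loop_truth():
    """Closed square loop with four valence-3 nodes (each with an open spoke)."""
    pts = {0: (14.0, 14.0), 1: (26.0, 14.0), 2: (26.0, 26.0), 3: (14.0, 26.0)}
    segs, sid = [], 0
    for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        pa = np.array([*pts[a], 6.0])
        pb = np.array([*pts[b], 6.0])
        segs.append(ss.TruthSegment(sid, a, b, np.vstack([pa, pb]), 1.5))
        sid += 1
    center = np.array([20.0, 20.0])
    for a in range(4):
        pa = np.array([*pts[a], 6.0])
        out = (pa[:2] - center) / np.linalg.norm(pa[:2] - center)
        end = np.array([*(pa[:2] + 8 * out), 6.0])
        segs.append(ss.TruthSegment(sid, a, None, np.vstack([pa, end]), 1.5))
        sid += 1
    nodes = [ss.TruthNode(i, np.array([*pts[i], 6.0]), 3) for i in range(4)]
    return ss.VesselGraphTruth(
        nodes=nodes, segments=segs, domain_size=(40.0, 40.0, 12.0),
        connected_component_count=1,
    )


def small_network_truth(seed: int) -> ss.VesselGraphTruth:
    """A resolvable closed 18-node network sized for fast rendering."""
    return ss.generate_vessel_network(
        (48.0, 48.0, 24.0),
        lattice_shape=(3, 3, 2),
        margin=(6.0, 6.0, 5.0),
        jitter=0.2,
        radius_mean=1.4,
        radius_sd=0.15,
        bend=0.2,
        seed=seed,
    )
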