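"""Vessel-channel stack -> node-segment network with valences and diameters.

The capillary network is summarized as branch *nodes* (valence = number of
vessel segments meeting there) joined by *segments* (a capillary is the
vessel segment between two nodes). Extraction: threshold -> 3D thinning ->
branch-voxel clustering -> path tracing -> spur pruning -> per-segment
diameter from the distance transform -> capillary classification at the
10 um diameter cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

log = logging.getLogger(__name__)

__all__ = [
    "VesselMask",
    "GraphNode",
    "GraphSegment",
    "VesselGraph",
    "ValenceTally",
    "segment_vessels",
    "skeletonize_to_graph",
    "estimate_diameters",
    "classify_capillaries",
    "tally_valences",
]

CAPILLARY_MAX_DIAMETER = 10.0  # um


@dataclass
class VesselMask:
    mask: np.ndarray  # bool, [z, y, x]
    voxel_spacing: tuple[float, float, float]  # (dx, dy, dz) um

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class GraphNode:
    id: int
    position: np.ndarray  # (x, y, z) um
    valence: int
    capillary_valence: int | None = None  # valence counting capillary segments only

    @property
    def effective_valence(self) -> int:
        return self.valence if self.capillary_valence is None else self.capillary_valence


@dataclass
class GraphSegment:
    id: int
    u: int | None  # endpoint node ids; None marks an open end
    v: int | None
    polyline: np.ndarray  # (N, 3) um
    mean_diameter: float | None = None
    is_capillary: bool = True
    is_cycle: bool = False  # closed path with no branch node

    @property
    def length(self) -> float:
        d = np.diff(self.polyline, axis=0)
        return float(np.sqrt((d ** 2).sum(axis=1)).sum())


@dataclass
class VesselGraph:
    nodes: dict[int, GraphNode]
    segments: list[GraphSegment]
    voxel_spacing: tuple[float, float, float]
    dissolved_nodes: list[int] = field(default_factory=list)

    @property
    def open_end_count(self) -> int:
        return sum(
            int(s.u is None) + int(s.v is None) for s in self.segments if not s.is_cycle
        )

    def incident(self, node_id: int) -> list[GraphSegment]:
        return [s for s in self.segments if node_id in (s.u, s.v)]

    def recompute_valences(self) -> None:
        count: dict[int, int] = {nid: 0 for nid in self.nodes}
        for s in self.segments:
            for end in (s.u, s.v):
                if end is not None:
                    count[end] += 1
        for nid, node in self.nodes.items():
            node.valence = count[nid]

    def capillary_segment_count(self) -> float:
        """Capillary segments, merging runs through pass-through nodes.

        A node whose capillary valence drops to 2 joins its two capillary
        segments into one, reducing the count by one per dissolved node.
        """
        n_cap = sum(1 for s in self.segments if s.is_capillary)
        n_pass = sum(
            1
            for n in self.nodes.values()
            if n.capillary_valence == 2 and n.valence >= 3
        )
        return n_cap - n_pass

    def handshake_residual(self) -> int:
        """2*E_internode + open endpoints - sum of valences (0 on valid graphs)."""
        e2 = sum(
            (s.u is not None) + (s.v is not None)
            for s in self.segments
            if not s.is_cycle
        )
        return e2 - sum(n.valence for n in self.nodes.values())


@dataclass
class ValenceTally:
    """Branch-node counts per valence within a counting region."""

    counts: dict[int, int]
    open_end_count: int = 0
    high_valence_nodes: int = 0  # nodes with valence >= 5 folded in per policy

    @property
    def total_nodes(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_vessels(
    channel: np.ndarray,
    voxel_spacing: tuple[float, float, float],
    *,
    method: str = "otsu",
    threshold: float | None = None,
    keep_largest: bool = False,
) -> VesselMask:
    """Binarize a vessel-stain channel.

    ``method="otsu"`` picks a global automatic threshold; ``"fixed"`` uses
    ``threshold``; ``"halfmax"`` thresholds at half the channel maximum.
    """
    img = np.asarray(channel)
    if img.min() < 0:
        raise ValueError("intensities must be nonnegative")
    if not img.any():
        warnings.warn("all-zero vessel channel: returning an empty mask", stacklevel=2)
        return VesselMask(np.zeros(img.shape, dtype=bool), voxel_spacing)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "halfmax":
        thr = 0.5 * float(img.max())
    elif method == "otsu":
        thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = img > thr
    if not mask.any():
        return VesselMask(mask, voxel_spacing)
    if keep_largest:
        lab, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return VesselMask(mask, voxel_spacing)


# ---------------------------------------------------------------------------
# skeleton -> graph
# ---------------------------------------------------------------------------

_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)
_HALF_OFFSETS = _OFFSETS[: len(_OFFSETS) // 2]  # one of each +-pair


def _skeleton_edges(skel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """26-connected voxel adjacency of a skeleton. Returns (coords, edges)."""
    coords = np.argwhere(skel)
    n = len(coords)
    idx_vol = np.full(skel.shape, -1, dtype=np.int64)
    idx_vol[tuple(coords.T)] = np.arange(n)
    pad = np.pad(idx_vol, 1, constant_values=-1)
    edges = []
    base = coords + 1
    for off in _HALF_OFFSETS:
        nb = pad[tuple((base + off).T)]
        hit = nb >= 0
        if hit.any():
            edges.append(np.column_stack([np.arange(n)[hit], nb[hit]]))
    if edges:
        return coords, np.vstack(edges)
    return coords, np.zeros((0, 2), dtype=np.int64)


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, a: int) -> int:
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


def _positions_um(coords_zyx: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    return coords_zyx[:, ::-1] * spacing  # -> (x, y, z) um


def skeletonize_to_graph(
    mask: VesselMask,
    *,
    prune_length: float = 3.0,
    junction_fuse_length: float = 2.0,
) -> VesselGraph:
    """3D thinning and conversion to a node-segment network.

    Skeleton voxels with >= 3 skeleton neighbors are clustered (26-adjacent
    branch voxels merge into one node at their centroid); paths between node
    clusters, or to open ends, become segments. Open-ended spurs shorter than
    ``prune_length`` (um) are removed, and internode segments shorter than
    ``junction_fuse_length`` are contracted (a thinning artifact: one
    valence-4 junction can emerge as two nearby valence-3 clusters).
    """
    spacing = np.asarray(mask.voxel_spacing, dtype=float)
    if mask.is_empty:
        return VesselGraph({}, [], tuple(spacing))
    skel = skeletonize(mask.mask)
    if not skel.any():
        return VesselGraph({}, [], tuple(spacing))
    coords, edges = _skeleton_edges(skel)
    n = len(coords)
    degree = np.zeros(n, dtype=np.int64)
    if len(edges):
        np.add.at(degree, edges[:, 0], 1)
        np.add.at(degree, edges[:, 1], 1)

    branch = degree >= 3
    # cluster 26-adjacent branch voxels
    uf = _UnionFind(n)
    for a, b in edges:
        if branch[a] and branch[b]:
            uf.union(int(a), int(b))
    cluster_of: dict[int, int] = {}
    clusters: dict[int, list[int]] = {}
    for i in np.nonzero(branch)[0]:
        r = uf.find(int(i))
        cluster_of[int(i)] = r
        clusters.setdefault(r, []).append(int(i))

    # adjacency restricted to non-branch voxels, plus voxel -> adjacent clusters
    adj: dict[int, list[int]] = {}
    vox_clusters: dict[int, set[int]] = {}
    cluster_pairs: set[tuple[int, int]] = set()
    for a, b in edges:
        a, b = int(a), int(b)
        ba, bb = branch[a], branch[b]
        if not ba and not bb:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        elif ba and not bb:
            vox_clusters.setdefault(b, set()).add(cluster_of[a])
        elif bb and not ba:
            vox_clusters.setdefault(a, set()).add(cluster_of[b])
        else:
            ra, rb = cluster_of[a], cluster_of[b]
            if ra != rb:
                cluster_pairs.add((min(ra, rb), max(ra, rb)))

    node_ids = {root: k for k, root in enumerate(sorted(clusters))}
    node_pos = {
        node_ids[root]: _positions_um(coords[members].mean(axis=0)[None, :], spacing)[0]
        for root, members in clusters.items()
    }

    segments: list[GraphSegment] = []
    visited = np.zeros(n, dtype=bool)
    visited[branch] = True

    def seg_endpoints_for(vox: int) -> list[int]:
        return sorted(vox_clusters.get(vox, ()))

    nonbranch = [int(i) for i in np.nonzero(~branch)[0]]
    for start in nonbranch:
        if visited[start]:
            continue
        # walk to one end of the path component
        comp = [start]
        visited[start] = True
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for nb in adj.get(cur, ()):
                if not visited[nb]:
                    visited[nb] = True
                    comp.append(nb)
                    frontier.append(nb)
        comp_set = set(comp)
        ends = [
            v
            for v in comp
            if len([w for w in adj.get(v, ()) if w in comp_set]) < 2
        ]
        if not ends:  # pure cycle, no branch voxels
            order = _walk_path(comp[0], None, adj, comp_set)
            poly = _positions_um(coords[order], spacing)
            poly = np.vstack([poly, poly[:1]])
            segments.append(
                GraphSegment(len(segments), None, None, poly, is_cycle=True)
            )
            continue
        ends = sorted(ends)
        first = ends[0]
        order = _walk_path(first, None, adj, comp_set)
        u_cl = seg_endpoints_for(order[0])
        v_cl = seg_endpoints_for(order[-1])
        if len(order) == 1 and len(u_cl) >= 2:
            # single voxel bridging two clusters
            v_cl = u_cl[1:]
            u_cl = u_cl[:1]
        u = node_ids[u_cl[0]] if u_cl else None
        v = node_ids[v_cl[0]] if v_cl else None
        poly = _positions_um(coords[order], spacing)
        if u is not None:
            poly = np.vstack([node_pos[u][None, :], poly])
        if v is not None:
            poly = np.vstack([poly, node_pos[v][None, :]])
        segments.append(GraphSegment(len(segments), u, v, poly))
        # a voxel adjacent to >2 clusters contributes extra zero-length links
        extra = (u_cl[1:] if u is not None else []) + (v_cl[1:] if v is not None else [])
        anchor = u if u is not None else v
        for c in extra:
            segments.append(
                GraphSegment(
                    len(segments),
                    anchor,
                    node_ids[c],
                    np.vstack([node_pos[anchor][None, :], node_pos[node_ids[c]][None, :]]),
                )
            )

    for ra, rb in sorted(cluster_pairs):
        a, b = node_ids[ra], node_ids[rb]
        segments.append(
            GraphSegment(
                len(segments), a, b, np.vstack([node_pos[a][None, :], node_pos[b][None, :]])
            )
        )

    nodes = {
        nid: GraphNode(nid, pos, 0) for nid, pos in sorted(node_pos.items())
    }
    graph = VesselGraph(nodes, segments, tuple(spacing))
    graph.recompute_valences()
    _prune(graph, prune_length, junction_fuse_length)
    return graph


def _walk_path(start: int, prev: int | None, adj: dict, comp: set) -> list[int]:
    order = [start]
    cur, last = start, prev
    while True:
        nxt = [w for w in adj.get(cur, ()) if w in comp and w != last]
        if not nxt:
            break
        last, cur = cur, nxt[0]
        if cur == start:  # closed cycle
            break
        order.append(cur)
    return order


def _merge_two(graph: VesselGraph, node_id: int) -> None:
    """Dissolve a valence-2 node by concatenating its two segments."""
    inc = graph.incident(node_id)
    if len(inc) != 2:
        return
    a, b = inc
    if a is b:  # self-loop through the node -> closed cycle
        a.u = a.v = None
        a.is_cycle = True
        del graph.nodes[node_id]
        return
    pa = a.polyline if a.v == node_id else a.polyline[::-1]
    pb = b.polyline if b.u == node_id else b.polyline[::-1]
    new_u = a.u if a.v == node_id else a.v
    new_v = b.v if b.u == node_id else b.u
    merged = GraphSegment(
        a.id,
        new_u,
        new_v,
        np.vstack([pa, pb[1:]]),
        is_capillary=a.is_capillary and b.is_capillary,
    )
    graph.segments.remove(a)
    graph.segments.remove(b)
    graph.segments.append(merged)
    del graph.nodes[node_id]


def _contract_segment(graph: VesselGraph, seg: GraphSegment) -> None:
    """Fuse the two endpoint nodes of a short internode segment."""
    u, v = seg.u, seg.v
    if u is None or v is None or u == v:
        if u is not None and u == v:
            graph.segments.remove(seg)  # short self-loop: thinning artifact
        return
    keep, drop = graph.nodes[u], graph.nodes[v]
    keep.position = 0.5 * (keep.position + drop.position)
    graph.segments.remove(seg)
    for s in graph.segments:
        if s.u == v:
            s.u = u
        if s.v == v:
            s.v = u
    del graph.nodes[v]


def _prune(graph: VesselGraph, prune_length: float, fuse_length: float) -> None:
    changed = True
    while changed:
        changed = False
        graph.recompute_valences()
        for seg in list(graph.segments):
            open_u, open_v = seg.u is None, seg.v is None
            if seg.is_cycle or open_u == open_v:
                continue
            if seg.length < prune_length:
                graph.segments.remove(seg)
                changed = True
        graph.recompute_valences()
        for seg in list(graph.segments):
            if seg.is_cycle or seg.u is None or seg.v is None:
                continue
            if seg.u == seg.v:
                # tiny ring left by thinning at a fat junction; artifact rings
                # scale with the tube circumference, real capillary loops are
                # far longer
                if seg.length < max(3.0 * fuse_length, prune_length):
                    graph.segments.remove(seg)
                    changed = True
            elif seg.length < fuse_length:
                _contract_segment(graph, seg)
                changed = True
        graph.recompute_valences()
        for nid in list(graph.nodes):
            val = graph.nodes[nid].valence
            if val == 2:
                _merge_two(graph, nid)
                changed = True
            elif val == 1:
                # dangling cluster: fold the node into its single segment end
                (seg,) = graph.incident(nid)
                if seg.u == nid:
                    seg.u = None
                else:
                    seg.v = None
                del graph.nodes[nid]
                changed = True
            elif val == 0:
                del graph.nodes[nid]
                changed = True
    graph.recompute_valences()
    for new_id, seg in enumerate(graph.segments):
        seg.id = new_id


# ---------------------------------------------------------------------------
# diameters and classification
# ---------------------------------------------------------------------------

def estimate_diameters(graph: VesselGraph, mask: VesselMask) -> VesselGraph:
    """Per-segment mean diameter = 2 x mean distance-transform value along the
    centerline, computed in physical units with anisotropic spacing."""
    spacing = np.asarray(mask.voxel_spacing, dtype=float)
    edt = ndimage.distance_transform_edt(mask.mask, sampling=spacing[::-1])
    shape = np.array(mask.mask.shape)
    for seg in graph.segments:
        pts = seg.polyline
        idx = np.clip((pts[:, ::-1] / spacing[::-1]).astype(int), 0, shape - 1)
        inside = mask.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        if not inside.any():
            raise ValueError(
                f"segment {seg.id} lies entirely outside the vessel mask; "
                "graph and mask are inconsistent"
            )
        vals = edt[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        seg.mean_diameter = float(2.0 * vals.mean())
    return graph


def classify_capillaries(
    graph: VesselGraph, max_diameter: float = CAPILLARY_MAX_DIAMETER
) -> VesselGraph:
    """Flag capillary segments (mean diameter <= ``max_diameter``) and
    recompute node valences counting capillary segments only.

    A node whose capillary valence drops to 2 becomes a pass-through (it is
    no longer a branch point of the capillary network); its two capillary
    segments are treated as one for segment counting.
    """
    for seg in graph.segments:
        if seg.mean_diameter is None:
            raise ValueError("diameters must be estimated before classification")
        seg.is_capillary = seg.mean_diameter <= max_diameter
    cap_count: dict[int, int] = {nid: 0 for nid in graph.nodes}
    for seg in graph.segments:
        if not seg.is_capillary:
            continue
        for end in (seg.u, seg.v):
            if end is not None:
                cap_count[end] += 1
    graph.dissolved_nodes = []
    for nid, node in graph.nodes.items():
        node.capillary_valence = cap_count[nid]
        if node.valence >= 3 and cap_count[nid] == 2:
            graph.dissolved_nodes.append(nid)
            log.info("node %d dissolved to a pass-through after classification", nid)
    return graph


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

def _node_iter(graph_or_truth):
    """Yield (position, effective valence) for VesselGraph or VesselGraphTruth."""
    if isinstance(graph_or_truth, VesselGraph):
        for node in graph_or_truth.nodes.values():
            yield node.position, node.effective_valence
    else:
        for node in graph_or_truth.nodes:
            yield node.position, node.valence


def tally_valences(
    graph_or_truth,
    region=None,
    *,
    high_valence_policy: str = "decompose",
) -> ValenceTally:
    """Count branch nodes per valence (3 and 4) inside a counting region.

    ``region`` is a :class:`~nvuquant.stereology.DisectorFrame` (counted with
    its unbiased inclusion/exclusion rule), a boolean voxel mask, or ``None``
    for the whole extent. Valences >= 5 are absent from the counting model;
    the default policy decomposes a k-valent node into (k - 2) virtual
    3-valent nodes, which preserves the cyclomatic identity; ``"clip"``
    counts it as one valence-4 node.
    """
    if high_valence_policy not in ("decompose", "clip"):
        raise ValueError("high_valence_policy must be 'decompose' or 'clip'")
    counts = {3: 0, 4: 0}
    high = 0
    for pos, val in _node_iter(graph_or_truth):
        if val < 3:
            continue
        if region is not None and not _in_region(pos, region, graph_or_truth):
            continue
        if val in (3, 4):
            counts[val] += 1
        else:
            high += 1
            if high_valence_policy == "decompose":
                counts[3] += val - 2
            else:
                counts[4] += 1
    if high:
        log.info(
            "%d node(s) with valence >= 5 folded into the tally (%s policy)",
            high,
            high_valence_policy,
        )
    open_ends = (
        graph_or_truth.open_end_count
        if hasattr(graph_or_truth, "open_end_count")
        else 0
    )
    return ValenceTally(counts=counts, open_end_count=open_ends, high_valence_nodes=high)


def _in_region(pos: np.ndarray, region, graph_or_truth) -> bool:
    if hasattr(region, "contains"):  # DisectorFrame
        return bool(region.contains(pos[None, :])[0])
    mask = np.asarray(region)
    if mask.dtype != bool:
        raise TypeError("region must be a DisectorFrame or a boolean mask")
    spacing = np.asarray(getattr(graph_or_truth, "voxel_spacing", (1.0, 1.0, 1.0)))
    idx = (pos[::-1] / spacing[::-1]).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(mask.shape)):
        raise ValueError("region mask does not cover the node positions")
    return bool(mask[tuple(idx)])
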