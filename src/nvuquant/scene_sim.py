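"""Ground-truthed synthetic confocal scenes of the cortical microvasculature.

The downstream estimators (vessel-graph extraction, optical-disector counts,
fractionator totals, end-foot coverage, plaque load) are all validated against
scenes produced here, where the answer is known by construction:

* :func:`generate_vessel_network` builds a capillary network as a perturbed
  3D lattice whose branch points have valence 3-4, with per-segment radii in
  the capillary range (diameter <= 10 um by default).
* :func:`generate_pericytes` seats pericyte somata ("ghost-like cell bodies")
  on the vessel wall.
* :func:`render_scene` voxelizes the network into multichannel fluorescence
  stacks (vessel lectin, pericyte, AQP4 end-foot shell, nuclei) with PSF blur
  and Poisson-Gaussian noise.
* :func:`generate_plaque_section` produces 2D amyloid-plaque sections with a
  known percent-area burden inside a cortex-like ROI.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

__all__ = [
    "TruthNode",
    "TruthSegment",
    "VesselGraphTruth",
    "PericyteSoma",
    "PericyteTruth",
    "CoverageTruth",
    "ImageScene",
    "PlaqueSectionTruth",
    "generate_vessel_network",
    "generate_pericytes",
    "render_scene",
    "generate_plaque_section",
    "random_closed_multigraph",
]


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthNode:
    """A branch point of the capillary network.

    ``valence`` is the number of vessel segments meeting at the node.
    """

    id: int
    position: np.ndarray  # (x, y, z) um
    valence: int


@dataclass
class TruthSegment:
    """A capillary: the vessel segment between two nodes (or open ends)."""

    id: int
    u: int | None  # endpoint node id, None for an open end
    v: int | None
    polyline: np.ndarray  # (N, 3) centerline in um
    radius: float  # um

    @property
    def length(self) -> float:
        d = np.diff(self.polyline, axis=0)
        return float(np.sqrt((d ** 2).sum(axis=1)).sum())

    def point_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated point and unit tangent at arc-length fraction ``t``."""
        seg = np.sqrt((np.diff(self.polyline, axis=0) ** 2).sum(axis=1))
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = t * cum[-1]
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(max(i, 0), len(seg) - 1)
        frac = 0.0 if seg[i] == 0 else (s - cum[i]) / seg[i]
        p = self.polyline[i] + frac * (self.polyline[i + 1] - self.polyline[i])
        tan = self.polyline[i + 1] - self.polyline[i]
        n = np.linalg.norm(tan)
        return p, (tan / n if n > 0 else np.array([1.0, 0.0, 0.0]))


@dataclass
class VesselGraphTruth:
    """Ground-truth node-segment network of a synthetic capillary bed."""

    nodes: list[TruthNode]
    segments: list[TruthSegment]
    domain_size: tuple[float, float, float]  # (x, y, z) extent in um
    connected_component_count: int
    meta: dict = field(default_factory=dict)

    def valence_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for n in self.nodes:
            out[n.valence] = out.get(n.valence, 0) + 1
        return out

    def node_positions(self) -> np.ndarray:
        if not self.nodes:
            return np.zeros((0, 3))
        return np.array([n.position for n in self.nodes])

    @property
    def internode_segment_count(self) -> int:
        return sum(1 for s in self.segments if s.u is not None and s.v is not None)

    @property
    def open_end_count(self) -> int:
        return sum((s.u is None) + (s.v is None) for s in self.segments)

    @property
    def is_closed(self) -> bool:
        return self.open_end_count == 0

    def cyclomatic_number(self) -> int:
        """E - V + C over the internode network: the topological capillary count."""
        return self.internode_segment_count - len(self.nodes) + self.connected_component_count


@dataclass(frozen=True)
class PericyteSoma:
    centroid: np.ndarray  # um, on the vessel wall surface
    segment_id: int
    bump_radius: float  # um


@dataclass
class PericyteTruth:
    somata: list[PericyteSoma]

    @property
    def total_count(self) -> int:
        return len(self.somata)

    def centroids(self) -> np.ndarray:
        if not self.somata:
            return np.zeros((0, 3))
        return np.array([s.centroid for s in self.somata])


@dataclass
class CoverageTruth:
    """Target and realized fraction of the vessel wall overlaid by AQP4."""

    coverage_fraction: float  # generator target in [0, 1]
    realized_fraction: float | None = None
    shell_thickness: float = 0.0  # um


@dataclass
class ImageScene:
    """Multichannel voxel stack with physical spacing and truth links.

    Channels are indexed ``[z, y, x]``; ``voxel_spacing`` is ``(dx, dy, dz)``
    in um. Physical position = index * spacing, stack corner at the origin.
    """

    channels: dict[str, np.ndarray]
    voxel_spacing: tuple[float, float, float]
    truth: VesselGraphTruth | None = None
    pericyte_truth: PericyteTruth | None = None
    coverage_truth: CoverageTruth | None = None
    vessel_mask_truth: np.ndarray | None = None  # generator's voxelized tube mask

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass
class PlaqueSectionTruth:
    """2D plaque section with the generator's own positive mask."""

    image: np.ndarray
    roi_mask: np.ndarray
    plaque_mask: np.ndarray
    true_area_fraction: float  # percent of ROI covered
    pixel_size_um: float


# ---------------------------------------------------------------------------
# vessel network generation
# ---------------------------------------------------------------------------

_DEF_RADIUS_MEAN = 1.75  # um -> 3.5 um diameter, well under the 10 um capillary cutoff
_DEF_RADIUS_SD = 0.35


def _single_tube_truth(L, rng, radius_mean, radius_sd, margin) -> VesselGraphTruth:
    axis = int(np.argmax(L))
    other = [a for a in range(3) if a != axis]
    r = float(np.clip(rng.normal(radius_mean, radius_sd), 0.5, radius_mean + 3 * radius_sd))
    n_pts = 25
    t = np.linspace(margin[axis] + r, L[axis] - margin[axis] - r, n_pts)
    poly = np.zeros((n_pts, 3))
    poly[:, axis] = t
    amp = min(0.08 * L[other[0]], 2.0)
    poly[:, other[0]] = L[other[0]] / 2 + amp * np.sin(np.linspace(0, 2 * np.pi, n_pts))
    poly[:, other[1]] = L[other[1]] / 2
    seg = TruthSegment(id=0, u=None, v=None, polyline=poly, radius=r)
    return VesselGraphTruth(
        nodes=[], segments=[seg], domain_size=tuple(L),
        connected_component_count=1, meta={"degenerate_single_tube": True},
    )


def generate_vessel_network(
    domain_size: tuple[float, float, float],
    target_segment_density: float = 8000.0,
    *,
    valence_mix: float = 0.5,
    radius_mean: float = _DEF_RADIUS_MEAN,
    radius_sd: float = _DEF_RADIUS_SD,
    seed: int = 0,
    margin: float | tuple[float, float, float] = 0.0,
    jitter: float = 0.35,
    noncapillary_fraction: float = 0.0,
    lattice_shape: tuple[int, int, int] | None = None,
    bend: float = 1.0,
    max_retries: int = 6,
) -> VesselGraphTruth:
    """Generate a closed capillary network with branch valences 3-4.

    The network is a jittered 3D lattice with random edge deletion: every
    lattice node is assigned a target valence (4 with probability
    ``valence_mix``, else 3) and non-spanning-tree edges are removed until
    targets are met, which preserves connectivity exactly.

    Parameters
    ----------
    domain_size : (x, y, z) extent in um.
    target_segment_density : segments per mm^3; low enough densities collapse
        to a single open tube (0 nodes, 1 segment).
    valence_mix : fraction of nodes targeted at valence 4.
    margin : keep-out border in um (scalar or per-axis); nodes and centerlines
        stay inside ``[margin, L - margin]`` laterally.
    jitter : node jitter as a fraction of the lattice tile (1.0 = uniform over
        the tile, which makes node positions marginally uniform per axis).
    noncapillary_fraction : fraction of segments given supra-capillary radii
        (5.5-7.5 um, diameter > 10 um) to exercise the capillary classifier.
    lattice_shape : explicit lattice dimensions, overriding the density-based
        choice (each must be >= 2 for a closed network).
    """
    rng = np.random.default_rng(seed)
    L = np.asarray(domain_size, dtype=float)
    if np.any(L <= 0):
        raise ValueError("domain_size must be positive")
    if target_segment_density <= 0:
        raise ValueError("target_segment_density must be positive")
    if radius_mean <= 0 or radius_sd < 0:
        raise ValueError("radii must be positive")
    m = np.broadcast_to(np.asarray(margin, dtype=float), (3,)).astype(float).copy()
    inner = L - 2 * m
    if np.any(inner <= 4 * radius_mean):
        raise ValueError(
            f"domain {tuple(L)} too small for capillaries of radius ~{radius_mean} um "
            f"with margin {tuple(m)}"
        )

    if lattice_shape is None:
        e_target = target_segment_density * float(np.prod(L)) / 1e9
        s = (3.0 * float(np.prod(inner)) / max(e_target, 1.0)) ** (1.0 / 3.0)
        dims = np.maximum(np.round(inner / s).astype(int), 1)
        if e_target < 6 or np.min(dims) < 2 or np.prod(dims) < 8:
            return _single_tube_truth(L, rng, radius_mean, radius_sd, m)
    else:
        dims = np.asarray(lattice_shape, dtype=int)
        if np.any(dims < 2):
            raise ValueError("lattice_shape entries must be >= 2 for a closed network")

    nx_, ny_, nz_ = (int(d) for d in dims)
    tiles = inner / dims

    # --- lattice graph, deterministic node ordering ---
    lattice = [(i, j, k) for i in range(nx_) for j in range(ny_) for k in range(nz_)]
    index = {v: n for n, v in enumerate(lattice)}
    G = nx.Graph()
    G.add_nodes_from(lattice)
    for (i, j, k) in lattice:
        if i + 1 < nx_:
            G.add_edge((i, j, k), (i + 1, j, k))
        if j + 1 < ny_:
            G.add_edge((i, j, k), (i, j + 1, k))
        if k + 1 < nz_:
            G.add_edge((i, j, k), (i, j, k + 1))

    # --- valence targets; corner nodes start at degree 3 and stay there ---
    draw = rng.random(len(lattice))
    target = {
        v: min(G.degree[v], 4 if draw[index[v]] < valence_mix else 3) for v in lattice
    }
    n4_drawn = int(sum(1 for v in lattice if target[v] == 4))
    full_edges = list(G.edges)

    # --- delete non-spanning-tree edges until degree targets are met ---
    # Restricting deletions to non-tree edges of a (re-randomized) spanning
    # tree preserves connectivity exactly; a final relaxation round lets a
    # still-stuck node shed an edge to a valence-4 neighbor, reassigning that
    # neighbor's class (min degree stays >= 3).
    for attempt in range(max_retries + 1):
        if all(G.degree[v] <= target[v] for v in lattice):
            break
        relax = attempt == max_retries
        for e in G.edges:
            G.edges[e]["w"] = rng.random()
        tree = {frozenset(e) for e in nx.minimum_spanning_tree(G, weight="w").edges}
        nontree = [e for e in G.edges if frozenset(e) not in tree]
        order = rng.permutation(len(nontree))
        changed = True
        while changed:
            changed = False
            for idx in order:
                u, v = nontree[idx]
                if (
                    G.has_edge(u, v)
                    and G.degree[u] > target[u]
                    and G.degree[v] > target[v]
                ):
                    G.remove_edge(u, v)
                    changed = True
        if relax:
            for idx in order:
                u, v = nontree[idx]
                if not G.has_edge(u, v):
                    continue
                for a, b in ((u, v), (v, u)):
                    if G.degree[a] > target[a] and G.degree[b] >= 4:
                        G.remove_edge(a, b)
                        target[b] = min(target[b], G.degree[b])
                        break

    # --- cleanup: shed remaining valence >= 5 via any non-bridge edge ---
    for u in [v for v in lattice if G.degree[v] > 4]:
        while G.degree[u] > 4:
            bridges = {frozenset(e) for e in nx.bridges(G)}
            cand = sorted(
                (b for b in G.neighbors(u)
                 if G.degree[b] >= 4 and frozenset((u, b)) not in bridges),
                key=lambda b: index[b],
            )
            if not cand:
                break
            G.remove_edge(u, cand[int(rng.integers(len(cand)))])

    # --- rebalance the valence mix toward the drawn composition ---
    # deadlock relaxation skews toward valence 3; restore by re-adding
    # deleted lattice edges between degree-3 pairs (3 -> 4, a maximum
    # matching so promotions are not starved) or by dropping non-tree
    # edges between degree-4 pairs (4 -> 3)
    for e in G.edges:
        G.edges[e]["w"] = rng.random()
    tree = {frozenset(e) for e in nx.minimum_spanning_tree(G, weight="w").edges}

    def _count4() -> int:
        return sum(1 for v in lattice if G.degree[v] == 4)

    c4 = _count4()
    if c4 < n4_drawn - 1:
        pool = [
            (u, v) for u, v in full_edges
            if not G.has_edge(u, v) and G.degree[u] == 3 and G.degree[v] == 3
        ]
        matching = sorted(
            (tuple(sorted((index[u], index[v]))) for u, v in
             nx.max_weight_matching(nx.Graph(pool), maxcardinality=True)),
        )
        back = {index[v]: v for v in lattice}
        need = (n4_drawn - c4 + 1) // 2
        pick = rng.permutation(len(matching))[:need]
        for i in sorted(pick):
            iu, iv = matching[i]
            G.add_edge(back[iu], back[iv])
    elif c4 > n4_drawn + 1:
        for _ in range(c4 - n4_drawn):
            cand = [
                (u, v) for u, v in G.edges
                if frozenset((u, v)) not in tree
                and G.degree[u] == 4 and G.degree[v] == 4
            ]
            if not cand or _count4() <= n4_drawn + 1:
                break
            u, v = cand[int(rng.integers(len(cand)))]
            G.remove_edge(u, v)

    # --- node positions: tile centers + jitter, inside the margin box ---
    jit = rng.uniform(-0.5 * jitter, 0.5 * jitter, size=(len(lattice), 3))
    positions = np.empty((len(lattice), 3))
    for v, n in index.items():
        positions[n] = m + (np.array(v) + 0.5 + jit[n]) * tiles
    lo = m + 1e-3
    hi = L - m - 1e-3
    positions = np.clip(positions, lo, hi)

    nodes = [
        TruthNode(id=index[v], position=positions[index[v]], valence=int(G.degree[v]))
        for v in lattice
    ]

    edges = sorted(G.edges, key=lambda e: (index[e[0]], index[e[1]]))
    n_e = len(edges)
    radii = np.clip(
        rng.normal(radius_mean, radius_sd, n_e),
        max(0.5, radius_mean - 2.5 * radius_sd),
        radius_mean + 2.5 * radius_sd,
    )
    if noncapillary_fraction > 0:
        big = rng.random(n_e) < noncapillary_fraction
        radii[big] = rng.uniform(5.5, 7.5, int(big.sum()))

    segments = []
    for sid, (u, v) in enumerate(edges):
        p, q = positions[index[u]], positions[index[v]]
        mid = 0.5 * (p + q)
        d = q - p
        dn = np.linalg.norm(d)
        if dn > 0:
            perp = np.cross(d / dn, rng.standard_normal(3))
            pn = np.linalg.norm(perp)
            if pn > 1e-9:
                mid = mid + perp / pn * min(0.08 * dn, bend) * rng.random()
        poly = np.clip(np.vstack([p, mid, q]), lo, hi)
        segments.append(
            TruthSegment(id=sid, u=index[u], v=index[v], polyline=poly, radius=float(radii[sid]))
        )

    vc: dict[int, int] = {}
    for n in nodes:
        vc[n.valence] = vc.get(n.valence, 0) + 1
    n34 = vc.get(3, 0) + vc.get(4, 0)
    return VesselGraphTruth(
        nodes=nodes,
        segments=segments,
        domain_size=tuple(L),
        connected_component_count=nx.number_connected_components(G),
        meta={
            "seed": seed,
            "lattice_shape": (nx_, ny_, nz_),
            "valence_counts": vc,
            "observed_valence4_fraction": (vc.get(4, 0) / n34 if n34 else float("nan")),
        },
    )


def random_closed_multigraph(
    n_nodes: int, valence_mix: float = 0.5, seed: int = 0
) -> nx.MultiGraph:
    """Random connected closed network with all degrees in {3, 4}.

    Built from a configuration model (largest connected component), used as a
    topology-only truth for validating the node-valence capillary count
    against the brute-force cyclomatic number E - V + 1.
    """
    rng = np.random.default_rng(seed)
    degrees = np.where(rng.random(n_nodes) < valence_mix, 4, 3)
    if degrees.sum() % 2:
        degrees[0] = 7 - degrees[0]  # flip 3<->4 to even the handshake sum
    g = nx.configuration_model(list(degrees), seed=int(rng.integers(2 ** 31)))
    comp = max(nx.connected_components(g), key=len)
    return g.subgraph(comp).copy()


# ---------------------------------------------------------------------------
# pericytes
# ---------------------------------------------------------------------------

def generate_pericytes(
    truth: VesselGraphTruth,
    count: int,
    *,
    bump_radius_range: tuple[float, float] = (2.0, 3.0),
    min_separation: float = 6.0,
    seed: int = 0,
    edge_margin: float = 1.0,
    max_attempts_per_soma: int = 400,
) -> PericyteTruth:
    """Seat ``count`` pericyte somata on the vessel walls of ``truth``.

    Each soma centroid lies exactly on the wall surface of its segment
    (centerline point + radius along a random normal); somata keep a minimum
    mutual separation so rendered bumps stay resolvable.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = np.random.default_rng(seed)
    L = np.asarray(truth.domain_size)
    somata: list[PericyteSoma] = []
    attempts = 0
    budget = max_attempts_per_soma * max(count, 1)
    while len(somata) < count and attempts < budget:
        attempts += 1
        seg = truth.segments[int(rng.integers(len(truth.segments)))]
        p, tan = seg.point_at(float(rng.uniform(0.15, 0.85)))
        normal = rng.standard_normal(3)
        normal -= normal.dot(tan) * tan
        nn = np.linalg.norm(normal)
        if nn < 1e-9:
            continue
        normal /= nn
        br = float(rng.uniform(*bump_radius_range))
        c = p + seg.radius * normal
        if np.any(c < edge_margin) or np.any(c > L - edge_margin):
            continue
        if somata and np.min(
            np.linalg.norm(np.array([s.centroid for s in somata]) - c, axis=1)
        ) < min_separation:
            continue
        somata.append(PericyteSoma(centroid=c, segment_id=seg.id, bump_radius=br))
    if len(somata) < count:
        warnings.warn(
            f"placed only {len(somata)}/{count} pericytes with min_separation="
            f"{min_separation} um; truth reflects the placed count",
            stacklevel=2,
        )
    return PericyteTruth(somata=somata)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _resample_polyline(poly: np.ndarray, step: float) -> np.ndarray:
    seg = np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1))
    total = seg.sum()
    if total == 0:
        return poly[:1]
    n = max(int(math.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((n, 3))
    for a in range(3):
        out[:, a] = np.interp(s, cum, poly[:, a])
    return out


def _stamp_ball(img: np.ndarray, center_um: np.ndarray, radius_um: float,
                spacing: np.ndarray, value: float) -> None:
    """Add ``value`` inside a physical ball; ``img`` indexed [z, y, x]."""
    sp_zyx = spacing[::-1]
    c_idx = center_um[::-1] / sp_zyx
    lo = np.maximum(np.floor(c_idx - radius_um / sp_zyx).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + radius_um / sp_zyx).astype(int) + 1,
                    np.array(img.shape))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[(np.arange(lo[a], hi[a]) - c_idx[a]) * sp_zyx[a] for a in range(3)],
        indexing="ij",
    )
    ball = (grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2) <= radius_um ** 2
    sub = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[ball] = np.maximum(sub[ball], value)


def render_scene(
    truth: VesselGraphTruth,
    pericytes: PericyteTruth | None = None,
    coverage: CoverageTruth | float | None = None,
    *,
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.25),
    psf_sigma: float = 0.3,
    vessel_gain: float = 150.0,
    pericyte_gain: float = 150.0,
    aqp4_gain: float = 150.0,
    nuclei_gain: float = 120.0,
    nucleus_radius: float = 1.3,
    background: float = 10.0,
    read_noise: float = 2.0,
    noise: str = "poisson-gaussian",
    coverage_corr_length: float = 4.0,
    seed: int = 0,
) -> ImageScene:
    """Voxelize a truth network into a multichannel fluorescence stack.

    The vessel channel is a tube rendering of the segments (plus pericyte
    wall bumps, which are part of the lectin-labeled basement membrane); the
    AQP4 channel is a perivascular wall shell covering the requested fraction
    of the vessel surface; the nuclei channel holds a blob at each soma.
    PSF blur, then Poisson shot noise + additive Gaussian read noise, are
    applied last (``noise="none"`` yields the pure signal, no background).

    The default z spacing is the acquisition optical-section interval
    (0.25 um).
    """
    sp = np.asarray(voxel_spacing, dtype=float)
    if np.any(sp <= 0):
        raise ValueError("voxel spacing must be positive")
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be >= 0")
    if noise not in ("poisson-gaussian", "none"):
        raise ValueError("noise must be 'poisson-gaussian' or 'none'")
    rng = np.random.default_rng(seed)
    L = np.asarray(truth.domain_size, dtype=float)
    shape = tuple(int(math.ceil(L[a] / sp[a])) for a in (2, 1, 0))  # (z, y, x)

    centerline = np.zeros(shape, dtype=bool)
    radius_grid = np.zeros(shape, dtype=np.float32)
    field_grid = np.zeros(shape, dtype=np.float32)

    step = 0.45 * float(sp.min())
    for seg in truth.segments:
        pts = _resample_polyline(seg.polyline, step)
        if np.any(pts < -1e-6) or np.any(pts > L + 1e-6):
            raise ValueError(f"segment {seg.id} extends outside the domain")
        sigma_s = max(coverage_corr_length / step, 1.0)
        fld = ndimage.gaussian_filter1d(
            rng.standard_normal(len(pts)), sigma=sigma_s, mode="nearest"
        )
        idx = np.minimum(
            (pts / sp).astype(int), np.array([shape[2], shape[1], shape[0]]) - 1
        )
        iz, iy, ix = idx[:, 2], idx[:, 1], idx[:, 0]
        centerline[iz, iy, ix] = True
        np.maximum.at(radius_grid, (iz, iy, ix), seg.radius)
        field_grid[iz, iy, ix] = fld

    if centerline.any():
        dist, inds = ndimage.distance_transform_edt(
            ~centerline, sampling=sp[::-1], return_indices=True
        )
        near = tuple(inds)
        tube_mask = dist <= radius_grid[near]
    else:
        tube_mask = np.zeros(shape, dtype=bool)

    # perivascular AQP4 shell on the vessel wall layer
    aqp4_mask = np.zeros(shape, dtype=bool)
    cov_target = None
    realized = None
    if coverage is not None:
        cov_target = coverage.coverage_fraction if isinstance(coverage, CoverageTruth) else float(coverage)
        if not 0.0 <= cov_target <= 1.0:
            raise ValueError("coverage fraction must be in [0, 1]")
        wall = tube_mask & ~ndimage.binary_erosion(tube_mask)
        n_wall = int(wall.sum())
        if n_wall and cov_target > 0:
            vals = field_grid[near][wall]
            if cov_target >= 1.0:
                sel = np.ones(n_wall, dtype=bool)
            else:
                thr = np.quantile(vals, 1.0 - cov_target)
                sel = vals >= thr
            aqp4_mask[wall] = sel
            realized = float(sel.mean())
        elif n_wall:
            realized = 0.0

    vessel = tube_mask.astype(np.float32) * vessel_gain
    aqp4 = aqp4_mask.astype(np.float32) * aqp4_gain
    peri = np.zeros(shape, dtype=np.float32)
    nuclei = np.zeros(shape, dtype=np.float32)
    if pericytes is not None:
        for soma in pericytes.somata:
            _stamp_ball(peri, soma.centroid, soma.bump_radius, sp, pericyte_gain)
            _stamp_ball(vessel, soma.centroid, soma.bump_radius, sp, vessel_gain)
            _stamp_ball(nuclei, soma.centroid, nucleus_radius, sp, nuclei_gain)

    channels = {
        "vessel_lectin": vessel,
        "pericyte": peri,
        "aqp4": aqp4,
        "nuclei": nuclei,
    }
    if psf_sigma > 0:
        sig_vox = psf_sigma / sp[::-1]
        channels = {k: ndimage.gaussian_filter(v, sigma=sig_vox) for k, v in channels.items()}
    if noise == "poisson-gaussian":
        out = {}
        for k, v in channels.items():
            lam = v + background
            img = rng.poisson(lam).astype(np.float32)
            img += rng.normal(0.0, read_noise, size=shape).astype(np.float32)
            out[k] = np.clip(img, 0.0, None)
        channels = out

    cov_truth = None
    if cov_target is not None:
        cov_truth = CoverageTruth(
            coverage_fraction=cov_target,
            realized_fraction=realized,
            shell_thickness=float(sp.max()),
        )
    return ImageScene(
        channels=channels,
        voxel_spacing=tuple(sp),
        truth=truth,
        pericyte_truth=pericytes,
        coverage_truth=cov_truth,
        vessel_mask_truth=tube_mask,
    )


# ---------------------------------------------------------------------------
# plaque sections
# ---------------------------------------------------------------------------

def generate_plaque_section(
    roi_shape: tuple[int, int] = (512, 512),
    target_area_fraction: float = 5.0,
    *,
    blob_radius_um: tuple[float, float] = (5.0, 14.0),
    pixel_size_um: float = 1.5,
    amplitude: float = 120.0,
    background: float = 20.0,
    noise_sd: float = 4.0,
    smooth_sigma_px: float = 1.0,
    seed: int = 0,
    max_blobs: int = 20000,
) -> PlaqueSectionTruth:
    """2D section with plaque-like blobs covering a known percent of the ROI.

    Blobs (random disks) are added until the realized area fraction inside the
    elliptical cortex-stand-in ROI is within +-0.5 percentage points of the
    target; the final blob is shrunk to fit the remaining deficit.
    """
    if not 0.0 <= target_area_fraction <= 100.0:
        raise ValueError("target_area_fraction must be in [0, 100]")
    rng = np.random.default_rng(seed)
    h, w = roi_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.46 * h, 0.46 * w
    roi = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    roi_px = int(roi.sum())

    plaque = np.zeros(roi_shape, dtype=bool)
    target_px = target_area_fraction / 100.0 * roi_px
    # rejection-adjusted placement: guarantee +-0.5 percentage points, and
    # proportionally tighter for small targets
    tol_points = min(0.5, max(0.02, 0.1 * target_area_fraction))
    tol_px = tol_points / 100.0 * roi_px
    r_lo = max(blob_radius_um[0] / pixel_size_um, 2.0)
    r_hi = max(blob_radius_um[1] / pixel_size_um, r_lo)
    for _ in range(max_blobs):
        deficit = target_px - int((plaque & roi).sum())
        if deficit <= max(1.0, 0.3 * tol_px):
            break
        r = min(float(rng.uniform(r_lo, r_hi)), math.sqrt(max(deficit, 1.0) / math.pi))
        if r < 1.0:
            break
        while True:
            y0 = rng.uniform(0, h)
            x0 = rng.uniform(0, w)
            if roi[int(min(y0, h - 1)), int(min(x0, w - 1))]:
                break
        plaque |= (yy - y0) ** 2 + (xx - x0) ** 2 <= r ** 2
    else:
        raise RuntimeError("could not reach the target plaque fraction")

    true_frac = 100.0 * int((plaque & roi).sum()) / roi_px
    if abs(true_frac - target_area_fraction) > 0.5 and target_area_fraction <= 99.0:
        raise RuntimeError(
            f"realized plaque fraction {true_frac:.2f}% misses target "
            f"{target_area_fraction}% by more than 0.5 points"
        )

    signal = plaque.astype(np.float32) * amplitude
    if smooth_sigma_px > 0:
        signal = ndimage.gaussian_filter(signal, smooth_sigma_px)
    image = background + signal
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, roi_shape).astype(np.float32)
    image = np.clip(image, 0.0, None)
    return PlaqueSectionTruth(
        image=image.astype(np.float32),
        roi_mask=roi,
        plaque_mask=plaque,
        true_area_fraction=true_frac,
        pixel_size_um=pixel_size_um,
    )
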