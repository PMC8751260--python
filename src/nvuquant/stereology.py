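"""Optical-disector sampling and fractionator estimators.

Design-based stereology: raw counts inside systematically-uniformly-random
(SUR) placed 3D counting frames (optical disectors) are scaled by the
reciprocals of the known sampling fractions,

    N_tot = sum(counts) * (1/ssf) * (1/asf) * (1/tsf),

with ssf the section sampling fraction, asf = A_frame / A_step the area
fraction, and tsf = h / t the thickness fraction (disector height over
section thickness, no guard zones).

The per-disector capillary count is a topological statistic of the branch
nodes: N_cap = sum_n[(n - 2)/2 * N_node(n)] + 1 over valences n in {3, 4},
which for a closed connected network equals the cyclomatic number E - V + 1
(the number of independent loops).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vesselgraph import ValenceTally, tally_valences

__all__ = [
    "SamplingDesign",
    "DisectorFrame",
    "DisectorResult",
    "TotalEstimate",
    "place_disectors",
    "capillary_count_eq1",
    "estimate_total_capillaries",
    "count_pericytes_in_frame",
    "estimate_total_pericytes",
    "pericytes_per_capillary",
    "survey_capillaries",
    "survey_points",
]

# acquisition constants of the reference design
REFERENCE_FRAME = (143.95, 111.52)  # um x um counting frame
REFERENCE_SSF = 1.0 / 53.5
REFERENCE_THICKNESS = 25.0  # um post-shrinkage section thickness
OPTICAL_SECTION_DZ = 0.25  # um z-interval of the confocal stacks


@dataclass(frozen=True)
class SamplingDesign:
    """Fractionator constants: fractions, frame geometry, probe counts."""

    ssf: float = REFERENCE_SSF
    frame_size: tuple[float, float] = REFERENCE_FRAME  # (w, h) um
    a_step: float = REFERENCE_FRAME[0] * REFERENCE_FRAME[1]  # um^2 per position
    thickness: float = REFERENCE_THICKNESS  # t, um
    disector_height: float = REFERENCE_THICKNESS  # h, um
    frames_per_section: int = 5
    sections_per_subject: int = 2
    step: tuple[float, float] | None = None  # explicit (sx, sy); else sqrt(a_step)

    def __post_init__(self) -> None:
        if not 0 < self.ssf <= 1:
            raise ValueError("ssf must be in (0, 1]")
        if self.a_frame > self.a_step + 1e-9:
            raise ValueError("A_frame may not exceed A_step (asf <= 1)")
        if not 0 < self.disector_height <= self.thickness:
            raise ValueError("need 0 < h <= t")
        if self.step is not None:
            sx, sy = self.step
            if abs(sx * sy - self.a_step) > 1e-6 * self.a_step:
                raise ValueError("step dimensions must satisfy sx * sy = a_step")

    @property
    def a_frame(self) -> float:
        return self.frame_size[0] * self.frame_size[1]

    @property
    def asf(self) -> float:
        return self.a_frame / self.a_step

    @property
    def tsf(self) -> float:
        return self.disector_height / self.thickness

    @property
    def step_xy(self) -> tuple[float, float]:
        if self.step is not None:
            return self.step
        s = float(np.sqrt(self.a_step))
        return (s, s)

    @property
    def volume_fraction(self) -> float:
        return self.ssf * self.asf * self.tsf


@dataclass(frozen=True)
class DisectorFrame:
    """A 3D counting probe: counting frame x disector height.

    Unbiased counting rule: the +x and +y ("top and right") faces include,
    the -x and -y faces exclude; objects are counted by centroid. The z
    window is [z0, z0 + height), with no guard zones.
    """

    origin: tuple[float, float, float]  # (x0, y0, z0) um
    size: tuple[float, float, float]  # (w, h, height) um

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x0, y0, z0 = self.origin
        w, h, d = self.size
        return (
            (p[:, 0] > x0)
            & (p[:, 0] <= x0 + w)
            & (p[:, 1] > y0)
            & (p[:, 1] <= y0 + h)
            & (p[:, 2] >= z0)
            & (p[:, 2] < z0 + d)
        )

    def voxel_slices(self, voxel_spacing) -> tuple[slice, slice, slice]:
        """(z, y, x) slices of this frame in a stack with the given spacing."""
        sp = np.asarray(voxel_spacing, dtype=float)
        lo = np.array(self.origin) / sp
        hi = (np.array(self.origin) + np.array(self.size)) / sp
        lo_i = np.maximum(np.floor(lo).astype(int), 0)
        hi_i = np.maximum(np.ceil(hi).astype(int), lo_i + 1)
        return (
            slice(lo_i[2], hi_i[2]),
            slice(lo_i[1], hi_i[1]),
            slice(lo_i[0], hi_i[0]),
        )


@dataclass
class DisectorResult:
    """Per-frame tallies feeding the fractionator."""

    frame: DisectorFrame
    tally: ValenceTally | None = None
    n_cap: float | None = None
    q: int | None = None  # pericyte count
    aqp4_sum: float | None = None
    stl_sum: float | None = None


@dataclass
class TotalEstimate:
    quantity: str
    estimate: float
    per_frame: list[float]
    design: SamplingDesign

    @property
    def raw_sum(self) -> float:
        return float(sum(self.per_frame))


# ---------------------------------------------------------------------------
# probe placement
# ---------------------------------------------------------------------------

def place_disectors(
    region_extent: tuple[float, float],
    design: SamplingDesign,
    seed: int | np.random.Generator = 0,
) -> list[DisectorFrame]:
    """Systematic-uniform-random disector placement over one section.

    A grid with steps (sx, sy) (sx * sy = A_step) starts at a uniform random
    offset; every grid position whose frame fits inside the region yields a
    frame with a uniform random z start. If the grid yields more than
    ``frames_per_section`` frames, a uniform subsample is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lx, ly = float(region_extent[0]), float(region_extent[1])
    w, h = design.frame_size
    if lx < w or ly < h:
        raise ValueError(
            f"region {region_extent} is smaller than the counting frame {design.frame_size}"
        )
    sx, sy = design.step_xy
    offx = float(rng.uniform(0.0, sx))
    offy = float(rng.uniform(0.0, sy))
    xs = np.arange(offx, lx - w + 1e-9, sx)
    ys = np.arange(offy, ly - h + 1e-9, sy)
    zmax = design.thickness - design.disector_height
    frames = []
    for y0 in ys:
        for x0 in xs:
            z0 = float(rng.uniform(0.0, zmax)) if zmax > 0 else 0.0
            frames.append(
                DisectorFrame(
                    origin=(float(x0), float(y0), z0),
                    size=(w, h, design.disector_height),
                )
            )
    if not frames:
        raise ValueError("no frame fits the region with the requested step")
    if len(frames) > design.frames_per_section:
        keep = np.sort(
            rng.choice(len(frames), size=design.frames_per_section, replace=False)
        )
        frames = [frames[i] for i in keep]
    return frames


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def capillary_count_eq1(
    tally: ValenceTally | dict[int, int], *, plus_one: str = "per_sum"
) -> float:
    """Per-disector capillary count from the node-valence tally.

    N_cap = sum_n[(n - 2)/2 * N_node(n)] + 1. The +1 is applied once to the
    sum (default), which makes N_cap the cyclomatic number of a closed
    connected network; ``plus_one="per_valence"`` instead adds 1 for every
    valence class present (a literal alternative reading, kept selectable).
    """
    counts = tally.counts if isinstance(tally, ValenceTally) else dict(tally)
    if any(c < 0 for c in counts.values()):
        raise ValueError("tally counts must be >= 0")
    if plus_one not in ("per_sum", "per_valence"):
        raise ValueError("plus_one must be 'per_sum' or 'per_valence'")
    s = sum((n - 2) / 2.0 * c for n, c in counts.items())
    if plus_one == "per_sum":
        return s + 1.0
    bonus = sum(1 for n, c in counts.items() if c > 0)
    return s + max(bonus, 1)


def _scaled_total(values, design: SamplingDesign, label: str) -> TotalEstimate:
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no disector results to aggregate")
    for name, frac in (("ssf", design.ssf), ("asf", design.asf), ("tsf", design.tsf)):
        if frac <= 0:
            raise ValueError(f"sampling fraction {name} must be positive")
    total = sum(vals) * (1.0 / design.ssf) * (1.0 / design.asf) * (1.0 / design.tsf)
    return TotalEstimate(quantity=label, estimate=total, per_frame=vals, design=design)


def estimate_total_capillaries(
    results: list[DisectorResult], design: SamplingDesign
) -> TotalEstimate:
    """Fractionator total: N_tot(cap) = sum(N_cap) / (ssf * asf * tsf)."""
    vals = []
    for r in results:
        if r.n_cap is None:
            raise ValueError("DisectorResult.n_cap not populated")
        vals.append(r.n_cap)
    return _scaled_total(vals, design, "total_capillaries")


def count_pericytes_in_frame(frame: DisectorFrame, candidates) -> int:
    """Pericytes counted by centroid under the frame's inclusion rule."""
    pts = np.asarray(
        [getattr(c, "centroid", c) for c in candidates], dtype=float
    ).reshape(-1, 3)
    if len(pts) == 0:
        return 0
    return int(frame.contains(pts).sum())


def estimate_total_pericytes(
    results: list[DisectorResult], design: SamplingDesign
) -> TotalEstimate:
    """Fractionator total pericytes: N_tot_peri = sum(Q) / (ssf * asf * tsf)."""
    vals = []
    for r in results:
        if r.q is None:
            raise ValueError("DisectorResult.q not populated")
        vals.append(r.q)
    return _scaled_total(vals, design, "total_pericytes")


def pericytes_per_capillary(peri: TotalEstimate, cap: TotalEstimate) -> float:
    if cap.estimate <= 0:
        raise ZeroDivisionError("capillary total is zero; ratio undefined")
    return peri.estimate / cap.estimate


# ---------------------------------------------------------------------------
# surveys over truth networks or extracted graphs
# ---------------------------------------------------------------------------

def survey_capillaries(
    sections,
    design: SamplingDesign,
    seed: int = 0,
    *,
    region_extent: tuple[float, float] | None = None,
    plus_one: str = "per_sum",
) -> tuple[list[DisectorResult], TotalEstimate]:
    """Run the full disector survey over per-section networks.

    ``sections`` is the list of *sampled* sections (graphs or truths); the
    design's ssf already accounts for the sections not sampled.
    """
    rng = np.random.default_rng(seed)
    results: list[DisectorResult] = []
    for sec in sections:
        extent = region_extent
        if extent is None:
            extent = tuple(np.asarray(sec.domain_size[:2], dtype=float))
        for frame in place_disectors(extent, design, rng):
            tally = tally_valences(sec, frame)
            results.append(
                DisectorResult(frame=frame, tally=tally,
                               n_cap=capillary_count_eq1(tally, plus_one=plus_one))
            )
    return results, estimate_total_capillaries(results, design)


def survey_points(
    point_sets,
    design: SamplingDesign,
    seed: int = 0,
    *,
    region_extent: tuple[float, float],
    label: str = "total_pericytes",
) -> tuple[list[DisectorResult], TotalEstimate]:
    """Disector survey over per-section point clouds (e.g. soma centroids)."""
    rng = np.random.default_rng(seed)
    results = []
    for pts in point_sets:
        for frame in place_disectors(region_extent, design, rng):
            results.append(
                DisectorResult(frame=frame, q=count_pericytes_in_frame(frame, pts))
            )
    return results, _scaled_total([r.q for r in results], design, label)
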