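"""Parameter-recovery simulations against the synthetic ground truth.

Each function runs one estimator end to end on generated data with a known
answer and reports the recovery statistics. These are the package's own
validation experiments; the test suite and the acceptance script both call
them. Problem sizes are chosen for desk-scale runtimes (see the methods
note) while keeping the estimators in their intended regime.
"""

from __future__ import annotations

import numpy as np

from .endfeet_coverage import build_isosurface, percent_contact
from .pericytes import detect_pericytes
from .plaque_load import compute_percent_area
from .scene_sim import (
    generate_pericytes,
    generate_plaque_section,
    generate_vessel_network,
    render_scene,
)
from .stereology import SamplingDesign, survey_capillaries
from .vesselgraph import segment_vessels

__all__ = [
    "fractionator_capillary_recovery",
    "pericyte_recovery",
    "coverage_recovery",
    "plaque_recovery",
]


# ---------------------------------------------------------------------------
# capillary fractionator
# ---------------------------------------------------------------------------

# One synthetic "subject": two flat cortical slabs (sections); one is
# systematically sampled (ssf = 1/2) and probed with a 5 x 2 SUR frame grid
# (10 disectors per subject). Lateral node margins equal the frame extent so
# every node's frame-inclusion probability is exactly asf; full-tile jitter
# makes node depth uniform so tsf = h/t holds without guard zones.
_FRAC_FRAME = (143.95, 111.52)
_FRAC_STEP = (200.0, 120.0)
_FRAC_EXTENT = (
    5 * _FRAC_STEP[0] + _FRAC_FRAME[0],
    2 * _FRAC_STEP[1] + _FRAC_FRAME[1],
)
_FRAC_T = 10.0
_FRAC_H = 8.0
_FRAC_SECTIONS = 2
_FRAC_LATTICE = (61, 10, 2)


def fractionator_design(frames_per_section: int = 10) -> SamplingDesign:
    return SamplingDesign(
        ssf=0.5,
        frame_size=_FRAC_FRAME,
        a_step=_FRAC_STEP[0] * _FRAC_STEP[1],
        thickness=_FRAC_T,
        disector_height=_FRAC_H,
        frames_per_section=frames_per_section,
        sections_per_subject=1,
        step=_FRAC_STEP,
    )


def _subject_sections(seed: int) -> list:
    return [
        generate_vessel_network(
            (_FRAC_EXTENT[0], _FRAC_EXTENT[1], _FRAC_T),
            lattice_shape=_FRAC_LATTICE,
            margin=(_FRAC_FRAME[0], _FRAC_FRAME[1], 0.0),
            jitter=1.0,
            bend=0.3,
            seed=seed * 101 + k,
        )
        for k in range(_FRAC_SECTIONS)
    ]


def fractionator_capillary_recovery(
    n_subjects: int = 50, seed: int = 0
) -> dict:
    """Fractionator total-capillary estimates vs ground truth.

    Each subject's truth is the summed cyclomatic number (topological
    capillary count) of its sections; the estimate runs the full survey:
    section sampling (ssf), SUR disector placement (asf), disector height
    (tsf), per-frame node-valence tallies, and the Eq.-style scaled total.
    """
    rng = np.random.default_rng(seed)
    design = fractionator_design()
    rel_errors = []
    for s in range(n_subjects):
        sub_seed = int(rng.integers(2 ** 31))
        sections = _subject_sections(sub_seed)
        truth_total = sum(sec.cyclomatic_number() for sec in sections)
        off = int(rng.integers(2))
        sampled = sections[off :: 2]
        _, est = survey_capillaries(
            sampled, design, seed=sub_seed + 1, region_extent=_FRAC_EXTENT
        )
        rel_errors.append((est.estimate - truth_total) / truth_total)
    rel_errors = np.array(rel_errors)
    return {
        "n_subjects": n_subjects,
        "rel_errors": rel_errors,
        "mean_rel_bias": float(rel_errors.mean()),
        "within_20pct_rate": float(np.mean(np.abs(rel_errors) <= 0.20)),
    }


# ---------------------------------------------------------------------------
# pericytes
# ---------------------------------------------------------------------------

def pericyte_recovery(n_scenes: int = 50, seed: int = 0, *, n_pericytes: int = 10) -> dict:
    """Detection + disector counting + fractionator scaling vs true somata.

    Thin rendered scenes under default noise; the frame grid tiles the whole
    scene (asf = tsf = 1) so the shared-face inclusion/exclusion rule and the
    detector are what is being tested, not Monte-Carlo placement noise.
    """
    from .stereology import DisectorFrame, count_pericytes_in_frame

    rng = np.random.default_rng(seed)
    rel_errors = []
    for s in range(n_scenes):
        sub_seed = int(rng.integers(2 ** 31))
        truth = generate_vessel_network(
            (48.0, 48.0, 12.0),
            lattice_shape=(3, 3, 2),
            margin=(7.0, 7.0, 3.0),
            jitter=0.2,
            radius_mean=1.4,
            radius_sd=0.15,
            bend=0.2,
            seed=sub_seed,
        )
        peri = generate_pericytes(
            truth, n_pericytes, seed=sub_seed + 1, min_separation=7.0,
            bump_radius_range=(2.0, 2.8),
        )
        scene = render_scene(
            truth, peri, voxel_spacing=(0.5, 0.5, 0.25), psf_sigma=0.3,
            noise="poisson-gaussian", seed=sub_seed + 2,
        )
        detections = detect_pericytes(scene)
        # 2 x 2 frame tiling of the full scene
        q = 0
        for ox in (0.0, 24.0):
            for oy in (0.0, 24.0):
                frame = DisectorFrame(origin=(ox, oy, 0.0), size=(24.0, 24.0, 12.0))
                q += count_pericytes_in_frame(frame, detections)
        truth_n = peri.total_count
        rel_errors.append((q - truth_n) / truth_n)
    rel_errors = np.array(rel_errors)
    return {
        "n_scenes": n_scenes,
        "rel_errors": rel_errors,
        "mean_rel_bias": float(rel_errors.mean()),
    }


# ---------------------------------------------------------------------------
# end-foot coverage
# ---------------------------------------------------------------------------

def _coverage_scene(target: float, seed: int, noise: str):
    from .scene_sim import TruthSegment, VesselGraphTruth

    segs = []
    for k, y in enumerate((12.0, 24.0, 36.0)):
        poly = np.array([[3.0, y, 5.0], [57.0, y, 5.0]])
        segs.append(TruthSegment(k, None, None, poly, 2.0))
    truth = VesselGraphTruth(
        nodes=[], segments=segs, domain_size=(60.0, 48.0, 10.0),
        connected_component_count=3,
    )
    psf = 0.0 if noise == "none" else 0.3
    return render_scene(
        truth, None, target, voxel_spacing=(0.25, 0.25, 0.25),
        psf_sigma=psf, noise=noise, seed=seed,
    )


def coverage_recovery(
    targets=(0.2, 0.4, 0.6, 0.8), seed: int = 0, *, noise: str = "none",
    projection: str = "2d",
) -> dict:
    """Percent contact vs the generator's wall-coverage fraction.

    Straight-tube scenes with equal per-voxel stain brightness; the measured
    AQP4/STL intensity ratio over the capillary iso-surface should recover
    the coverage fraction (x100).
    """
    measured = []
    for k, target in enumerate(targets):
        scene = _coverage_scene(float(target), seed + k, noise)
        method = "halfmax" if noise == "none" else "otsu"
        vmask = segment_vessels(
            scene.channels["vessel_lectin"], scene.voxel_spacing, method=method
        )
        iso = build_isosurface(vmask.mask, shell_thickness=2)
        res = percent_contact(scene.channels, iso, projection=projection)
        measured.append(res.percent_contact)
    measured = np.array(measured)
    truth = 100.0 * np.array(targets, dtype=float)
    return {
        "targets_pct": truth,
        "measured_pct": measured,
        "abs_errors_pp": np.abs(measured - truth),
        "max_abs_error_pp": float(np.max(np.abs(measured - truth))),
        "monotone": bool(np.all(np.diff(measured) > 0)),
    }


# ---------------------------------------------------------------------------
# plaque load
# ---------------------------------------------------------------------------

def plaque_recovery(targets=(0.1, 1.0, 5.0, 10.0), seed: int = 0) -> dict:
    """Measured vs true percent-area across a burden sweep (default noise).

    Threshold fixed midway between section background and plaque amplitude;
    the regression slope of measured on true percent area should be 1.
    """
    true_vals, measured = [], []
    for k, target in enumerate(targets):
        sec = generate_plaque_section((512, 512), float(target), seed=seed + k)
        res = compute_percent_area(
            sec.image, sec.roi_mask, method="fixed", threshold=80.0,
            pixel_size_um=sec.pixel_size_um,
        )
        true_vals.append(sec.true_area_fraction)
        measured.append(res.percent_area)
    true_vals = np.array(true_vals)
    measured = np.array(measured)
    slope, intercept = np.polyfit(true_vals, measured, 1)
    return {
        "true_pct": true_vals,
        "measured_pct": measured,
        "slope": float(slope),
        "intercept": float(intercept),
    }
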