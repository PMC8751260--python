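"""Percent contact of AQP4-positive astrocytic end-feet on capillaries.

The measurement masks everything but a thin shell ("iso-surface") at the
capillary surface and takes the intensity ratio

    % contact surface = 100 * (AQP4 stain intensity) / (STL stain intensity)

summed over the shell. By default both channels and the shell are
max-intensity-projected over z (a 2D reconstruction) before summing; a 3D
mode sums over the raw shell voxels for sensitivity analysis.

This is an intensity ratio, not a geometric overlap: doubling the AQP4
detector gain doubles the result, and values above 100% are possible; they
are reported and flagged, never clipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = ["IsoSurfaceMask", "CoverageResult", "build_isosurface", "percent_contact",
           "coverage_for_frame"]


@dataclass
class IsoSurfaceMask:
    """Capillary surface shell: vessel-mask voxels within ``shell_thickness``
    erosion steps of the surface (interior excluded)."""

    mask: np.ndarray  # bool, [z, y, x]
    shell_thickness: int  # voxels
    frame: object | None = None

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class CoverageResult:
    aqp4_intensity_sum: float
    stl_intensity_sum: float
    percent_contact: float
    projection: str
    over_100: bool
    frame: object | None = None


def build_isosurface(vessel_mask: np.ndarray, shell_thickness: int = 2,
                     frame=None) -> IsoSurfaceMask:
    """Surface shell of the vessel mask within one disector.

    ``rind = mask & ~erosion(mask, shell_thickness)``: for thickness 1 this
    is exactly the surface voxels, interior excluded. A vessel-free frame
    yields an empty shell (coverage undefined there; callers exclude such
    frames from averages).
    """
    mask = np.asarray(vessel_mask)
    if mask.dtype != bool:
        raise TypeError("vessel_mask must be boolean")
    if shell_thickness < 1:
        raise ValueError("shell_thickness must be >= 1")
    if not mask.any():
        warnings.warn("vessel-free frame: empty iso-surface, coverage undefined",
                      stacklevel=2)
        return IsoSurfaceMask(mask.copy(), shell_thickness, frame)
    rind = mask & ~ndimage.binary_erosion(mask, iterations=shell_thickness)
    return IsoSurfaceMask(rind, shell_thickness, frame)


def percent_contact(
    channels: dict[str, np.ndarray],
    iso: IsoSurfaceMask,
    *,
    projection: str = "2d",
    aqp4_channel: str = "aqp4",
    stl_channel: str = "vessel_lectin",
) -> CoverageResult:
    """Intensity-ratio end-foot contact over the capillary iso-surface.

    ``projection="2d"`` (default) max-projects both channels and the shell
    over z and sums over the projected shell pixels; ``"3d"`` sums over the
    shell voxels directly.
    """
    if projection not in ("2d", "3d"):
        raise ValueError("projection must be '2d' or '3d'")
    aqp4 = np.asarray(channels[aqp4_channel], dtype=float)
    stl = np.asarray(channels[stl_channel], dtype=float)
    if aqp4.shape != iso.mask.shape or stl.shape != iso.mask.shape:
        raise ValueError("channels and iso-surface mask must share one shape")
    if projection == "2d":
        m = iso.mask.any(axis=0)
        a_sum = float(aqp4.max(axis=0)[m].sum())
        s_sum = float(stl.max(axis=0)[m].sum())
    else:
        a_sum = float(aqp4[iso.mask].sum())
        s_sum = float(stl[iso.mask].sum())
    if s_sum <= 0:
        raise ValueError("STL intensity sum is zero over the iso-surface; "
                         "percent contact undefined")
    pct = 100.0 * a_sum / s_sum
    over = pct > 100.0
    if over:
        log.warning("percent contact %.1f%% exceeds 100%% (gain imbalance?)", pct)
    return CoverageResult(
        aqp4_intensity_sum=a_sum,
        stl_intensity_sum=s_sum,
        percent_contact=pct,
        projection=projection,
        over_100=over,
        frame=iso.frame,
    )


def coverage_for_frame(
    scene,
    vessel_mask: np.ndarray,
    frame,
    *,
    shell_thickness: int = 2,
    projection: str = "2d",
) -> CoverageResult | None:
    """Per-disector coverage: crop the stack to the frame, build the shell,
    take the ratio. Returns ``None`` for vessel-free frames (logged)."""
    sl = frame.voxel_slices(scene.voxel_spacing)
    sub_mask = vessel_mask[sl]
    if not sub_mask.any():
        log.info("frame at %s contains no vessel; coverage skipped", frame.origin)
        return None
    iso = build_isosurface(sub_mask, shell_thickness, frame=frame)
    sub_channels = {k: v[sl] for k, v in scene.channels.items()}
    return percent_contact(sub_channels, iso, projection=projection)
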