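"""Pericyte soma detection from the pericyte-marker channel.

Pericytes sit in bump-shaped protrusions of the lectin-labeled basement
membrane; the marker channel (PDGFRB) shows compact blobs co-located with a
nucleus. Detection: light smoothing, half-max (or Otsu) threshold, size
filter, optional nucleus-colocalization check; centroids are returned in
physical coordinates for the disector counting rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["PericyteDetection", "detect_pericytes"]


@dataclass(frozen=True)
class PericyteDetection:
    centroid: np.ndarray  # (x, y, z) um
    volume_um3: float
    mean_intensity: float


def detect_pericytes(
    scene,
    *,
    channel: str = "pericyte",
    nuclei_channel: str = "nuclei",
    method: str = "halfmax",
    threshold: float | None = None,
    smooth_sigma_um: float = 0.4,
    min_volume_um3: float = 8.0,
    require_nucleus: bool = True,
) -> list[PericyteDetection]:
    """Detect pericyte somata in an :class:`~nvuquant.scene_sim.ImageScene`."""
    sp = np.asarray(scene.voxel_spacing, dtype=float)
    img = np.asarray(scene.channels[channel], dtype=float)
    if smooth_sigma_um > 0:
        img = ndimage.gaussian_filter(img, sigma=smooth_sigma_um / sp[::-1])
    if not img.any():
        return []
    if method == "halfmax":
        thr = 0.5 * float(img.max())
    elif method == "otsu":
        thr = float(threshold_otsu(img))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")

    mask = img > thr
    if not mask.any():
        return []
    lab, n = ndimage.label(mask)
    voxel_vol = float(np.prod(sp))
    nuc = None
    nuc_thr = 0.0
    if require_nucleus and nuclei_channel in scene.channels:
        nuc = ndimage.gaussian_filter(
            np.asarray(scene.channels[nuclei_channel], dtype=float),
            sigma=smooth_sigma_um / sp[::-1],
        )
        nuc_thr = 0.3 * float(nuc.max()) if nuc.any() else 0.0

    out: list[PericyteDetection] = []
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    coms = ndimage.center_of_mass(img, lab, index=np.arange(1, n + 1))
    means = ndimage.mean(img, lab, index=np.arange(1, n + 1))
    for i in range(n):
        if sizes[i] * voxel_vol < min_volume_um3:
            continue
        com_zyx = np.asarray(coms[i])
        centroid = com_zyx[::-1] * sp  # (x, y, z) um
        if nuc is not None and nuc_thr > 0:
            idx = tuple(np.clip(np.round(com_zyx).astype(int), 0,
                                np.array(nuc.shape) - 1))
            if nuc[idx] <= nuc_thr:
                continue
        out.append(
            PericyteDetection(
                centroid=centroid,
                volume_um3=float(sizes[i] * voxel_vol),
                mean_intensity=float(means[i]),
            )
        )
    return out
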