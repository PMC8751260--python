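"""Percent-area amyloid plaque burden on 2D section images.

Positive signal is thresholded within a region of interest (the cortical
outline), speckle below a physical size floor is removed, and the burden is
reported as the percent of ROI area occupied by plaques.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["PlaqueLoadResult", "compute_percent_area"]


@dataclass
class PlaqueLoadResult:
    roi_area_px: int
    roi_area_um2: float
    positive_area_px: int
    positive_area_um2: float
    percent_area: float
    threshold: float
    method: str


def compute_percent_area(
    image: np.ndarray,
    roi: np.ndarray,
    *,
    method: str = "otsu",
    threshold: float | None = None,
    min_object_size_um2: float = 10.0,
    pixel_size_um: float = 1.5,
    invert: bool = False,
) -> PlaqueLoadResult:
    """Percent of the ROI covered by thresholded plaque signal.

    ``method="otsu"`` derives an automatic global threshold from the ROI
    histogram; ``"fixed"`` uses ``threshold`` directly. ``invert`` handles
    brightfield chromogen images where deposits are dark on a light
    background. Objects smaller than ``min_object_size_um2`` are discarded
    (set to 0 to keep every positive pixel). The threshold and method used
    are recorded in the result for provenance.
    """
    img = np.asarray(image, dtype=float)
    roi = np.asarray(roi)
    if roi.dtype != bool:
        raise TypeError("roi must be a boolean mask")
    if img.shape != roi.shape:
        raise ValueError("image and ROI must share one shape")
    roi_px = int(roi.sum())
    if roi_px == 0:
        raise ValueError("empty ROI")
    if invert:
        img = float(img.max()) - img

    vals = img[roi]
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(vals) == 0:
            thr = float(vals[0])  # flat ROI: nothing exceeds the threshold
        else:
            thr = float(threshold_otsu(vals))
    else:
        raise ValueError(f"unknown method {method!r}")

    if thr >= vals.max():
        if method == "fixed":
            warnings.warn("threshold above the ROI intensity range: 0% positive",
                          stacklevel=2)
        pos = np.zeros_like(roi)
    elif thr < vals.min():
        warnings.warn("threshold below the ROI intensity range: 100% positive",
                      stacklevel=2)
        pos = roi.copy()
    else:
        pos = (img > thr) & roi

    if min_object_size_um2 > 0 and pos.any():
        min_px = int(round(min_object_size_um2 / (pixel_size_um ** 2)))
        if min_px > 1:
            lab, n = ndimage.label(pos)
            sizes = np.bincount(lab.ravel())
            small = np.nonzero(sizes < min_px)[0]
            pos = pos & ~np.isin(lab, small[small > 0])

    pos_px = int(pos.sum())
    px_area = pixel_size_um ** 2
    return PlaqueLoadResult(
        roi_area_px=roi_px,
        roi_area_um2=roi_px * px_area,
        positive_area_px=pos_px,
        positive_area_um2=pos_px * px_area,
        percent_area=100.0 * pos_px / roi_px,
        threshold=thr,
        method=method,
    )
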