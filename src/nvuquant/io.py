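"""Scene and truth serialization.

Stacks go to multipage TIFF (one file per channel, ZYX pages); truths go to
a JSON sidecar: nodes, segments, somata, coverage fraction, and the plaque
mask as a run-length-encoded field. Round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .scene_sim import (
    CoverageTruth,
    ImageScene,
    PericyteSoma,
    PericyteTruth,
    PlaqueSectionTruth,
    TruthNode,
    TruthSegment,
    VesselGraphTruth,
)

__all__ = [
    "rle_encode",
    "rle_decode",
    "truth_to_dict",
    "truth_from_dict",
    "save_scene",
    "load_scene",
    "save_plaque_section",
    "load_plaque_section",
]


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean array (C-order runs, starting with False)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "runs": []}
    change = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:  # convention: runs alternate starting from False
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(payload: dict) -> np.ndarray:
    shape = tuple(payload["shape"])
    runs = payload["runs"]
    out = np.zeros(int(np.prod(shape)) if shape else 0, dtype=bool)
    pos = 0
    val = False
    for r in runs:
        if val:
            out[pos:pos + r] = True
        pos += r
        val = not val
    return out.reshape(shape)


def truth_to_dict(
    truth: VesselGraphTruth | None = None,
    pericytes: PericyteTruth | None = None,
    coverage: CoverageTruth | None = None,
) -> dict:
    out: dict = {}
    if truth is not None:
        out["vessel_graph"] = {
            "domain_size": list(truth.domain_size),
            "connected_component_count": truth.connected_component_count,
            "nodes": [
                {"id": n.id, "position": n.position.tolist(), "valence": n.valence}
                for n in truth.nodes
            ],
            "segments": [
                {
                    "id": s.id,
                    "u": s.u,
                    "v": s.v,
                    "polyline": s.polyline.tolist(),
                    "radius": s.radius,
                }
                for s in truth.segments
            ],
        }
    if pericytes is not None:
        out["pericytes"] = [
            {
                "centroid": s.centroid.tolist(),
                "segment_id": s.segment_id,
                "bump_radius": s.bump_radius,
            }
            for s in pericytes.somata
        ]
    if coverage is not None:
        out["coverage"] = {
            "coverage_fraction": coverage.coverage_fraction,
            "realized_fraction": coverage.realized_fraction,
            "shell_thickness": coverage.shell_thickness,
        }
    return out


def truth_from_dict(payload: dict) -> tuple[
    VesselGraphTruth | None, PericyteTruth | None, CoverageTruth | None
]:
    truth = None
    if "vessel_graph" in payload:
        g = payload["vessel_graph"]
        truth = VesselGraphTruth(
            nodes=[
                TruthNode(n["id"], np.array(n["position"]), n["valence"])
                for n in g["nodes"]
            ],
            segments=[
                TruthSegment(
                    s["id"], s["u"], s["v"], np.array(s["polyline"]), s["radius"]
                )
                for s in g["segments"]
            ],
            domain_size=tuple(g["domain_size"]),
            connected_component_count=g["connected_component_count"],
        )
    peri = None
    if "pericytes" in payload:
        peri = PericyteTruth(
            somata=[
                PericyteSoma(np.array(s["centroid"]), s["segment_id"], s["bump_radius"])
                for s in payload["pericytes"]
            ]
        )
    cov = None
    if "coverage" in payload:
        c = payload["coverage"]
        cov = CoverageTruth(
            coverage_fraction=c["coverage_fraction"],
            realized_fraction=c["realized_fraction"],
            shell_thickness=c["shell_thickness"],
        )
    return truth, peri, cov


def save_scene(scene: ImageScene, out_dir: str | Path, stem: str = "scene") -> Path:
    """Write one multipage TIFF per channel plus a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in scene.channels.items():
        tifffile.imwrite(
            out / f"{stem}_{name}.tif",
            np.asarray(arr, dtype=np.float32),
            metadata={"spacing_um": list(scene.voxel_spacing), "axes": "ZYX"},
        )
    sidecar = {
        "voxel_spacing": list(scene.voxel_spacing),
        "channels": sorted(scene.channels),
        **truth_to_dict(scene.truth, scene.pericyte_truth, scene.coverage_truth),
    }
    path = out / f"{stem}_truth.json"
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def load_scene(out_dir: str | Path, stem: str = "scene") -> ImageScene:
    out = Path(out_dir)
    sidecar = json.loads((out / f"{stem}_truth.json").read_text())
    channels = {
        name: tifffile.imread(out / f"{stem}_{name}.tif")
        for name in sidecar["channels"]
    }
    truth, peri, cov = truth_from_dict(sidecar)
    return ImageScene(
        channels=channels,
        voxel_spacing=tuple(sidecar["voxel_spacing"]),
        truth=truth,
        pericyte_truth=peri,
        coverage_truth=cov,
    )


def save_plaque_section(section: PlaqueSectionTruth, out_dir: str | Path,
                        stem: str = "plaque") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{stem}.tif", section.image.astype(np.float32))
    payload = {
        "pixel_size_um": section.pixel_size_um,
        "true_area_fraction": section.true_area_fraction,
        "roi_mask": rle_encode(section.roi_mask),
        "plaque_mask": rle_encode(section.plaque_mask),
    }
    path = out / f"{stem}_truth.json"
    path.write_text(json.dumps(payload))
    return path


def load_plaque_section(out_dir: str | Path, stem: str = "plaque") -> PlaqueSectionTruth:
    out = Path(out_dir)
    payload = json.loads((out / f"{stem}_truth.json").read_text())
    return PlaqueSectionTruth(
        image=tifffile.imread(out / f"{stem}.tif"),
        roi_mask=rle_decode(payload["roi_mask"]),
        plaque_mask=rle_decode(payload["plaque_mask"]),
        true_area_fraction=payload["true_area_fraction"],
        pixel_size_um=payload["pixel_size_um"],
    )
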