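"""End-to-end demo pipeline: simulate -> extract -> sample -> estimate -> stats.

Runs the full 2 x 2 x 2 factorial study design (genotype x exposure x
survival, n subjects per group) on synthetic scenes, measures every subject
with the same estimators a real study would use, and writes tidy CSV tables
(per-disector, per-subject, per-group, ANOVA + post-hoc) plus a run log.
Outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .endfeet_coverage import coverage_for_frame
from .pericytes import detect_pericytes
from .plaque_load import compute_percent_area
from .scene_sim import generate_pericytes, generate_plaque_section, generate_vessel_network, render_scene
from .stats_report import one_way_anova_tukey, summarize_groups, two_way_anova_sidak
from .stereology import (
    DisectorResult,
    SamplingDesign,
    capillary_count_eq1,
    count_pericytes_in_frame,
    estimate_total_capillaries,
    estimate_total_pericytes,
    pericytes_per_capillary,
    place_disectors,
)
from .vesselgraph import classify_capillaries, estimate_diameters, segment_vessels, skeletonize_to_graph, tally_valences

__all__ = ["GroupEffects", "PipelineConfig", "default_config", "run_pipeline"]

GENOTYPES = ("Tg", "Wt")
EXPOSURES = ("bTBI", "Sham")
SURVIVALS = ("3mo", "12mo")


@dataclass
class GroupEffects:
    """Generator parameters for one experimental group."""

    capillary_lattice: tuple[int, int, int] = (3, 3, 2)
    pericyte_count: int = 10
    coverage_target: float = 0.60
    plaque_target: float | None = None  # percent; None for amyloid-free genotypes


@dataclass
class PipelineConfig:
    subjects_per_group: int = 3
    scene_size: tuple[float, float, float] = (48.0, 48.0, 20.0)  # um
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.25)
    psf_sigma: float = 0.3
    noise: str = "poisson-gaussian"
    frame_size: tuple[float, float] = (14.0, 14.0)
    step: tuple[float, float] = (15.0, 15.0)
    frames_per_section: int = 5
    disector_height: float = 16.0
    plaque_shape: tuple[int, int] = (256, 256)
    groups: dict[str, GroupEffects] = field(default_factory=dict)

    def group_key(self, genotype: str, exposure: str, survival: str) -> str:
        return f"{genotype}-{exposure}-{survival}"

    def effects(self, genotype: str, exposure: str, survival: str) -> GroupEffects:
        return self.groups.get(
            self.group_key(genotype, exposure, survival), GroupEffects()
        )

    def design(self) -> SamplingDesign:
        return SamplingDesign(
            ssf=1.0,
            frame_size=self.frame_size,
            a_step=self.step[0] * self.step[1],
            thickness=self.scene_size[2],
            disector_height=self.disector_height,
            frames_per_section=self.frames_per_section,
            sections_per_subject=1,
            step=self.step,
        )


def default_config() -> PipelineConfig:
    """The demo study: qualitative group effects of the blast-injury design.

    Transgenic (Tg) animals develop plaques that grow with survival time;
    blast exposure lowers end-foot coverage in Tg at 3 months and raises
    capillary (and pericyte) numbers in Tg at 12 months, while Wt blast
    animals lose capillaries and pericytes by 12 months.
    """
    cfg = PipelineConfig()
    g = cfg.groups
    base = GroupEffects()
    for gt in GENOTYPES:
        for ex in EXPOSURES:
            for sv in SURVIVALS:
                g[cfg.group_key(gt, ex, sv)] = GroupEffects(
                    capillary_lattice=base.capillary_lattice,
                    pericyte_count=base.pericyte_count,
                    coverage_target=base.coverage_target,
                    plaque_target=(0.25 if sv == "3mo" else 5.5) if gt == "Tg" else None,
                )
    g["Tg-bTBI-3mo"].coverage_target = 0.45
    g["Tg-bTBI-12mo"].capillary_lattice = (4, 4, 2)
    g["Tg-bTBI-12mo"].pericyte_count = 16
    g["Tg-Sham-12mo"].capillary_lattice = (4, 3, 2)
    g["Tg-Sham-12mo"].pericyte_count = 13
    g["Wt-bTBI-12mo"].capillary_lattice = (2, 3, 2)
    g["Wt-bTBI-12mo"].pericyte_count = 6
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    groups = {
        k: GroupEffects(**{**v, "capillary_lattice": tuple(v.get("capillary_lattice", (3, 3, 2)))})
        for k, v in raw.pop("groups", {}).items()
    }
    for key in ("scene_size", "voxel_spacing", "frame_size", "step", "plaque_shape"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    if groups:
        cfg.groups = groups
    return cfg


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2 ** 31))


def _measure_subject(
    cfg: PipelineConfig, eff: GroupEffects, seed: int
) -> tuple[dict, list[dict]]:
    truth = generate_vessel_network(
        cfg.scene_size,
        lattice_shape=eff.capillary_lattice,
        margin=(6.0, 6.0, 4.0),
        jitter=0.3,
        seed=_sub_seed(seed, 0),
    )
    peri_truth = generate_pericytes(
        truth, eff.pericyte_count, seed=_sub_seed(seed, 1), min_separation=5.0
    )
    scene = render_scene(
        truth,
        peri_truth,
        eff.coverage_target,
        voxel_spacing=cfg.voxel_spacing,
        psf_sigma=cfg.psf_sigma,
        noise=cfg.noise,
        seed=_sub_seed(seed, 2),
    )
    vmask = segment_vessels(
        scene.channels["vessel_lectin"], scene.voxel_spacing, method="otsu"
    )
    graph = skeletonize_to_graph(vmask)
    if graph.segments:
        estimate_diameters(graph, vmask)
        classify_capillaries(graph)
    detections = detect_pericytes(scene)
    design = cfg.design()
    frames = place_disectors(
        cfg.scene_size[:2], design, np.random.default_rng(_sub_seed(seed, 3))
    )
    results, disector_rows = [], []
    cov_values = []
    for k, frame in enumerate(frames):
        tally = tally_valences(graph, frame)
        n_cap = capillary_count_eq1(tally)
        q = count_pericytes_in_frame(frame, detections)
        cov = coverage_for_frame(scene, vmask.mask, frame)
        results.append(DisectorResult(frame=frame, tally=tally, n_cap=n_cap, q=q))
        if cov is not None:
            cov_values.append(cov.percent_contact)
        disector_rows.append(
            {
                "frame": k,
                "n_node3": tally.counts.get(3, 0),
                "n_node4": tally.counts.get(4, 0),
                "n_cap": n_cap,
                "pericytes_q": q,
                "coverage_pct": cov.percent_contact if cov is not None else np.nan,
            }
        )
    cap_tot = estimate_total_capillaries(results, design)
    peri_tot = estimate_total_pericytes(results, design)
    ratio = (
        pericytes_per_capillary(peri_tot, cap_tot) if cap_tot.estimate > 0 else np.nan
    )
    out = {
        "capillary_total": cap_tot.estimate,
        "pericyte_total": peri_tot.estimate,
        "pericytes_per_capillary": ratio,
        "coverage_pct": float(np.mean(cov_values)) if cov_values else np.nan,
        "true_capillary_loops": truth.cyclomatic_number(),
        "true_pericytes": peri_truth.total_count,
    }
    if eff.plaque_target is not None:
        section = generate_plaque_section(
            cfg.plaque_shape, eff.plaque_target, seed=_sub_seed(seed, 4)
        )
        res = compute_percent_area(
            section.image,
            section.roi_mask,
            method="fixed",
            threshold=80.0,
            pixel_size_um=section.pixel_size_um,
        )
        out["plaque_pct"] = res.percent_area
        out["true_plaque_pct"] = section.true_area_fraction
    return out, disector_rows


MEASUREMENTS = (
    "capillary_total",
    "pericyte_total",
    "pericytes_per_capillary",
    "coverage_pct",
)


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full demo study; returns the result tables and optionally
    writes them as CSV plus a JSON run log."""
    cfg = config or default_config()
    per_subject, per_disector = [], []
    idx = 0
    for gt in GENOTYPES:
        for ex in EXPOSURES:
            for sv in SURVIVALS:
                eff = cfg.effects(gt, ex, sv)
                for rep in range(cfg.subjects_per_group):
                    sid = f"{gt}-{ex}-{sv}-s{rep + 1}"
                    try:
                        meas, frames = _measure_subject(cfg, eff, _sub_seed(seed, idx))
                    except Exception as err:  # noqa: BLE001
                        raise RuntimeError(
                            f"pipeline stage failed for subject {sid}: {err}"
                        ) from err
                    row = {
                        "subject": sid,
                        "genotype": gt,
                        "exposure": ex,
                        "survival": sv,
                        **meas,
                    }
                    per_subject.append(row)
                    for fr in frames:
                        per_disector.append(
                            {"subject": sid, "genotype": gt, "exposure": ex,
                             "survival": sv, **fr}
                        )
                    idx += 1
    subj = pd.DataFrame(per_subject)
    dis = pd.DataFrame(per_disector)

    group_rows = []
    for meas in MEASUREMENTS + ("plaque_pct",):
        sub = subj.dropna(subset=[meas]) if meas in subj else pd.DataFrame()
        if len(sub) == 0:
            continue
        s = summarize_groups(sub, value=meas, by=["genotype", "exposure", "survival"])
        s.insert(0, "measurement", meas)
        group_rows.append(s)
    groups = pd.concat(group_rows, ignore_index=True)

    anova_rows, posthoc_rows = [], []
    for meas in MEASUREMENTS:
        sub = subj.dropna(subset=[meas])
        # genotype x exposure within each survival stratum
        for sv in SURVIVALS:
            strat = sub[sub["survival"] == sv]
            res = two_way_anova_sidak(strat, value=meas, factor_a="exposure",
                                      factor_b="genotype")
            _collect(res, anova_rows, posthoc_rows, meas, f"genotype_x_exposure@{sv}")
        # exposure x survival within each genotype
        for gt in GENOTYPES:
            strat = sub[sub["genotype"] == gt]
            res = two_way_anova_sidak(strat, value=meas, factor_a="exposure",
                                      factor_b="survival")
            _collect(res, anova_rows, posthoc_rows, meas, f"exposure_x_survival@{gt}")
    if "plaque_pct" in subj:
        tg = subj[subj["genotype"] == "Tg"].dropna(subset=["plaque_pct"]).copy()
        if len(tg):
            tg["group"] = tg["exposure"] + "-" + tg["survival"]
            res = one_way_anova_tukey(tg, value="plaque_pct", group="group")
            _collect(res, anova_rows, posthoc_rows, "plaque_pct", "one_way_Tg")
    anova = pd.DataFrame(anova_rows)
    posthoc = pd.DataFrame(posthoc_rows)

    tables = {
        "per_disector": dis,
        "per_subject": subj,
        "per_group": groups,
        "anova": anova,
        "posthoc": posthoc,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        cfg_text = yaml.safe_dump(asdict(cfg), sort_keys=True)
        log = {
            "seed": seed,
            "nvuquant_version": __version__,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "subjects": int(len(subj)),
            "notes": ["subject n <= 3 per group: under-powered, demo fidelity only"]
            if cfg.subjects_per_group <= 3
            else [],
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return tables


def _collect(res, anova_rows, posthoc_rows, measurement, layout) -> None:
    for _, r in res.table.iterrows():
        anova_rows.append({"measurement": measurement, "layout": layout, **r.to_dict()})
    for _, r in res.posthoc.iterrows():
        posthoc_rows.append({"measurement": measurement, "layout": layout, **r.to_dict()})
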