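"""End-to-end orchestration: generate -> segment -> fit -> stats.

Each stage reads the artifacts of the previous one from disk, so runs are
resumable and any stage can be fed externally produced inputs (e.g. masks
from a neural-network segmenter). The resolved configuration is written
next to the outputs of every run; per-stage object counts are logged so
silent data loss is visible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .cellstats import GroupTable, summarize_groups
from .core import AcquisitionConfig, DecaySpec
from .decayfit import FitOptions, aggregate_roi_decay, fit_biexp, fit_mono
from .errors import FlimError, InsufficientSignalError
from .io import read_mask, read_scene, write_mask, write_scene
from .model import make_irf
from .segmentation import SegmentationParams, segment_cells, segment_nuclei, split_nucleus_cytoplasm
from .synthetic import render_phantom_scene

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("flimcell")

STAGES = ("generate", "segment", "fit", "stats")

PERCELL_COLUMNS = [
    "group", "scene", "cell_label", "compartment", "channel", "model",
    "tau", "tau1", "tau2", "a1", "a2", "tau_m", "chi2_reduced",
    "total_photons", "converged", "flags",
]


class AcquisitionBlock(BaseModel):
    repetition_period: float = 12.5
    n_bins: int = 256
    irf_fwhm: float = 0.2
    irf_offset_fraction: float = 0.10
    photon_rate: float = 1.5e5
    collection_time: float = 60.0
    dark_count_fraction: float = 0.01


class DecaySpecBlock(BaseModel):
    lifetimes: List[float]
    amplitudes: List[float]
    label: str = ""

    def to_spec(self) -> DecaySpec:
        return DecaySpec(tuple(self.lifetimes), tuple(self.amplitudes), self.label)


class GroupBlock(BaseModel):
    # channel -> compartment -> decay spec
    channels: Dict[str, Dict[str, DecaySpecBlock]]

    @field_validator("channels")
    @classmethod
    def _check_compartments(cls, v):
        for ch, comps in v.items():
            for comp in comps:
                if comp not in ("cytoplasm", "nucleus"):
                    raise ValueError(f"unknown compartment {comp!r} in channel {ch!r}")
        return v


class SceneBlock(BaseModel):
    n_cells: int = Field(5, ge=0)
    n_scenes: int = Field(2, ge=1)
    shape: List[int] = [192, 192]
    nucleus_budget_fraction: float = Field(0.4, gt=0, le=1)


class SegmentationBlock(BaseModel):
    mode: Literal["truth", "classical", "external"] = "truth"
    smooth_sigma: float = 2.0
    min_area: int = 50
    nucleus_intensity_fraction: float = 0.6
    intensity_channel: Optional[str] = None  # default: first channel


class FittingBlock(BaseModel):
    # channel -> "mono" | "biexp"
    models: Dict[str, Literal["mono", "biexp"]]
    min_photons_mono: float = 1000.0
    min_photons_biexp: float = 5000.0
    fit_background: bool = True


class StatsBlock(BaseModel):
    low_percentile: float = 1.0
    high_percentile: float = 99.0
    alpha: float = 0.05
    # metrics as "channel/metric", e.g. "nadh/a1"; empty -> all available
    metrics: List[str] = []
    compartments: List[str] = ["cytoplasm", "nucleus"]


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (JSON schema via ``model_json_schema``)."""

    seed: int = Field(0, ge=0, lt=2**31)
    output_dir: str = "flimcell_run"
    acquisition: AcquisitionBlock = AcquisitionBlock()
    scene: SceneBlock = SceneBlock()
    groups: Dict[str, GroupBlock]
    segmentation: SegmentationBlock = SegmentationBlock()
    fitting: FittingBlock
    stats: StatsBlock = StatsBlock()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)


def _scene_seed(base: int, group_index: int, scene_index: int) -> int:
    ss = np.random.SeedSequence([base, group_index, scene_index])
    return int(ss.generate_state(1)[0] % (2**31))


def _scene_dirs(out: Path, config: PipelineConfig):
    for gi, group in enumerate(sorted(config.groups)):
        for si in range(config.scene.n_scenes):
            yield group, gi, si, out / group / f"scene_{si:03d}"


def stage_generate(config: PipelineConfig, out: Path) -> int:
    n_scenes = 0
    for group, gi, si, scene_dir in _scene_dirs(out, config):
        cfg = AcquisitionConfig(
            **config.acquisition.model_dump(),
            seed=_scene_seed(config.seed, gi, si),
        )
        specs = {
            ch: {comp: block.to_spec() for comp, block in comps.items()}
            for ch, comps in config.groups[group].channels.items()
        }
        scene = render_phantom_scene(
            n_cells=config.scene.n_cells,
            cfg=cfg,
            group_specs=specs,
            shape=tuple(config.scene.shape),
            nucleus_budget_fraction=config.scene.nucleus_budget_fraction,
        )
        write_scene(scene, scene_dir)
        n_scenes += 1
        log.info("generate: %s (%d cells)", scene_dir, scene.cell_mask.n_objects)
    return n_scenes


def stage_segment(config: PipelineConfig, out: Path) -> int:
    params = SegmentationParams(
        smooth_sigma=config.segmentation.smooth_sigma,
        min_area=config.segmentation.min_area,
        nucleus_intensity_fraction=config.segmentation.nucleus_intensity_fraction,
    )
    n_cells_total = 0
    for group, gi, si, scene_dir in _scene_dirs(out, config):
        scene = read_scene(scene_dir)
        mode = config.segmentation.mode
        if mode == "truth":
            cells, nuclei = scene.cell_mask, scene.nucleus_mask
        elif mode == "external":
            cells = read_mask(scene_dir / "cells.tif", "cell", "external")
            nuclei = read_mask(scene_dir / "nuclei.tif", "nucleus", "external")
        else:
            ch = config.segmentation.intensity_channel or sorted(scene.stacks)[0]
            intensity = scene.stacks[ch].intensity()
            cells = segment_cells(intensity, params)
            nuclei = segment_nuclei(intensity, cells, params)
        split = split_nucleus_cytoplasm(cells, nuclei)
        write_mask(scene_dir / "cells.tif", cells)
        write_mask(scene_dir / "nuclei.tif", nuclei)
        write_mask(scene_dir / "cytoplasm.tif", split.cytoplasm)
        pd.DataFrame(
            [
                {
                    "cell_label": c,
                    "nucleus_label": split.pairing.get(c, 0),
                    "flagged": c in split.unpaired_cells,
                }
                for c in (int(v) for v in cells.object_labels)
            ],
            columns=["cell_label", "nucleus_label", "flagged"],
        ).to_csv(scene_dir / "pairing.csv", index=False)
        n_cells_total += cells.n_objects
        log.info("segment: %s -> %d cells, %d paired nuclei",
                 scene_dir, cells.n_objects, len(split.pairing))
    return n_cells_total


def stage_fit(config: PipelineConfig, out: Path) -> pd.DataFrame:
    opts = FitOptions(
        min_photons_mono=config.fitting.min_photons_mono,
        min_photons_biexp=config.fitting.min_photons_biexp,
        fit_background=config.fitting.fit_background,
    )
    rows = []
    n_converged = 0
    for group, gi, si, scene_dir in _scene_dirs(out, config):
        scene = read_scene(scene_dir)
        irf = make_irf(scene.config)
        cyto = read_mask(scene_dir / "cytoplasm.tif", "cytoplasm")
        nuclei = read_mask(scene_dir / "nuclei.tif", "nucleus")
        pairing = pd.read_csv(scene_dir / "pairing.csv")
        for ch, model in config.fitting.models.items():
            stack = scene.stacks[ch]
            for _, prow in pairing.iterrows():
                cell = int(prow["cell_label"])
                targets = [("cytoplasm", cyto, cell)]
                if not prow["flagged"] and int(prow["nucleus_label"]) > 0:
                    targets.append(("nucleus", nuclei, int(prow["nucleus_label"])))
                for comp, mask, label in targets:
                    try:
                        curve = aggregate_roi_decay(stack, mask, (label, comp))
                        if model == "mono":
                            fit = fit_mono(curve, irf, opts)
                            row = {
                                "tau": fit.tau, "tau1": np.nan, "tau2": np.nan,
                                "a1": np.nan, "a2": np.nan, "tau_m": np.nan,
                            }
                        else:
                            fit = fit_biexp(curve, irf, opts)
                            row = {
                                "tau": np.nan, "tau1": fit.tau1, "tau2": fit.tau2,
                                "a1": fit.a1, "a2": fit.a2, "tau_m": fit.tau_m,
                            }
                    except (InsufficientSignalError, FlimError) as exc:
                        log.warning("fit skipped %s cell %d %s: %s",
                                    scene_dir, cell, comp, exc)
                        continue
                    row.update(
                        group=group,
                        scene=f"{group}/scene_{si:03d}",
                        cell_label=cell,
                        compartment=comp,
                        channel=ch,
                        model=model,
                        chi2_reduced=fit.chi2_reduced,
                        total_photons=curve.total_photons,
                        converged=fit.converged,
                        flags=";".join(getattr(fit, "flags", ())),
                    )
                    rows.append(row)
                    n_converged += int(fit.converged)
    table = pd.DataFrame(rows, columns=PERCELL_COLUMNS)
    table.to_csv(out / "percell.csv", index=False)
    log.info("fit: %d fits (%d converged)", len(table), n_converged)
    return table


_METRIC_COLUMNS = {"mono": ("tau",), "biexp": ("tau1", "tau2", "a1", "a2", "tau_m")}


def percell_to_group_table(percell: pd.DataFrame) -> GroupTable:
    """Reshape the per-cell fit table into the long-format statistics table."""
    rows = []
    for _, r in percell.iterrows():
        for metric in _METRIC_COLUMNS[r["model"]]:
            value = r[metric]
            if pd.isna(value):
                continue
            rows.append(
                {
                    "group": r["group"],
                    "cell_label": f"{r['scene']}:{r['cell_label']}",
                    "compartment": r["compartment"],
                    "metric": f"{r['channel']}/{metric}",
                    "value": float(value),
                }
            )
    return GroupTable(pd.DataFrame(rows, columns=list(("group", "cell_label",
                                                       "compartment", "metric", "value"))))


def stage_stats(config: PipelineConfig, out: Path) -> pd.DataFrame:
    percell = pd.read_csv(out / "percell.csv")
    if percell.empty:
        (out / "report.md").write_text("# flimcell report\n\nZero cells fitted.\n")
        empty = pd.DataFrame()
        empty.to_csv(out / "summary.csv", index=False)
        log.info("stats: zero cells; empty report written")
        return empty
    table = percell_to_group_table(percell)
    metrics = config.stats.metrics or sorted(set(table.data["metric"]))
    all_summaries = []
    report = ["# flimcell report", ""]
    for metric in metrics:
        for comp in config.stats.compartments:
            sub = table.data[(table.data["metric"] == metric)
                             & (table.data["compartment"] == comp)]
            if sub.empty or sub["group"].nunique() < 2:
                continue
            summary, pairwise = summarize_groups(
                table, metric, compartment=comp,
                low=config.stats.low_percentile,
                high=config.stats.high_percentile,
                alpha=config.stats.alpha,
            )
            summary.insert(0, "metric", metric)
            summary.insert(1, "compartment", comp)
            all_summaries.append(summary)
            report.append(f"## {metric} — {comp}")
            report.append("")
            for _, s in summary.iterrows():
                report.append(
                    f"- {s['group']}: n={s['n']} (trimmed {s['n_trimmed']}), "
                    f"mean={s['mean']:.4g} ± {s['sd']:.3g}, median={s['median']:.4g}, "
                    f"Shapiro W={s['shapiro_w']:.3f} p={s['shapiro_p']:.3g}"
                )
            for _, pw in pairwise.iterrows():
                mark = "SIGNIFICANT" if pw["significant"] else "n.s."
                report.append(
                    f"- {pw['group_a']} vs {pw['group_b']}: t={pw['t']:.3f}, "
                    f"df={pw['df']:.1f}, p={pw['p']:.3g} "
                    f"(adjusted {pw['p_adjusted']:.3g}) [{mark}]"
                )
            report.append("")
    summary_df = (
        pd.concat(all_summaries, ignore_index=True) if all_summaries else pd.DataFrame()
    )
    summary_df.to_csv(out / "summary.csv", index=False)
    (out / "report.md").write_text("\n".join(report) + "\n")
    log.info("stats: %d metric/compartment summaries", len(all_summaries))
    return summary_df


def run_pipeline(config: PipelineConfig, stages=STAGES) -> Path:
    """Run the requested stages in order; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(config.model_dump_json(indent=1))
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        log.info("run: seed=%d stages=%s", config.seed, ",".join(stages))
        for stage in STAGES:
            if stage in stages:
                {"generate": stage_generate,
                 "segment": stage_segment,
                 "fit": stage_fit,
                 "stats": stage_stats}[stage](config, out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
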