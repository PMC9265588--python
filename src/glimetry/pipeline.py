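"""End-to-end pipeline driver: simulate → reconstruct → segment → quantify → stats.

A run is described by a single JSON :class:`RunConfig`; every run writes
the resolved configuration, per-stage provenance and its outputs next to
each other so the directory is self-describing and exactly reproducible
from the recorded seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .acquisition import AcquisitionConfig
from .quantify import build_cell_table
from .reconstruct import integrate_gradient_hilbert, retrieve_phase_gradient
from .segment import (default_phase_threshold, refine_mask,
                      traces_from_fluorescence, voxelize_trace)
from .simulate import (fluorescence_channel, make_phantom, project_phase,
                       simulate_interferograms)
from .stats import comparisons_frame, fit_mass_volume, report_markdown, summarize

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SimulateParams:
    enabled: bool = True
    n_animals_per_group: int = 2
    cells_per_tomogram: int = 5
    shape_zyx: tuple[int, int, int] = (24, 192, 192)
    mean_radius_um: float = 4.0
    night_volume_scale: float = 0.75
    noise_sd: float = 0.01
    gamma: float = 1.0


@dataclass
class SegmentParams:
    trace_source: str = "fluorescence"  # or "file"
    traces_path: str | None = None
    tau: float | None = None            # default: 3x robust background sigma
    slice_step: int = 2


@dataclass
class QuantifyParams:
    alpha_ml_per_g: float = 0.2
    axial_norm: str = "psf"
    groups_csv: str | None = None


@dataclass
class StatsParams:
    alpha_level: float = 0.05
    significance_from: str = "mixed"


@dataclass
class RunConfig:
    out_dir: str = "glimetry-run"
    seed: int = 0
    log_level: str = "INFO"
    stack_path: str | None = None  # input stack when not simulating
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    simulate: SimulateParams = field(default_factory=SimulateParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["acquisition"] = self.acquisition.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sub = {"acquisition": AcquisitionConfig.from_dict,
               "simulate": lambda x: _load_sub(SimulateParams, x),
               "segment": lambda x: _load_sub(SegmentParams, x),
               "quantify": lambda x: _load_sub(QuantifyParams, x),
               "stats": lambda x: _load_sub(StatsParams, x)}
        for key, loader in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = loader(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _load_sub(cls, d: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "shape_zyx" in d:
        d = dict(d, shape_zyx=tuple(d["shape_zyx"]))
    return cls(**d)


def _reconstruct_tomogram(stack):
    gmap = retrieve_phase_gradient(stack)
    return integrate_gradient_hilbert(gmap)


def _segment_and_quantify(phase, traces, groups_row_fn, cfg, config, prefix=""):
    """Voxelize, refine (shared tau over all coarse masks), return masks."""
    masks = []
    for t in traces:
        t.cell_id = f"{prefix}{t.cell_id}"
        masks.append(voxelize_trace(t, phase.phi.shape, config.voxel_um))
    tau = cfg.segment.tau
    if tau is None and masks:
        tau = default_phase_threshold(phase, masks)
    return [refine_mask(m, phase, tau) for m in masks]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured pipeline; returns paths of the main artifacts."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
    acq = cfg.acquisition
    all_masks_phase: list[tuple] = []  # (masks, phase) per tomogram
    groups_rows = []

    if cfg.simulate.enabled:
        stage = "simulate+reconstruct+segment"
        try:
            sim = cfg.simulate
            tomo_dir = out / "tomograms"
            tomo_dir.mkdir(exist_ok=True)
            for gi, (group, scale) in enumerate(
                    [("day", 1.0), ("night", sim.night_volume_scale)]):
                for a in range(sim.n_animals_per_group):
                    animal = f"{group}-a{a + 1}"
                    seed = cfg.seed + 1000 * gi + a + 1
                    acq_a = dataclasses.replace(acq, seed=seed)
                    rng = acq_a.rng()
                    phantom = make_phantom(
                        sim.shape_zyx, sim.cells_per_tomogram,
                        mean_radius_um=sim.mean_radius_um, volume_scale=scale,
                        config=acq_a, rng=rng)
                    phase_true = project_phase(phantom, acq_a)
                    stack = simulate_interferograms(
                        phase_true, gamma=sim.gamma, config=acq_a,
                        noise_sd=sim.noise_sd, rng=rng)
                    gio.write_stack(tomo_dir / f"{animal}_stack.tif", stack)
                    phase = _reconstruct_tomogram(stack)
                    gio.write_tomogram(tomo_dir / f"{animal}_phase.tif", phase)
                    fluo = fluorescence_channel(phantom, rng=rng)
                    traces = traces_from_fluorescence(
                        fluo, slice_step=cfg.segment.slice_step)
                    masks = _segment_and_quantify(
                        phase, traces, None, cfg, acq_a, prefix=f"{animal}-")
                    for m in masks:
                        groups_rows.append({"cell_id": m.cell_id,
                                            "animal_id": animal, "group": group})
                    all_masks_phase.append((masks, phase, acq_a))
            groups = pd.DataFrame(groups_rows)
            gio.write_cells(out / "groups.csv", groups)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e
    else:
        try:
            if cfg.stack_path is None:
                raise ValueError("stack_path required when simulate.enabled=false")
            stack = gio.read_stack(cfg.stack_path)
            acq = stack.config
            phase = _reconstruct_tomogram(stack)
            gio.write_tomogram(out / "phase.tif", phase)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("reconstruct", e) from e
        try:
            if cfg.segment.traces_path is None:
                raise ValueError("segment.traces_path required for file traces")
            traces = gio.read_traces(cfg.segment.traces_path)
            masks = _segment_and_quantify(phase, traces, None, cfg, acq)
            all_masks_phase.append((masks, phase, acq))
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("segment", e) from e
        try:
            if cfg.quantify.groups_csv is None:
                raise ValueError("quantify.groups_csv is required")
            groups = gio.read_groups(cfg.quantify.groups_csv)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("quantify", e) from e

    try:
        tables = [build_cell_table(masks, phase, groups, acq_t,
                                   alpha_ml_per_g=cfg.quantify.alpha_ml_per_g,
                                   axial_norm=cfg.quantify.axial_norm)
                  for masks, phase, acq_t in all_masks_phase]
        cells = pd.concat([t for t in tables if len(t)], ignore_index=True)
        cells = cells.sort_values(["animal_id", "cell_id"]).reset_index(drop=True)
        gio.write_cells(out / "cells.csv", cells)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("quantify", e) from e

    try:
        healthy = cells[~cells["damaged"]]
        comparisons = summarize(healthy, alpha_level=cfg.stats.alpha_level,
                                significance_from=cfg.stats.significance_from)
        comparisons_frame(comparisons).to_csv(out / "comparisons.csv", index=False)
        fits = []
        for g in ("day", "night"):
            try:
                fits.append(fit_mass_volume(healthy, g))
            except ValueError as ve:
                log.warning("volume-mass fit skipped for %s: %s", g, ve)
        pd.DataFrame([f.__dict__ for f in fits]).to_csv(out / "fits.csv", index=False)
        (out / "report.md").write_text(report_markdown(comparisons, fits))
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("stats", e) from e

    return {"cells": str(out / "cells.csv"),
            "comparisons": str(out / "comparisons.csv"),
            "fits": str(out / "fits.csv"),
            "report": str(out / "report.md")}
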