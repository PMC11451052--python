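"""End-to-end pipeline: simulate/ingest → align → proximity → export.

A single structured YAML config drives a full run, so an analysis is
reproducible from one file plus a seed.  Every run writes a manifest
(config snapshot, software version, per-stage row counts, output
inventory, wall time), success or failure.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .alignment import DEFAULT_BIN_NM, DEFAULT_MAX_SHIFT_NM, align_rounds
from .io import LocalizationTable, read_dataset, write_dataset
from .proximity import (
    InsufficientDataError,
    ProximityConfig,
    estimate_precision,
    export_pair_distances,
    median_distance_matrix,
)
from .synthetic import (
    AcquisitionConfig,
    GolgiGeometry,
    TargetLayout,
    build_golgi_model,
    default_acquisition,
    default_geometry,
    default_layouts,
    simulate_experiment,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "ConfigValidationError",
    "load_config",
    "run_pipeline",
    "plot_heatmap",
]


class ConfigValidationError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    mode: str = "simulate"
    seed: int | None = 0
    output_dir: str = "paintprox_out"
    unit: str = "nm"
    pixel_size: float | None = 108.0
    input: dict = field(default_factory=dict)
    model: dict | str = "default"
    acquisition: dict = field(default_factory=dict)
    alignment: dict = field(default_factory=dict)
    proximity: dict = field(default_factory=dict)
    precision: dict = field(default_factory=dict)
    write_localizations: bool = True

    def validate(self) -> None:
        problems: list[str] = []
        if self.mode not in ("simulate", "real"):
            problems.append(f"mode must be 'simulate' or 'real', got '{self.mode}'")
        if self.mode == "simulate" and self.seed is None:
            problems.append("seed is required when mode=simulate")
        if self.mode == "real" and not self.input.get("path"):
            problems.append("input.path is required when mode=real")
        if self.mode == "simulate" and self.input.get("path"):
            problems.append("mode=simulate and input.path are mutually exclusive")
        if self.unit not in ("nm", "pixel"):
            problems.append(f"unit must be 'nm' or 'pixel', got '{self.unit}'")
        if self.unit == "pixel" and not self.pixel_size:
            problems.append("pixel_size is required when unit=pixel")
        cutoff = self.proximity.get("cutoff", 500.0)
        if not cutoff > 0:
            problems.append(f"proximity.cutoff must be > 0, got {cutoff}")
        if self.alignment.get("bin_size", DEFAULT_BIN_NM) <= 0:
            problems.append("alignment.bin_size must be > 0")
        if self.alignment.get("mode", "redundant") not in ("redundant", "reference"):
            problems.append("alignment.mode must be 'redundant' or 'reference'")
        if problems:
            raise ConfigValidationError(problems)

    def build_acquisition(self) -> AcquisitionConfig:
        base = default_acquisition()
        kwargs = {k: v for k, v in self.acquisition.items()}
        if "round_order" in kwargs:
            kwargs["round_order"] = tuple(kwargs["round_order"])
        if kwargs.get("round_shifts") is not None:
            kwargs["round_shifts"] = tuple(tuple(s) for s in kwargs["round_shifts"])
        merged = {**asdict_acq(base), **kwargs}
        return AcquisitionConfig(**merged)

    def build_model(self, seed: int):
        if self.model == "default" or not self.model:
            return build_golgi_model(default_geometry(), default_layouts(), seed)
        spec: Mapping[str, Any] = self.model  # type: ignore[assignment]
        geom_kwargs = dict(spec.get("geometry", {}))
        if "stack_axis" in geom_kwargs:
            geom_kwargs["stack_axis"] = tuple(geom_kwargs["stack_axis"])
        if "field_of_view" in geom_kwargs:
            geom_kwargs["field_of_view"] = tuple(geom_kwargs["field_of_view"])
        geometry = (
            GolgiGeometry(**geom_kwargs) if geom_kwargs else default_geometry()
        )
        raw_layouts = spec.get("layouts")
        if raw_layouts:
            layouts = []
            for entry in raw_layouts:
                entry = dict(entry)
                if entry.get("between") is not None:
                    entry["between"] = tuple(entry["between"])
                layouts.append(TargetLayout(**entry))
        else:
            layouts = default_layouts()
        return build_golgi_model(geometry, layouts, spec.get("seed", seed))


def asdict_acq(cfg: AcquisitionConfig) -> dict:
    return {
        "round_order": cfg.round_order,
        "mean_blinks_per_site": cfg.mean_blinks_per_site,
        "blink_count_law": cfg.blink_count_law,
        "sigma_loc": cfg.sigma_loc,
        "linkage_radius": cfg.linkage_radius,
        "false_rate": cfg.false_rate,
        "erasure_efficiency": cfg.erasure_efficiency,
        "round_shifts": cfg.round_shifts,
        "pixel_size": cfg.pixel_size,
        "frames_per_round": cfg.frames_per_round,
        "mean_event_frames": cfg.mean_event_frames,
    }


@dataclass
class RunManifest:
    """Provenance record written on every run, success or failure."""

    config: dict
    version: str
    seed: int | None
    status: str = "running"
    failed_stage: str | None = None
    stage_rows: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML pipeline config; ``overrides`` (flat dict) wins."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ConfigValidationError([f"unknown config key '{k}'" for k in unknown])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def plot_heatmap(matrix, path: Path, title: str = "Median NN distance (nm)") -> None:
    """Render the median-distance matrix as an annotated heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(matrix), 1.0 + 0.6 * len(matrix)))
    data = matrix.to_numpy(float)
    im = ax.imshow(data, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if np.isfinite(data[i, j]):
                ax.text(j, i, f"{data[i, j]:.0f}", ha="center", va="center", fontsize=7,
                        color="white" if data[i, j] < np.nanmax(data) * 0.6 else "black")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, log=None) -> RunManifest:
    """Execute the configured pipeline and write all exports.

    Stages: simulate or ingest, optional alignment, proximity matrix,
    precision table, heatmap, violin export, registration report, manifest.
    """
    config.validate()
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        version=__version__,
        seed=config.seed,
    )
    _log = log or (lambda msg: None)

    def finish(status: str, stage: str | None = None) -> RunManifest:
        manifest.status = status
        manifest.failed_stage = stage
        manifest.wall_time_s = time.monotonic() - t0
        manifest.write(out / "manifest.json")
        return manifest

    stage = "input"
    try:
        truth = None
        if config.mode == "simulate":
            stage = "simulate"
            model = config.build_model(int(config.seed))
            acq = config.build_acquisition()
            dataset, truth = simulate_experiment(model, acq, int(config.seed))
            _log(f"simulate: {len(dataset)} rounds, "
                 f"{sum(len(t) for t in dataset.values())} localizations")
            if config.write_localizations:
                write_dataset(dataset, out / "localizations", dialect="csv")
                manifest.outputs.append("localizations/")
                truth.support_distances.to_csv(out / "ground_truth_distances.csv", index=False)
                manifest.outputs.append("ground_truth_distances.csv")
        else:
            stage = "ingest"
            inp = config.input
            dataset = read_dataset(
                inp["path"],
                dialect=inp.get("dialect"),
                unit=config.unit,
                pixel_size=config.pixel_size,
                column_map=inp.get("column_map"),
                round_order=inp.get("round_order"),
            )
            _log(f"ingest: {len(dataset)} channels from {inp['path']}")
        manifest.stage_rows[stage] = {k: len(v) for k, v in dataset.items()}

        align_cfg = config.alignment
        if align_cfg.get("enabled", True):
            stage = "align"
            reference = align_cfg.get("reference") or next(iter(dataset))
            dataset, registration = align_rounds(
                dataset,
                reference=reference,
                bin_size=align_cfg.get("bin_size", DEFAULT_BIN_NM),
                max_shift=align_cfg.get("max_shift", DEFAULT_MAX_SHIFT_NM),
                mode=align_cfg.get("mode", "redundant"),
                true_shifts=truth.shifts if truth is not None else None,
            )
            registration.to_frame().to_csv(out / "registration.csv", index=False)
            manifest.outputs.append("registration.csv")
            _log(f"align: reference={reference}")

        stage = "proximity"
        prox_cfg = ProximityConfig(
            cutoff=config.proximity.get("cutoff", 500.0),
            symmetrize=config.proximity.get("symmetrize", False),
            min_pair_count=config.proximity.get("min_pair_count", 50),
        )
        result = median_distance_matrix(dataset, prox_cfg)
        result.median_matrix.to_csv(out / "median_matrix.csv")
        pair_table = export_pair_distances(result)
        pair_table.to_csv(out / "pair_distances.csv", index=False)
        manifest.outputs += ["median_matrix.csv", "pair_distances.csv"]
        manifest.stage_rows["proximity"] = int(len(pair_table))
        _log(f"proximity: {len(pair_table)} retained pair distances")

        stage = "precision"
        rows = []
        for name, table in dataset.items():
            try:
                est = estimate_precision(table, config.precision.get("fit_range", 100.0))
                rows.append((name, est.sigma, est.method, est.n_used))
            except InsufficientDataError:
                rows.append((name, float("nan"), "insufficient_data", 0))
        import pandas as pd

        pd.DataFrame(rows, columns=["channel", "sigma_nm", "method", "n_used"]).to_csv(
            out / "precision.csv", index=False
        )
        manifest.outputs.append("precision.csv")

        stage = "heatmap"
        plot_heatmap(result.median_matrix, out / "heatmap.png")
        manifest.outputs.append("heatmap.png")
    except Exception:
        finish("failed", stage)
        raise
    return finish("ok")
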