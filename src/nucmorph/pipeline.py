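"""End-to-end orchestration: simulate, measure, timelapse, correlate.

Each run mode reads a :class:`RunConfig` (usually from YAML), executes the
corresponding chain of library calls and writes tidy CSV outputs plus a
JSON run manifest recording the config hash, package version, seed and
per-stage record counts (input / kept / discarded with reasons), so any
run can be audited and reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image_io import Calibration, ImageStack, bin_xy, median_filter_channel, read_stack
from .intensity import ChannelMap, QCThresholds, measure_scene
from .morphometry import measure_all
from .population import (
    DEFAULT_DENSITY_WINDOW_UM,
    binned_mean_map,
    build_population_table,
    decile_edges,
    match_live_fixed,
    normalize_table,
    spearman_correlation,
)
from .segmentation import LabelVolume, filter_edge_nuclei, ingest_label_volume
from .synthetic_data import ChannelModel, SceneSpec, simulate_scene, write_scene

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run; see the repository README for keys."""

    output_dir: str = "nucmorph_out"
    stack_path: str | None = None
    labels_path: str | None = None
    fixed_labels_path: str | None = None
    channel_names: list[str] = field(default_factory=lambda: ["dna", "sensor"])
    dna_channel: str = "dna"
    sensor_channel: str = "sensor"
    immunostain_channel: str | None = None
    xy_pitch_um: float = 0.5652
    z_step_um: float = 0.4
    axial_scale_factor: float = 0.860
    binning_factor: int = 1
    median_radius_px: int = 0
    exclude_edge_axes: list[str] = field(default_factory=lambda: ["z"])
    snr_min: float = 2.0
    cv_max: float = 0.8
    hoechst_nc_min: float = 4.0
    density_window_um: float = DEFAULT_DENSITY_WINDOW_UM
    n_baseline: int = 5
    heatmap_bins: int = 10
    seed: int = 0
    # simulate-mode knobs
    n_nuclei: int = 9
    shape_voxels: list[int] = field(default_factory=lambda: [40, 192, 192])
    wrinkle_amplitude: float = 0.0
    sensor_nuclear: float = 200.0
    sensor_cytoplasmic: float = 100.0
    noise_sigma_frac: float = 0.02

    def calibration(self) -> Calibration:
        return Calibration(
            xy_pitch_um=self.xy_pitch_um,
            z_step_nominal_um=self.z_step_um,
            axial_scale_factor=self.axial_scale_factor,
        )

    def channel_map(self) -> ChannelMap:
        return ChannelMap(
            dna=self.dna_channel,
            sensor=self.sensor_channel,
            immunostain=self.immunostain_channel,
        )

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(self.snr_min, self.cv_max, self.hoechst_nc_min)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, mode: str, counts: dict) -> Path:
    manifest = {
        "mode": mode,
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "counts": counts,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def _load_inputs(config: RunConfig) -> tuple[ImageStack, LabelVolume]:
    if not config.stack_path or not config.labels_path:
        raise ValueError("measure mode needs stack_path and labels_path")
    calibration = config.calibration()
    stack = read_stack(config.stack_path, calibration, config.channel_names)
    wanted = {config.dna_channel, config.sensor_channel}
    if config.immunostain_channel:
        wanted.add(config.immunostain_channel)
    missing = wanted - set(stack.channel_names)
    if missing:
        raise ValueError(
            f"configured channels {sorted(missing)} not in stack "
            f"(available: {stack.channel_names})"
        )
    if config.binning_factor > 1:
        stack = bin_xy(stack, config.binning_factor)
    if config.median_radius_px >= 1:
        stack = median_filter_channel(stack, config.dna_channel, config.median_radius_px)
    labels, _ = ingest_label_volume(config.labels_path, stack.calibration)
    if labels.shape != stack.shape:
        raise ValueError(
            f"label volume shape {labels.shape} does not match stack {stack.shape} "
            "(after preprocessing)"
        )
    return stack, labels


def _measure(config: RunConfig, stack: ImageStack, labels: LabelVolume) -> tuple[pd.DataFrame, dict]:
    n_input = labels.n_nuclei
    if config.exclude_edge_axes:
        labels = filter_edge_nuclei(labels, tuple(config.exclude_edge_axes))
    n_interior = labels.n_nuclei
    shape_table = measure_all(labels)
    intensity_table = measure_scene(
        stack, labels, config.channel_map(), config.qc_thresholds()
    )
    dz, dy, dx = stack.calibration.spacing_zyx_um
    nz, ny, nx = stack.shape
    table = build_population_table(
        shape_table,
        intensity_table,
        window_side_um=config.density_window_um,
        field_size_um=(nx * dx, ny * dy),
    )
    reasons: dict[str, int] = {"edge_truncated": n_input - n_interior}
    for codes in table["qc_reasons"].fillna(""):
        for code in filter(None, str(codes).split(";")):
            reasons[code] = reasons.get(code, 0) + 1
    kept = int(table["qc_pass"].fillna(False).sum())
    counts = {
        "input": n_input,
        "kept": kept,
        "discarded": n_input - kept,
        "discarded_reasons": reasons,
    }
    return table, counts


def run_measure(config: RunConfig) -> Path:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, labels = _load_inputs(config)
    table, counts = _measure(config, stack, labels)
    _write_csv(table, outdir / "per_nucleus.csv")
    return _write_manifest(outdir, config, "measure", counts)


def run_simulate(config: RunConfig) -> Path:
    outdir = Path(config.output_dir)
    spec = SceneSpec(
        shape_voxels=tuple(config.shape_voxels),
        calibration=config.calibration(),
        n_nuclei=config.n_nuclei,
        wrinkle_amplitude=config.wrinkle_amplitude,
        channels=ChannelModel(
            sensor_nuclear=config.sensor_nuclear,
            sensor_cytoplasmic=config.sensor_cytoplasmic,
            gaussian_sigma_frac=config.noise_sigma_frac,
        ),
        density_window_um=config.density_window_um,
        seed=config.seed,
    )
    scene = simulate_scene(spec)
    write_scene(scene, outdir)
    counts = {"input": spec.n_nuclei, "kept": scene.labels.n_nuclei, "discarded_reasons": {}}
    return _write_manifest(outdir, config, "simulate", counts)


def run_timelapse(config: RunConfig, measured_csv: str | Path) -> Path:
    """Normalize per-nucleus series in a tidy (nucleus_id, timepoint) table."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(measured_csv, comment="#")
    value_columns = [
        c for c in ("volume_um3", "solidity", "sencyt_index") if c in table.columns
    ]
    if not value_columns or "timepoint" not in table.columns:
        raise ValueError(
            "timelapse input needs a 'timepoint' column and at least one of "
            "volume_um3/solidity/sencyt_index"
        )
    normalized = normalize_table(table, value_columns, n_baseline=config.n_baseline)
    _write_csv(normalized, outdir / "timelapse_normalized.csv")
    counts = {
        "input": int(table["nucleus_id"].nunique()),
        "kept": int(normalized["nucleus_id"].nunique()),
        "discarded_reasons": {"short_series": normalized.attrs.get("n_dropped_short", 0)},
    }
    return _write_manifest(outdir, config, "timelapse", counts)


def run_correlate(config: RunConfig) -> Path:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, labels = _load_inputs(config)
    table, counts = _measure(config, stack, labels)
    _write_csv(table, outdir / "per_nucleus.csv")

    passed = table[table["qc_pass"].fillna(False)]
    correlations = []
    for x_name, y_name in [
        ("solidity", "sencyt_index"),
        ("density", "sencyt_index"),
        ("density", "solidity"),
    ]:
        sub = passed[[x_name, y_name]].dropna()
        if len(sub) >= 3:
            res = spearman_correlation(sub[x_name].to_numpy(), sub[y_name].to_numpy())
            correlations.append(
                {"x": x_name, "y": y_name, "rho": res.rho, "pvalue": res.pvalue,
                 "n": res.n, "method": res.method}
            )
    _write_csv(pd.DataFrame(correlations), outdir / "correlations.csv")

    sub = passed[["solidity", "density", "sencyt_index"]].dropna()
    if len(sub) >= config.heatmap_bins:
        x_edges = decile_edges(sub["solidity"].to_numpy(), config.heatmap_bins)
        y_edges = decile_edges(sub["density"].to_numpy(), config.heatmap_bins)
        mean, count = binned_mean_map(
            sub["solidity"].to_numpy(), sub["density"].to_numpy(),
            sub["sencyt_index"].to_numpy(), x_edges, y_edges,
        )
        _write_heatmap(outdir / "index_by_solidity_density.csv", mean, x_edges, y_edges)
        _write_heatmap(outdir / "count_by_solidity_density.csv", count, x_edges, y_edges)

    if config.fixed_labels_path:
        fixed, _ = ingest_label_volume(config.fixed_labels_path, stack.calibration)
        match = match_live_fixed(labels, fixed)
        _write_csv(match.pairs, outdir / "live_fixed_pairs.csv")
        counts["matched_pairs"] = int(len(match.pairs))
    return _write_manifest(outdir, config, "correlate", counts)


def _write_csv(table: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nucmorph {__version__}; lengths um, volumes um^3, intensities a.u.\n")
        table.to_csv(fh, index=False)


def _write_heatmap(path: Path, grid: np.ndarray, x_edges: np.ndarray, y_edges: np.ndarray) -> None:
    frame = pd.DataFrame(
        grid,
        index=[f"{a:.4g}..{b:.4g}" for a, b in zip(x_edges[:-1], x_edges[1:])],
        columns=[f"{a:.4g}..{b:.4g}" for a, b in zip(y_edges[:-1], y_edges[1:])],
    )
    frame.to_csv(path)


def run_pipeline(config: RunConfig, mode: str, **kwargs) -> Path:
    """Dispatch a run; returns the manifest path."""
    runners = {
        "measure": run_measure,
        "simulate": run_simulate,
        "timelapse": run_timelapse,
        "correlate": run_correlate,
    }
    if mode not in runners:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(runners)}")
    return runners[mode](config, **kwargs)
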