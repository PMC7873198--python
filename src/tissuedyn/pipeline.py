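"""End-to-end orchestration: simulate -> preprocess -> segment -> quantify
-> spatial -> dynamics -> qpcr, driven by one configuration mapping.

Every run writes a manifest echoing all parameters, derived seeds, and
SHA-256 hashes of outputs (relative paths, no timestamps), so re-running
a deterministic configuration reproduces outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import assemble_timecourse, classify_dynamics, timecourse_table
from .preprocess import (
    background_subtract,
    estimate_background,
    estimate_flatfield,
    flatfield_correct,
    write_channels,
    write_truth,
)
from .qpcr import fold_changes
from .quant import (
    flag_autofluorescent,
    normalize_cells,
    quantify_cells,
    summarize_tissue,
)
from .segment import segment_nuclei
from .spatial import assign_crypt_positions, position_time_heatmap, positional_profile
from .synthetic import (
    SCHEDULES,
    SyntheticImageParams,
    annotations_from_truth,
    generate_qpcr_table,
    generate_tissue_image,
    params_at_time,
)

ALL_STAGES = (
    "simulate",
    "preprocess",
    "segment",
    "quantify",
    "spatial",
    "dynamics",
    "qpcr",
)

CELL_TABLE_COLUMNS = [
    "sample",
    "label",
    "row",
    "col",
    "area",
    "topk_dapi",
    "topk_signal",
    "topk_costain",
    "topk_control",
    "normalized_signal",
    "autofluor_flag",
    "crypt_id",
    "position_index",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration (parsed YAML mapping).

    See ``examples`` in the repository README for the schema; every knob
    is echoed into the run manifest.
    """

    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES[:-1]))
    simulate: Dict[str, Any] = field(default_factory=dict)
    preprocess: Dict[str, Any] = field(default_factory=dict)
    segment: Dict[str, Any] = field(default_factory=dict)
    quantify: Dict[str, Any] = field(default_factory=dict)
    spatial: Dict[str, Any] = field(default_factory=dict)
    dynamics: Dict[str, Any] = field(default_factory=dict)
    qpcr: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}; valid: {list(ALL_STAGES)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)

    def to_mapping(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def derive_seed(base: int, *indices: int) -> int:
    """Deterministic child seed < 2**31 for sample ``indices``."""
    h = hashlib.sha256(("/".join(map(str, (base, *indices)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Dict[str, Any]:
    """Run the configured stages on synthetic data; return the manifest.

    Raises on the first stage failure, naming the stage and sample.
    Outputs: per-sample channel TIFFs plus truth, label masks, one pooled
    cell table CSV, per-(tissue, time) positional profiles, position x
    time heatmaps, a classified time-course table, fold-change tables,
    and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    manifest: Dict[str, Any] = {
        "tool": "tissuedyn",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_mapping(),
        "derived_seeds": {},
        "outputs": {},
    }

    cell_tables: List[pd.DataFrame] = []
    # per (tissue, time): {sample_name: unflagged normalized values}
    summary_inputs: Dict[tuple, Dict[str, np.ndarray]] = {}
    positioned_cells: Dict[tuple, List[pd.DataFrame]] = {}
    tissue_specs = config.simulate.get("tissues", [])
    timepoints = [float(t) for t in config.simulate.get("timepoints", [0.0])]
    n_samples = int(config.simulate.get("samples_per_timepoint", 1))
    base_overrides = dict(config.simulate.get("params", {}))

    if "simulate" in stages:
        for ti, spec in enumerate(tissue_specs):
            tissue = spec["name"]
            schedule = spec.get("schedule", "sustained")
            if isinstance(schedule, str) and schedule not in SCHEDULES:
                raise ValueError(
                    f"simulate: unknown schedule {schedule!r} for tissue {tissue!r}"
                )
            overrides = {**base_overrides, **spec.get("params", {})}
            base_params = SyntheticImageParams(**overrides)
            for tj, t in enumerate(timepoints):
                for s in range(n_samples):
                    seed_i = derive_seed(config.seed, ti, tj, s)
                    name = f"{tissue}_t{t:g}_s{s}"
                    manifest["derived_seeds"][name] = seed_i
                    params = params_at_time(base_params, t, schedule, seed_i)
                    channels, truth = generate_tissue_image(params)
                    sample_dir = out / "images" / name
                    sample_dir.mkdir(parents=True, exist_ok=True)
                    write_channels(sample_dir / "channels.tif", channels)
                    write_truth(sample_dir / "truth", truth)

                    result = _process_sample(
                        config, stages, channels, truth, name, sample_dir
                    )
                    if result is None:
                        continue
                    cells, positioned = result
                    cell_tables.append(cells)
                    unflagged = cells[~cells["autofluor_flag"]]
                    if len(unflagged) == 0:
                        raise ValueError(
                            f"quantify: sample {name!r} has zero unflagged cells"
                        )
                    summary_inputs.setdefault((tissue, t), {})[name] = unflagged[
                        "normalized_signal"
                    ].to_numpy()
                    if positioned is not None:
                        positioned_cells.setdefault((tissue, t), []).append(positioned)

    if cell_tables:
        all_cells = pd.concat(cell_tables, ignore_index=True)
        for col in CELL_TABLE_COLUMNS:
            if col not in all_cells.columns:
                all_cells[col] = pd.NA
        all_cells = all_cells[CELL_TABLE_COLUMNS]
        all_cells.to_csv(out / "cell_table.csv", index=False)

    if "spatial" in stages and positioned_cells:
        profiles_by_tissue: Dict[str, Dict[float, pd.DataFrame]] = {}
        window = int(config.spatial.get("window", 5))
        for (tissue, t), frames in sorted(positioned_cells.items()):
            pooled = pd.concat(frames, ignore_index=True)
            profile = positional_profile(pooled, window=window)
            profile.to_csv(out / f"profile_{tissue}_t{t:g}.csv", index=False)
            profiles_by_tissue.setdefault(tissue, {})[t] = profile
        for tissue, by_time in sorted(profiles_by_tissue.items()):
            if len(by_time) > 1:
                heatmap = position_time_heatmap(by_time)
                heatmap.to_csv(out / f"heatmap_{tissue}.csv")

    if "dynamics" in stages and summary_inputs:
        rows = []
        spec_by_name = {s["name"]: s for s in tissue_specs}
        for (tissue, t), samples in sorted(summary_inputs.items()):
            p = float(spec_by_name[tissue].get("percentile", 0.10))
            ts = summarize_tissue(samples, tissue, timepoint=t, treatment="IR", p=p)
            rows.append(
                {
                    "tissue": ts.tissue,
                    "treatment": ts.treatment,
                    "time_h": ts.timepoint,
                    "summary": ts.summary_value,
                    "sem": ts.sem,
                    "n_cells": ts.n_cells,
                }
            )
        summary_df = pd.DataFrame(rows)
        tcs = []
        for tissue in sorted({r["tissue"] for r in rows}):
            tc = assemble_timecourse(summary_df, tissue, treatment="IR")
            classify_dynamics(
                tc,
                late_time=float(config.dynamics.get("late_time", 5.0)),
                ratio_threshold=float(config.dynamics.get("ratio_threshold", 0.5)),
            )
            tcs.append(tc)
        timecourse_table(tcs).to_csv(out / "timecourse.csv", index=False)

    if "qpcr" in stages and config.qpcr:
        q = config.qpcr
        table = generate_qpcr_table(
            genes=q["genes"],
            conditions=q["conditions"],
            true_fold_changes=q.get("true_fold_changes", {}),
            control_condition=q["control_condition"],
            reference_gene=q.get("reference_gene", "ACTB"),
            noise_sd=float(q.get("noise_sd", 0.2)),
            replicates=int(q.get("replicates", 2)),
            seed=derive_seed(config.seed, 9999),
        )
        table.to_csv(out / "ct_table.csv", index=False)
        fc = fold_changes(
            table,
            control_condition=q["control_condition"],
            reference_gene=q.get("reference_gene", "ACTB"),
        )
        fc.to_csv(out / "fold_changes.csv", index=False)

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def preprocess_channels(
    channels: Dict[str, Any],
    background: Any = "truth",
    flatfield: Any = "truth",
    truth=None,
) -> Dict[str, Any]:
    """Background-then-flat-field correction of all channels.

    ``background``/``flatfield`` may be ``"truth"`` (use the generator's
    known values; synthetic runs only), ``"estimate"`` (robust floor of
    the image / smoothed control channel), a number (background only), or
    ``"none"``.
    """
    if background == "truth" or flatfield == "truth":
        if truth is None:
            raise ValueError("'truth' correction requires ground truth")
    out = {}
    field = None
    if flatfield == "truth":
        field = truth.illumination_field
    elif flatfield == "estimate":
        field = estimate_flatfield(channels["control"])
    elif flatfield not in ("none", None):
        raise ValueError(f"unknown flatfield mode {flatfield!r}")
    for role, channel in channels.items():
        if background == "truth":
            bg = truth.background_level
        elif background == "estimate":
            bg = estimate_background(channel)
        elif background in ("none", None):
            bg = 0.0
        else:
            bg = float(background)
        corrected = background_subtract(channel, bg)
        if field is not None:
            corrected = flatfield_correct(corrected, field)
        out[role] = corrected
    return out


def _process_sample(config, stages, channels, truth, name, sample_dir):
    """Preprocess, segment, quantify and position one sample.

    Returns (cell table, positioned cells or None), or None when the
    configured stages stop before quantification.
    """
    if "preprocess" in stages:
        channels = preprocess_channels(
            channels,
            background=config.preprocess.get("background", "truth"),
            flatfield=config.preprocess.get("flatfield", "truth"),
            truth=truth,
        )
    if "segment" not in stages:
        return None
    seg_cfg = config.segment
    mask = segment_nuclei(
        channels["dapi"],
        min_area=float(seg_cfg.get("min_area", 20)),
        max_area=float(seg_cfg.get("max_area", 2000)),
        smoothing_sigma=float(seg_cfg.get("smoothing_sigma", 1.0)),
    )
    import tifffile

    tifffile.imwrite(sample_dir / "mask.tif", mask.label_map.astype(np.uint16))
    if "quantify" not in stages:
        return None
    qcfg = config.quantify
    cells = quantify_cells(mask, channels, k=int(qcfg.get("k", 10)))
    cells = flag_autofluorescent(cells, k_mad=float(qcfg.get("mad_k", 5.0)))
    cells = normalize_cells(cells, mode=qcfg.get("normalize", "control"))
    cells.insert(0, "sample", name)

    positioned = None
    if "spatial" in stages:
        annotations = annotations_from_truth(truth, label_map=mask.label_map)
        positioned = assign_crypt_positions(cells, annotations)
        positioned = positioned[~positioned["autofluor_flag"]]
        cells = assign_crypt_positions(cells, annotations)
    return cells, positioned


def load_and_run(config_path: str | Path, out_dir: str | Path,
                 seed: Optional[int] = None) -> Dict[str, Any]:
    """Load a YAML config, optionally override the seed, and run."""
    config = RunConfig.from_yaml(config_path)
    if seed is not None:
        config.seed = int(seed)
    return run_pipeline(config, out_dir)
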