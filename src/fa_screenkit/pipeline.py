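"""Stage orchestration: chain generators and analysis stages into
reproducible runs.

Every run writes its effective config (YAML) next to its outputs and stamps
each CSV with the config hash and seed; rerunning with an identical config
reproduces byte-identical tables.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import io as fio
from . import quant, screen, synthetic

log = logging.getLogger("fa_screenkit")


def _prepare(config: fio.RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.save(out / "run_config.yaml")
    return out


def run_pipeline(config: fio.RunConfig) -> Dict[str, Path]:
    """Execute the configured stage; returns the written artifact paths."""
    stages = {
        "simulate-screen": simulate_screen_stage,
        "quantify": quantify_stage,
        "dynamics": dynamics_stage,
    }
    if config.stage not in stages:
        raise ValueError(f"unknown stage {config.stage!r}; "
                         f"choose from {sorted(stages)}")
    return stages[config.stage](config)


def simulate_screen_stage(config: fio.RunConfig) -> Dict[str, Path]:
    """Readout-level screen simulation followed by full screen statistics."""
    out = _prepare(config)
    chash = config.config_hash
    plates, _truth = synthetic.simulate_screen_readouts(
        n_plates=config.n_plates, n_sample_wells=config.n_sample_wells,
        effects={}, seed=config.seed)
    report = screen.screen_report(plates, config.thresholds,
                                  reference=config.zscore_reference)
    artifacts = {}
    table = pd.concat(plates, ignore_index=True)
    for name, df in (("plate_table", table), ("plate_qc", report.plate_qc),
                     ("zscores", report.zscores), ("hits", report.hits),
                     ("exclusions", report.exclusions)):
        path = out / f"{name}.csv"
        fio.write_table(df, path, config_hash=chash, seed=config.seed)
        artifacts[name] = path
    log.info("simulate-screen: %d plates, %d hits", len(plates),
             int(report.hits["hit"].sum()))
    return artifacts


def quantify_stage(config: fio.RunConfig) -> Dict[str, Path]:
    """Quantify every field TIFF in ``input_dir``; optionally aggregate to a
    plate table when a layout is configured."""
    if not config.input_dir:
        raise ValueError("quantify stage requires input_dir")
    out = _prepare(config)
    chash = config.config_hash
    paths = sorted(Path(config.input_dir).glob("*.tif*"))
    if not paths:
        raise ValueError(f"no TIFF fields found in {config.input_dir}")
    quants = []
    rows = []
    for path in paths:
        field = fio.read_image(path)
        fq = quant.quantify_field(field, config.quant)
        quants.append(fq)
        rows.append(dict(
            well_id=fq.well_id, field_id=fq.field_id, n_fas=fq.n_fas,
            n_nuclei=fq.n_nuclei,
            fas_per_cell=np.nan if fq.fas_per_cell is None else fq.fas_per_cell,
            fa_area_mean=(np.mean(fq.fa_areas) if fq.fa_areas else np.nan),
            focus_score=fq.focus_score,
            raw_object_count=fq.raw_object_count,
            focus_fail=fq.qc["focus_fail"],
            oversegmented=fq.qc["oversegmented"],
            low_nuclei=fq.qc["low_nuclei"],
            excluded=fq.excluded,
            source=path.name))
        if fq.excluded:
            log.info("field %s/%s excluded: %s", fq.well_id, fq.field_id,
                     [k for k, v in fq.qc.items() if v])
    artifacts = {}
    field_path = out / "field_quant.csv"
    fio.write_table(pd.DataFrame(rows), field_path, config_hash=chash,
                    seed=config.seed)
    artifacts["field_quant"] = field_path
    if config.layout_path:
        layout = fio.read_layout(config.layout_path)
        table = screen.aggregate_wells(quants, layout)
        plate_path = out / "plate_table.csv"
        fio.write_table(table, plate_path, config_hash=chash,
                        seed=config.seed)
        artifacts["plate_table"] = plate_path
    return artifacts


def dynamics_stage(config: fio.RunConfig) -> Dict[str, Path]:
    """Drift-correct, crop, track and summarize every stack in input_dir."""
    if not config.input_dir:
        raise ValueError("dynamics stage requires input_dir")
    out = _prepare(config)
    chash = config.config_hash
    paths = sorted(Path(config.input_dir).glob("*.tif*"))
    if not paths:
        raise ValueError(f"no TIFF stacks found in {config.input_dir}")
    track_rows = []
    summary_rows = []
    for path in paths:
        movie = fio.read_stack(path)
        corrected, _offsets = dyn.correct_drift(movie, config.dynamics)
        cropped = dyn.autocrop(corrected, config.dynamics)
        tracks = dyn.track_fas(cropped, config.dynamics)
        summary = dyn.summarize_dynamics(tracks, cropped.n_frames,
                                         cropped.frame_interval,
                                         config.dynamics)
        for tr in tracks:
            for i, frame in enumerate(tr.frames):
                track_rows.append(dict(
                    movie=path.name, track_id=tr.track_id, frame=frame,
                    area=tr.areas[i], intensity=tr.intensities[i],
                    origin=tr.origin, end=tr.end))
        summary_rows.append(dict(
            movie=path.name, n_tracks=summary.n_tracks,
            assembly_rate=summary.assembly_rate,
            disassembly_rate=summary.disassembly_rate,
            novel_fas_total=summary.novel_fas_total,
            novel_fas_per_frame=summary.novel_fas_per_frame))
    artifacts = {}
    for name, rows in (("tracks", track_rows), ("dynamics_summary",
                                                summary_rows)):
        path = out / f"{name}.csv"
        fio.write_table(pd.DataFrame(rows), path, config_hash=chash,
                        seed=config.seed)
        artifacts[name] = path
    return artifacts
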