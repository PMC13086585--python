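"""Shared I/O: TIFF fields and stacks, CSV tables, layout and run configs.

Tables are long-format CSV with a ``schema_version`` column; every pipeline
output directory also receives the effective run config (YAML) and its hash
so reruns are reproducible and attributable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import (ROLES, DynamicsParams, FAQuantParams, FieldImage,
                        Movie, MorphologyParams, ScreenThresholds)

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_field(field: FieldImage, path) -> None:
    """Write a multi-channel field as a multi-page TIFF (one page per
    channel, channel names in the JSON image description)."""
    path = Path(path)
    names = sorted(field.channels)
    stack = np.stack([np.asarray(field.channels[n]) for n in names])
    meta = {"channels": names, "well_id": field.well_id,
            "field_id": field.field_id}
    if field.pixel_size_um is not None:
        meta["pixel_size_um"] = field.pixel_size_um
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps(meta))


def read_image(path, channel_names: Optional[List[str]] = None) -> FieldImage:
    """Read a field TIFF written by :func:`write_field` (or any single- or
    multi-page TIFF with ``channel_names`` given explicitly)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    meta: Dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if arr.ndim == 2:
        arr = arr[None]
    names = channel_names or meta.get("channels")
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    if len(names) != arr.shape[0]:
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but {len(names)} channel names")
    return FieldImage(channels=dict(zip(names, arr)),
                      well_id=str(meta.get("well_id", "")),
                      field_id=str(meta.get("field_id", "")),
                      pixel_size_um=meta.get("pixel_size_um"))


def write_movie(movie: Movie, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(movie.frames),
                     photometric="minisblack",
                     description=json.dumps(
                         {"frame_interval": movie.frame_interval}))


def read_stack(path, frame_interval: Optional[float] = None) -> Movie:
    """Read a time-lapse TIFF stack; the frame interval comes from the file
    metadata when present and can be overridden by the argument."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    interval = frame_interval
    if interval is None and desc:
        try:
            interval = json.loads(desc).get("frame_interval")
        except (json.JSONDecodeError, TypeError):
            interval = None
    return Movie(frames=arr, frame_interval=float(interval or 2.0))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, config_hash: str = "",
                seed: Optional[int] = None) -> None:
    out = df.copy()
    out["schema_version"] = SCHEMA_VERSION
    if config_hash:
        out["config_hash"] = config_hash
    if seed is not None:
        out["seed"] = seed
    out.to_csv(Path(path), index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path)
    if "schema_version" in df.columns:
        versions = set(df["schema_version"].astype(str))
        if versions - {SCHEMA_VERSION}:
            raise ValueError(f"{path}: unsupported schema versions {versions}")
    return df


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

def read_layout(path) -> Dict[str, Tuple[str, Optional[str]]]:
    """Read a plate layout CSV with columns ``well_id, role[, gene]``."""
    df = read_table(path)
    for col in ("well_id", "role"):
        if col not in df.columns:
            raise ValueError(f"layout file lacks column {col!r}")
    if df["well_id"].duplicated().any():
        dups = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
        raise ValueError(f"duplicate wells in layout: {dups[:5]}")
    layout = {}
    for _, row in df.iterrows():
        role = row["role"]
        if role not in ROLES:
            raise ValueError(f"well {row['well_id']}: unknown role {role!r}")
        gene = row.get("gene")
        layout[row["well_id"]] = (role,
                                  None if pd.isna(gene) else str(gene))
    return layout


def write_layout(layout: Dict[str, Tuple[str, Optional[str]]], path) -> None:
    rows = [dict(well_id=w, role=r, gene=g)
            for w, (r, g) in sorted(layout.items())]
    write_table(pd.DataFrame(rows), path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    stage: str = "simulate-screen"
    input_dir: Optional[str] = None
    output_dir: str = "out"
    layout_path: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"
    n_plates: int = 2
    n_sample_wells: int = 100
    quant: FAQuantParams = field(default_factory=FAQuantParams)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    zscore_reference: str = "sample"

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        data = dict(data)
        for key, typ in (("quant", FAQuantParams),
                         ("thresholds", ScreenThresholds),
                         ("morphology", MorphologyParams),
                         ("dynamics", DynamicsParams)):
            if key in data and isinstance(data[key], dict):
                block = dict(data[key])
                if key == "quant" and isinstance(
                        block.get("circularity_range"), list):
                    block["circularity_range"] = tuple(
                        block["circularity_range"])
                data[key] = typ(**block)
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config not found: {path}")
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Filesystem locations (input/output/layout paths) are excluded so the
        same analysis writes identically stamped tables wherever it runs.
        """
        data = self.to_dict()
        for key in ("input_dir", "output_dir", "layout_path"):
            data.pop(key, None)
        payload = json.dumps(_plain(data), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML/JSON round trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
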