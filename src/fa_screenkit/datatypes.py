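"""Shared domain types for the focal-adhesion screening toolkit.

All images are 2-D ``numpy`` arrays indexed ``(row, col)`` with the origin at
the top-left corner and 0-based pixel indices.  Areas are pixel counts,
lengths are pixels, times are minutes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

#: closed vocabulary of well roles used throughout the screen modules
ROLES = ("sample", "mock", "neg_ctrl", "pos_ctrl", "death_ctrl")


@dataclass
class FieldImage:
    """One imaged field: named 2-D intensity channels plus well/field identity.

    Channels are keyed by name (``nucleus``, ``fa``, and optionally ``actin``,
    ``cytoplasm``, ``membrane``); all channels must share the same shape and
    contain finite, non-negative intensities.
    """

    channels: Dict[str, np.ndarray]
    well_id: str = ""
    field_id: str = ""
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2-D, got shape {shape}")
        for name, img in self.channels.items():
            arr = np.asarray(img)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative values")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"field {self.well_id}/{self.field_id}: missing channel {name!r}; "
                f"available: {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class Movie:
    """An ordered time-lapse stack of single-channel frames."""

    frames: np.ndarray  # (n_frames, rows, cols)
    frame_interval: float = 2.0  # minutes

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError(
                "Movie requires a (n_frames, rows, cols) stack with >= 2 frames"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Total covered time span in minutes."""
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class FAQuantParams:
    """Parameters of the FA/nuclei quantification pipeline.

    Two dialects are supported: ``screen`` (plate-based primary screen) and
    ``percell`` (per-cell confocal analysis).  Filter "radius" follows the
    Fiji convention: the median radius defines a disc neighbourhood while the
    Gaussian radius is used directly as sigma in pixels.
    Size-filter bounds are inclusive: objects of exactly ``min_area`` or
    ``max_area`` pixels are retained.
    """

    median_radius: int = 2
    rollball_radius: float = 1.0
    sliding_paraboloid: bool = True
    min_area: int = 50
    max_area: int = 5000
    circularity_range: Optional[Tuple[float, float]] = None
    nucleus_smooth_radius: float = 20.0
    maxima_threshold: float = 100.0
    edge_exclude_nuclei: bool = False
    edge_margin: int = 10
    otsu_bins: int = 256
    focus_threshold: float = 0.03
    focus_window: int = 64
    max_raw_objects: int = 20_000
    min_nuclei: int = 3  # fields with two nuclei or fewer are excluded
    mode: str = "screen"

    @classmethod
    def screen(cls, **overrides) -> "FAQuantParams":
        """Primary-screen dialect: 50-5000 px size window, no circularity."""
        return cls(mode="screen", min_area=50, max_area=5000,
                   circularity_range=None, edge_exclude_nuclei=False,
                   **overrides)

    @classmethod
    def percell(cls, **overrides) -> "FAQuantParams":
        """Per-cell dialect: 50-500 px, circularity 0.00-0.95, edge exclusion."""
        return cls(mode="percell", min_area=50, max_area=500,
                   circularity_range=(0.0, 0.95), edge_exclude_nuclei=True,
                   **overrides)


@dataclass
class FARecord:
    """One segmented focal adhesion."""

    label: int
    area: int
    centroid: Tuple[float, float]  # (row, col)
    circularity: float  # 4*pi*area/perimeter**2, clipped to <= 1


@dataclass
class FieldQuant:
    """Per-field quantification readout with QC flags."""

    n_fas: int
    fa_areas: List[int]
    n_nuclei: int
    fas_per_cell: Optional[float]
    qc: Dict[str, bool] = field(default_factory=dict)
    focus_score: Optional[float] = None
    raw_object_count: int = 0
    well_id: str = ""
    field_id: str = ""

    @property
    def excluded(self) -> bool:
        return any(self.qc.values())


@dataclass
class ScreenThresholds:
    """Hit-calling and QC thresholds of the screening statistics."""

    z_count_threshold: float = 4.2
    z_area_threshold: float = 3.5
    viability_min_cells: int = 50
    confirm_min_increase: float = 0.30
    zprime_warn: float = 0.5

    def __post_init__(self) -> None:
        for name in ("z_count_threshold", "z_area_threshold",
                     "viability_min_cells", "confirm_min_increase",
                     "zprime_warn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MorphologyParams:
    """Parameters for spreading-area and protrusive-area morphometry."""

    spread_blur: float = 4.0
    spread_min_object: int = 500
    prot_blur: float = 1.0
    marker_blur: float = 25.0
    marker_prominence: float = 100.0
    nucleus_smooth_radius: float = 20.0
    nucleus_prominence: float = 100.0

    def __post_init__(self) -> None:
        if min(self.spread_blur, self.prot_blur, self.marker_blur) <= 0:
            raise ValueError("all blur sigmas must be > 0")
        if self.spread_min_object < 1:
            raise ValueError("spread_min_object must be >= 1")


@dataclass
class CellMorphology:
    """Per-cell area partition: total = elevated + protrusive (exact)."""

    cell_label: int
    total_area: int
    elevated_area: int
    protrusive_area: int

    def __post_init__(self) -> None:
        if self.total_area != self.elevated_area + self.protrusive_area:
            raise ValueError("area partition identity violated")
        if self.protrusive_area < 0 or self.elevated_area > self.total_area:
            raise ValueError("elevated area exceeds total area")


@dataclass
class DynamicsParams:
    """Parameters of the time-lapse FA dynamics pipeline."""

    drift_min_grey: float = 120.0
    drift_max_shift: int = 20
    crop_blur: float = 15.0
    seg_threshold_sd: float = 2.0
    min_fa_size: int = 10
    min_phase_frames: int = 5
    dog_sigma_small: float = 0.0  # 0 = no smoothing of the kept band
    dog_sigma_large: float = 10.0

    def __post_init__(self) -> None:
        if self.seg_threshold_sd <= 0:
            raise ValueError("seg_threshold_sd must be > 0")
        if self.min_fa_size < 1:
            raise ValueError("min_fa_size must be >= 1")


# track origin / end annotations
ORIGIN_BIRTH = "birth"
ORIGIN_FIRST_FRAME = "first_frame"
ORIGIN_FROM_SPLIT = "from_split"
END_DEATH = "death"
END_LAST_FRAME = "last_frame"
END_INTO_MERGE = "into_merge"


@dataclass
class FATrack:
    """One adhesion's lifetime across a contiguous frame range."""

    track_id: int
    start_frame: int
    areas: List[int]
    intensities: List[float]
    centroids: List[Tuple[float, float]]
    origin: str = ORIGIN_BIRTH
    end: str = END_DEATH

    @property
    def n_frames(self) -> int:
        return len(self.areas)

    @property
    def end_frame(self) -> int:
        """Last frame index (inclusive) on which the track is present."""
        return self.start_frame + self.n_frames - 1

    @property
    def frames(self) -> range:
        return range(self.start_frame, self.end_frame + 1)


@dataclass
class DynamicsSummary:
    """Per-movie summary of FA dynamics."""

    assembly_rate: Optional[float]  # per minute, median over qualifying tracks
    disassembly_rate: Optional[float]  # per minute (magnitude)
    novel_fas_total: int
    novel_fas_per_frame: float
    n_tracks: int
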