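"""Synthetic fluorescence-microscopy generators with exact ground truth.

Every generator is a pure function of its spec (which carries the seed): the
same spec produces bit-identical output.  Planted truth (object counts,
integer pixel areas, effect multipliers, event schedules, drift paths) is
emitted alongside the images and is never re-measured from pixels.

Object models are deliberately simple: nuclei are Gaussian-profile discs,
focal adhesions are filled ellipses (axis ratio 1-4) placed in an annulus
around their parent nucleus, pairwise disjoint with a guard gap so that the
downstream median filter cannot merge them.  Noise is additive Gaussian with
optional Poisson shot noise; defocus is simulated by blurring the whole
field.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import ROLES, FieldImage, Movie

MAX_INTENSITY = 65535.0  # declared bit depth: 16-bit


class CrowdedFieldError(RuntimeError):
    """Raised when planted objects cannot be placed disjointly."""


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SynthFieldSpec:
    """Recipe for one synthetic field.

    ``n_fas_per_cell`` is a (mean, dispersion) pair: dispersion 0 plants
    exactly ``round(mean)`` adhesions per cell, dispersion > 0 draws a
    negative-binomial count with variance ``mean * (1 + dispersion)``.
    ``fa_area_px`` bounds the sampled target areas (uniform draw).
    """

    image_shape: Tuple[int, int] = (256, 256)
    n_nuclei: int = 4
    nucleus_radius_px: float = 9.0
    nucleus_peak: float = 8000.0
    n_fas_per_cell: Tuple[float, float] = (8.0, 0.0)
    fa_area_px: Tuple[float, float] = (60.0, 180.0)
    fa_axis_ratio: Tuple[float, float] = (1.0, 4.0)
    fa_peak: float = 3000.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    poisson_noise: bool = False
    blur_sigma_px: float = 0.0
    seed: int = 0
    # geometry guards (all pixels)
    nucleus_min_sep_px: float = 80.0
    nucleus_margin_px: int = 40
    fa_gap_px: int = 6
    fa_margin_px: int = 4
    fa_annulus_out_px: Optional[float] = None  # default: half nucleus sep
    channels: Tuple[str, ...] = ("nucleus", "fa")
    # extra-channel intensities (only used when requested in ``channels``)
    membrane_level: float = 1200.0
    cytoplasm_body_level: float = 4000.0
    cytoplasm_rim_level: float = 300.0
    cell_radius_px: float = 36.0
    body_radius_px: float = 22.0


@dataclass
class FieldGroundTruth:
    """Planted truth for one field."""

    n_nuclei: int
    nuclei: List[Tuple[int, int]]  # centres (row, col)
    fa_areas: List[int]  # realized integer pixel areas, one per planted FA
    fa_centers: List[Tuple[int, int]]
    fa_cell_index: List[int]
    cell_total_areas: List[int] = dc_field(default_factory=list)
    cell_body_areas: List[int] = dc_field(default_factory=list)

    @property
    def n_fas(self) -> int:
        return len(self.fa_areas)


@dataclass
class SynthPlateSpec:
    """Recipe for a plate of synthetic fields.

    ``layout`` maps well id -> (role, gene); sample wells carry a gene label
    and draw FA count/area scaled by that gene's (count, area) multiplier
    from ``effect_model``.
    """

    layout: Dict[str, Tuple[str, Optional[str]]]
    effect_model: Dict[str, Tuple[float, float]]
    fields_per_well: int = 2
    base_field_spec: SynthFieldSpec = dc_field(default_factory=SynthFieldSpec)
    pos_ctrl_count_multiplier: float = 3.0
    death_ctrl_nuclei: int = 1
    seed: int = 0
    plate_id: str = "plate01"

    def __post_init__(self) -> None:
        for well, (role, gene) in self.layout.items():
            if role not in ROLES:
                raise ValueError(f"well {well}: unknown role {role!r}")
            if role == "sample" and not gene:
                raise ValueError(f"sample well {well} lacks a gene label")
        for required in ("mock", "neg_ctrl", "pos_ctrl"):
            n = sum(1 for role, _ in self.layout.values() if role == required)
            if n < 2:
                raise ValueError(
                    f"layout must contain >= 2 {required} wells, found {n}")


@dataclass
class PlateGroundTruth:
    roles: Dict[str, str]
    genes: Dict[str, Optional[str]]
    effects: Dict[str, Tuple[float, float]]  # per well (count, area) mult
    field_truth: Dict[Tuple[str, str], FieldGroundTruth]


@dataclass
class FAEventSpec:
    """One scheduled adhesion in a synthetic movie.

    Noiseless mean intensity follows ``peak * exp(a * (t - t_peak))`` during
    assembly (birth..peak) and ``peak * exp(-d * (t - t_peak))`` afterwards,
    with ``a``/``d`` in per-minute log-slope units (magnitudes).
    """

    birth_frame: int
    death_frame: int
    center: Tuple[int, int]
    axes: Tuple[float, float] = (4.0, 2.5)
    angle: float = 0.0
    peak_intensity: float = 2000.0
    assembly_rate: float = 0.05
    disassembly_rate: float = 0.03
    peak_frame: Optional[int] = None
    growth_px_per_frame: float = 0.0


@dataclass
class SynthMovieSpec:
    image_shape: Tuple[int, int] = (128, 128)
    n_frames: int = 60
    frame_interval: float = 2.0  # minutes
    events: List[FAEventSpec] = dc_field(default_factory=list)
    drift_path: Optional[List[Tuple[int, int]]] = None  # per-frame steps
    first_frame_fas: int = 0
    merge_pairs: Tuple[Tuple[int, int], ...] = ()
    background_level: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class MovieGroundTruth:
    events: List[FAEventSpec]
    drift_steps: List[Tuple[int, int]]  # per-frame (drow, dcol) increments
    intensities: List[List[Optional[float]]]  # [event][frame] pre-noise mean
    merge_frames: Dict[Tuple[int, int], int]

    @property
    def drift_cumulative(self) -> List[Tuple[int, int]]:
        out, r, c = [], 0, 0
        for dr, dc in self.drift_steps:
            r += dr
            c += dc
            out.append((r, c))
        return out


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: Tuple[int, int], center: Tuple[float, float],
                  axes: Tuple[float, float], angle: float) -> np.ndarray:
    """Boolean mask of a filled rotated ellipse (pixel-centre inclusion)."""
    a, b = axes
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * np.cos(angle) + dr * np.sin(angle)
    v = -dc * np.sin(angle) + dr * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _draw_fa_count(rng: np.random.Generator,
                   mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(round(mean))
    # negative binomial with variance mean * (1 + dispersion)
    r = mean / dispersion
    p = 1.0 / (1.0 + dispersion)
    return int(rng.negative_binomial(r, p))


def _place_nuclei(spec: SynthFieldSpec,
                  rng: np.random.Generator) -> List[Tuple[int, int]]:
    nrows, ncols = spec.image_shape
    m = spec.nucleus_margin_px
    if nrows - 2 * m <= 0 or ncols - 2 * m <= 0:
        raise CrowdedFieldError("field too crowded: image smaller than margins")
    centres: List[Tuple[int, int]] = []
    tries = 0
    while len(centres) < spec.n_nuclei:
        tries += 1
        if tries > 400 * max(spec.n_nuclei, 1):
            raise CrowdedFieldError(
                "field too crowded: could not place all nuclei disjointly")
        r = int(rng.integers(m, nrows - m))
        c = int(rng.integers(m, ncols - m))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= spec.nucleus_min_sep_px ** 2
               for r0, c0 in centres):
            centres.append((r, c))
    return centres


def make_field(spec: SynthFieldSpec) -> Tuple[FieldImage, FieldGroundTruth]:
    """Generate one synthetic field and its planted ground truth.

    Planted FA footprints are pairwise disjoint, separated by at least
    ``fa_gap_px`` pixels, and disjoint from nucleus footprints.  Raises
    :class:`CrowdedFieldError` if placement fails after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.image_shape
    shape = (nrows, ncols)

    nucleus_img = np.zeros(shape)
    fa_img = np.zeros(shape)
    occupancy = np.zeros(shape, dtype=bool)

    nuclei = _place_nuclei(spec, rng)
    sigma_n = spec.nucleus_radius_px / 1.5
    for r, c in nuclei:
        rr, cc = np.mgrid[0:nrows, 0:ncols]
        d2 = (rr - r) ** 2.0 + (cc - c) ** 2.0
        blob = spec.nucleus_peak * np.exp(-d2 / (2 * sigma_n ** 2))
        blob[d2 > (2 * spec.nucleus_radius_px) ** 2] = 0.0
        nucleus_img = np.maximum(nucleus_img, blob)
        occupancy |= d2 <= (2 * spec.nucleus_radius_px) ** 2

    gap = spec.fa_gap_px
    margin = spec.fa_margin_px
    annulus_in = 2 * spec.nucleus_radius_px + gap
    annulus_out = (spec.fa_annulus_out_px if spec.fa_annulus_out_px
                   else max(annulus_in + 4.0,
                            0.75 * spec.nucleus_min_sep_px))

    fa_areas: List[int] = []
    fa_centers: List[Tuple[int, int]] = []
    fa_cell_index: List[int] = []
    mean, dispersion = spec.n_fas_per_cell
    lo_a, hi_a = spec.fa_area_px
    for cell_idx, (nr, nc) in enumerate(nuclei):
        n_fas = _draw_fa_count(rng, mean, dispersion)
        for _ in range(n_fas):
            placed = False
            for _attempt in range(400):
                radius = rng.uniform(annulus_in, annulus_out)
                theta = rng.uniform(0, 2 * np.pi)
                r = int(round(nr + radius * np.sin(theta)))
                c = int(round(nc + radius * np.cos(theta)))
                if not (margin <= r < nrows - margin
                        and margin <= c < ncols - margin):
                    continue
                target_area = rng.uniform(lo_a, hi_a)
                ratio = rng.uniform(*spec.fa_axis_ratio)
                b = np.sqrt(target_area / (np.pi * ratio))
                if b < 2.3:  # keep a width the radius-2 median cannot erase
                    b = 2.3
                a = target_area / (np.pi * b)
                angle = rng.uniform(0, np.pi)
                ext = int(np.ceil(max(a, b))) + gap + 1
                r0, r1 = max(r - ext, 0), min(r + ext + 1, nrows)
                c0, c1 = max(c - ext, 0), min(c + ext + 1, ncols)
                sub_shape = (r1 - r0, c1 - c0)
                sub_mask = _ellipse_mask(sub_shape, (r - r0, c - c0),
                                         (a, b), angle)
                if (sub_mask[0, :].any() or sub_mask[-1, :].any()
                        or sub_mask[:, 0].any() or sub_mask[:, -1].any()):
                    continue  # clipped by image border
                grown = _dilate_bool(sub_mask, gap)
                if (grown & occupancy[r0:r1, c0:c1]).any():
                    continue
                occupancy[r0:r1, c0:c1] |= sub_mask
                fa_img[r0:r1, c0:c1][sub_mask] = spec.fa_peak
                fa_areas.append(int(sub_mask.sum()))
                fa_centers.append((r, c))
                fa_cell_index.append(cell_idx)
                placed = True
                break
            if not placed:
                raise CrowdedFieldError(
                    "field too crowded: could not place all FAs disjointly")

    channels: Dict[str, np.ndarray] = {}
    cell_total_areas: List[int] = []
    cell_body_areas: List[int] = []
    extra = set(spec.channels) - {"nucleus", "fa"}
    if extra:
        membrane = np.zeros(shape)
        cytoplasm = np.zeros(shape)
        actin = np.zeros(shape)
        for nr, nc in nuclei:
            cell = _disc_mask(shape, (nr, nc), spec.cell_radius_px)
            body = _disc_mask(shape, (nr, nc), spec.body_radius_px)
            membrane[cell] = spec.membrane_level
            cytoplasm[cell] = np.maximum(cytoplasm[cell],
                                         spec.cytoplasm_rim_level)
            cytoplasm[body] = spec.cytoplasm_body_level
            actin[cell] = spec.membrane_level
            cell_total_areas.append(int(cell.sum()))
            cell_body_areas.append(int(body.sum()))
        if "membrane" in extra:
            channels["membrane"] = membrane
        if "cytoplasm" in extra:
            channels["cytoplasm"] = cytoplasm
        if "actin" in extra:
            channels["actin"] = actin

    channels["nucleus"] = nucleus_img
    channels["fa"] = fa_img
    out: Dict[str, np.ndarray] = {}
    for name in spec.channels:
        img = channels[name] + spec.background_level
        if spec.blur_sigma_px > 0:
            from scipy import ndimage as ndi
            img = ndi.gaussian_filter(img, spec.blur_sigma_px)
        if spec.poisson_noise:
            img = rng.poisson(np.maximum(img, 0)).astype(float)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        out[name] = np.clip(np.rint(img), 0, MAX_INTENSITY).astype(np.uint16)

    truth = FieldGroundTruth(
        n_nuclei=len(nuclei), nuclei=nuclei, fa_areas=fa_areas,
        fa_centers=fa_centers, fa_cell_index=fa_cell_index,
        cell_total_areas=cell_total_areas, cell_body_areas=cell_body_areas)
    return FieldImage(channels=out), truth


def _dilate_bool(mask: np.ndarray, by: int) -> np.ndarray:
    if by <= 0:
        return mask
    from scipy import ndimage as ndi
    yy, xx = np.mgrid[-by:by + 1, -by:by + 1]
    return ndi.binary_dilation(mask, structure=yy ** 2 + xx ** 2 <= by ** 2)


# ---------------------------------------------------------------------------
# plate generation
# ---------------------------------------------------------------------------

def default_layout(genes: Sequence[str], n_rows: int = 16, n_cols: int = 24
                   ) -> Dict[str, Tuple[str, Optional[str]]]:
    """Rectangular plate layout with controls in the two outer columns.

    The paper places controls on every 384-well plate but does not give their
    coordinates; this default cycles mock / pos_ctrl / neg_ctrl / death_ctrl
    down columns 1 and ``n_cols`` and fills inner wells with sample genes.
    """
    control_cycle = ("mock", "pos_ctrl", "neg_ctrl", "death_ctrl")
    layout: Dict[str, Tuple[str, Optional[str]]] = {}
    gene_iter = iter(genes)
    ctrl_i = 0
    for r in range(n_rows):
        row_name = _well_row_name(r)
        for c in range(1, n_cols + 1):
            well = f"{row_name}{c:02d}"
            if c == 1 or c == n_cols:
                layout[well] = (control_cycle[ctrl_i % 4], None)
                ctrl_i += 1
            else:
                gene = next(gene_iter, None)
                if gene is not None:
                    layout[well] = ("sample", gene)
    return layout


def _well_row_name(r: int) -> str:
    name = ""
    r += 1
    while r:
        r, rem = divmod(r - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def make_plate(spec: SynthPlateSpec
               ) -> Tuple[Dict[Tuple[str, str], FieldImage], PlateGroundTruth]:
    """Generate every field of a plate according to the layout and effects.

    Sample wells scale the base FA count mean and area bounds by their gene's
    (count, area) multipliers; ``pos_ctrl`` wells boost the FA count;
    ``death_ctrl`` wells contain ``death_ctrl_nuclei`` nuclei (near-empty).
    Per-well randomness is seeded from ``(spec.seed, well index, field)`` so
    plates are reproducible well-by-well.
    """
    fields: Dict[Tuple[str, str], FieldImage] = {}
    truth = PlateGroundTruth(roles={}, genes={}, effects={}, field_truth={})
    base = spec.base_field_spec
    for well_idx, (well, (role, gene)) in enumerate(sorted(spec.layout.items())):
        count_mult, area_mult = 1.0, 1.0
        if role == "sample":
            count_mult, area_mult = spec.effect_model.get(gene, (1.0, 1.0))
        elif role == "pos_ctrl":
            count_mult = spec.pos_ctrl_count_multiplier
        truth.roles[well] = role
        truth.genes[well] = gene
        truth.effects[well] = (count_mult, area_mult)
        mean, dispersion = base.n_fas_per_cell
        lo_a, hi_a = base.fa_area_px
        for f in range(spec.fields_per_well):
            field_spec = replace(
                base,
                n_nuclei=(spec.death_ctrl_nuclei if role == "death_ctrl"
                          else base.n_nuclei),
                n_fas_per_cell=(mean * count_mult, dispersion),
                fa_area_px=(lo_a * area_mult, hi_a * area_mult),
                seed=int(np.random.default_rng(
                    [spec.seed, well_idx, f]).integers(2 ** 31)),
            )
            image, field_truth = make_field(field_spec)
            image.well_id = well
            image.field_id = f"f{f:02d}"
            fields[(well, image.field_id)] = image
            truth.field_truth[(well, image.field_id)] = field_truth
    return fields, truth


# ---------------------------------------------------------------------------
# readout-level screen simulation (no images)
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimTruth:
    effects: Dict[str, Tuple[float, float]]  # gene -> (count, area) mult
    base_count: float
    base_area: float


def simulate_screen_readouts(
    n_plates: int,
    n_sample_wells: int,
    effects: Dict[str, Tuple[float, float]],
    seed: int,
    base_count: float = 10.0,
    count_sd: float = 0.5,
    base_area: float = 150.0,
    area_sd: float = 7.5,
    mean_cells: float = 250.0,
    n_mock: int = 8,
    n_pos: int = 8,
    n_neg: int = 4,
    n_death: int = 4,
    pos_ctrl_count_multiplier: float = 3.0,
    death_ctrl_mean_cells: float = 15.0,
    plate_prefix: str = "plate",
):
    """Draw per-well plate tables directly at the readout level.

    Sample wells draw ``fas_per_cell ~ N(base_count * count_mult, count_sd)``
    and ``fa_area_mean ~ N(base_area * area_mult, area_sd)``; cell counts are
    Poisson.  Returns ``(list of plate DataFrames, ScreenSimTruth)``.  Gene
    ``i`` of plate ``p`` is named ``g{p}_{i:04d}`` unless present in
    ``effects`` (planted genes are assigned to wells round-robin across
    plates by their sorted order).

    This is the statistics-scale companion of :func:`make_plate`: pixel-level
    plate generation at hundreds of wells per plate is unnecessary (and too
    slow) for validating the screening statistics, whose inputs are per-well
    readouts.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    planted = sorted(effects)
    plates = []
    for p in range(n_plates):
        rows = []
        for i in range(n_sample_wells):
            gene = f"g{p}_{i:04d}"
            idx = p * n_sample_wells + i
            if idx < len(planted):
                gene = planted[idx]
            cm, am = effects.get(gene, (1.0, 1.0))
            rows.append(dict(
                role="sample", gene=gene,
                fas_per_cell=rng.normal(base_count * cm, count_sd),
                fa_area_mean=rng.normal(base_area * am, area_sd),
                cell_count=int(rng.poisson(mean_cells))))
        for role, n, cm, cells in (("mock", n_mock, 1.0, mean_cells),
                                   ("pos_ctrl", n_pos,
                                    pos_ctrl_count_multiplier, mean_cells),
                                   ("neg_ctrl", n_neg, 1.0, mean_cells),
                                   ("death_ctrl", n_death, 1.0,
                                    death_ctrl_mean_cells)):
            for _ in range(n):
                rows.append(dict(
                    role=role, gene=None,
                    fas_per_cell=rng.normal(base_count * cm, count_sd),
                    fa_area_mean=rng.normal(base_area, area_sd),
                    cell_count=int(rng.poisson(cells))))
        df = pd.DataFrame(rows)
        df.insert(0, "plate_id", f"{plate_prefix}{p:02d}")
        df.insert(1, "well_id", [f"w{i:04d}" for i in range(len(df))])
        df["excluded_fields"] = 0
        plates.append(df)
    return plates, ScreenSimTruth(effects=dict(effects),
                                  base_count=base_count, base_area=base_area)


# ---------------------------------------------------------------------------
# movie generation
# ---------------------------------------------------------------------------

def _event_intensity(ev: FAEventSpec, frame: int,
                     interval: float) -> Optional[float]:
    if frame < ev.birth_frame or frame > ev.death_frame:
        return None
    peak_frame = (ev.peak_frame if ev.peak_frame is not None
                  else (ev.birth_frame + ev.death_frame) // 2)
    dt = (frame - peak_frame) * interval
    if frame <= peak_frame:
        return ev.peak_intensity * float(np.exp(ev.assembly_rate * dt))
    return ev.peak_intensity * float(np.exp(-ev.disassembly_rate * dt))


def make_movie(spec: SynthMovieSpec) -> Tuple[Movie, MovieGroundTruth]:
    """Generate a time-lapse stack with scheduled adhesion events and rigid
    drift.

    Each event paints its (optionally growing) elliptical footprint at its
    scheduled noiseless mean intensity; drift is applied as an integer rigid
    translation accumulated from ``drift_path`` steps.  Overlap between
    simultaneously alive events raises an error unless the pair is declared
    in ``merge_pairs``; for declared pairs the first frame at which the two
    footprints touch (8-connectivity) is recorded as the merge frame.
    """
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.image_shape
    events = list(spec.events)
    for ev in events:
        if not (0 <= ev.birth_frame <= ev.death_frame < spec.n_frames):
            raise ValueError(
                f"event frames [{ev.birth_frame}, {ev.death_frame}] outside "
                f"[0, {spec.n_frames})")
    placed = [_ellipse_mask((nrows, ncols), ev.center, ev.axes, ev.angle)
              for ev in events]
    for _ in range(spec.first_frame_fas):
        for _attempt in range(300):
            center = (int(rng.integers(15, nrows - 15)),
                      int(rng.integers(15, ncols - 15)))
            axes = (float(rng.uniform(3, 6)), float(rng.uniform(2.5, 4)))
            angle = float(rng.uniform(0, np.pi))
            mask = _dilate_bool(
                _ellipse_mask((nrows, ncols), center, axes, angle), 2)
            if not any((mask & other).any() for other in placed):
                placed.append(mask)
                break
        else:
            raise CrowdedFieldError(
                "movie too crowded: cannot place first-frame adhesions")
        events.append(FAEventSpec(
            birth_frame=0, death_frame=spec.n_frames - 1, center=center,
            axes=axes, angle=angle,
            peak_intensity=float(rng.uniform(1000, 3000)),
            assembly_rate=0.0, disassembly_rate=0.0, peak_frame=0))

    steps = (list(spec.drift_path) if spec.drift_path is not None
             else [(0, 0)] * spec.n_frames)
    if len(steps) != spec.n_frames:
        raise ValueError("drift_path must have one (drow, dcol) per frame")

    merge_ok = {tuple(sorted(p)) for p in spec.merge_pairs}
    merge_frames: Dict[Tuple[int, int], int] = {}
    frames = np.zeros((spec.n_frames, nrows, ncols))
    intensities: List[List[Optional[float]]] = [
        [None] * spec.n_frames for _ in events]

    dr_cum, dc_cum = 0, 0
    for f in range(spec.n_frames):
        dr_cum += steps[f][0]
        dc_cum += steps[f][1]
        canvas = np.full((nrows, ncols), spec.background_level)
        alive_masks: List[Tuple[int, np.ndarray]] = []
        for i, ev in enumerate(events):
            inten = _event_intensity(ev, f, spec.frame_interval)
            if inten is None:
                continue
            intensities[i][f] = inten
            grow = ev.growth_px_per_frame * (f - ev.birth_frame)
            mask = _ellipse_mask(
                (nrows, ncols),
                (ev.center[0] + dr_cum, ev.center[1] + dc_cum),
                (ev.axes[0] + grow, ev.axes[1] + grow), ev.angle)
            canvas[mask] += inten
            alive_masks.append((i, mask))
        for a in range(len(alive_masks)):
            for b in range(a + 1, len(alive_masks)):
                i, mi = alive_masks[a]
                j, mj = alive_masks[b]
                touching = (_dilate_bool(mi, 1) & mj).any()
                if touching:
                    pair = tuple(sorted((i, j)))
                    if pair not in merge_ok:
                        raise ValueError(
                            f"events {pair} overlap at frame {f} without a "
                            "declared merge")
                    merge_frames.setdefault(pair, f)
        if spec.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, spec.noise_sd,
                                         size=(nrows, ncols))
        frames[f] = np.clip(np.rint(canvas), 0, MAX_INTENSITY)

    movie = Movie(frames=frames.astype(np.uint16),
                  frame_interval=spec.frame_interval)
    truth = MovieGroundTruth(events=events, drift_steps=steps,
                             intensities=intensities,
                             merge_frames=merge_frames)
    return movie, truth
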