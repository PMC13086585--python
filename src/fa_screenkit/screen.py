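"""Plate-level screening statistics: QC, normalization and hit calling.

Operates on long-format "plate tables" (:class:`pandas.DataFrame`) with one
row per well and columns ``plate_id, well_id, role, gene, fas_per_cell,
fa_area_mean, cell_count, excluded_fields``.  Control rows carry a role from
the closed vocabulary (mock, neg_ctrl, pos_ctrl, death_ctrl); sample rows
carry a gene label.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ROLES, FieldQuant, ScreenThresholds

PLATE_COLUMNS = ["plate_id", "well_id", "role", "gene", "fas_per_cell",
                 "fa_area_mean", "cell_count", "excluded_fields"]


def zprime(positive: Sequence[float], negative: Sequence[float]) -> float:
    """Z'-factor: ``1 - 3 * (sd_p + sd_n) / |mean_p - mean_n|``.

    Uses sample (n-1) standard deviations; symmetric in group order and
    invariant under a common affine rescaling of both groups.  Raises if the
    group means coincide (separation undefined).
    """
    p = np.asarray(positive, dtype=float)
    n = np.asarray(negative, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("each control group needs >= 2 values")
    mu_p, mu_n = p.mean(), n.mean()
    if mu_p == mu_n:
        raise ValueError("separation undefined: control means are equal")
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1))
                 / abs(mu_p - mu_n))


def plate_zscores(plate: pd.DataFrame, parameter: str = "fas_per_cell",
                  reference: str = "sample") -> pd.Series:
    """Plate-wise Z-scores ``(x - mean_ref) / sd_ref`` for one parameter.

    ``reference`` selects the normalization population within the plate:
    ``"sample"`` (all non-control sample wells; the default, robust to
    sparse controls) or ``"mock"``.  Wells with missing (excluded) values
    receive no score.  Raises if the reference has fewer than two usable
    wells or zero spread.
    """
    if parameter not in ("fas_per_cell", "fa_area_mean"):
        raise ValueError(f"unknown parameter {parameter!r}")
    if reference not in ("sample", "mock"):
        raise ValueError(f"unknown reference population {reference!r}")
    ref_vals = plate.loc[plate["role"] == reference, parameter].dropna()
    if len(ref_vals) < 2:
        raise ValueError(
            f"reference population {reference!r} has "
            f"{len(ref_vals)} non-excluded wells; need >= 2")
    mu = ref_vals.mean()
    sd = ref_vals.std(ddof=1)
    if sd == 0:
        raise ValueError("reference standard deviation is zero")
    z = (plate[parameter] - mu) / sd
    z.index = plate["well_id"]
    return z


def call_hits(gene_stats: pd.DataFrame,
              thresholds: Optional[ScreenThresholds] = None) -> pd.DataFrame:
    """Call hits from per-gene Z-scores and cell counts.

    ``gene_stats`` needs columns ``gene, z_count, z_area, cell_count`` (an
    optional boolean ``artifact`` column marks manually flagged wells).
    A gene is a hit iff ``z_count > z_count_threshold`` or
    ``z_area > z_area_threshold`` (strict inequalities) and its well passed
    the viability filter (``cell_count >= viability_min_cells``).  Cell
    counts are mandatory: a missing count raises.
    """
    thresholds = thresholds or ScreenThresholds()
    required = {"gene", "z_count", "z_area", "cell_count"}
    missing = required - set(gene_stats.columns)
    if missing:
        raise ValueError(f"gene_stats lacks columns: {sorted(missing)}")
    if gene_stats["cell_count"].isna().any():
        bad = gene_stats.loc[gene_stats["cell_count"].isna(), "gene"].tolist()
        raise ValueError(f"missing cell counts for genes: {bad[:5]}")
    out = gene_stats[["gene", "z_count", "z_area"]].copy()
    viable = gene_stats["cell_count"] >= thresholds.viability_min_cells
    artifact = (gene_stats["artifact"].fillna(False).astype(bool)
                if "artifact" in gene_stats.columns
                else pd.Series(False, index=gene_stats.index))
    above = ((gene_stats["z_count"] > thresholds.z_count_threshold)
             | (gene_stats["z_area"] > thresholds.z_area_threshold))
    out["hit"] = (above & viable & ~artifact).to_numpy()
    reason = np.where(~viable, "viability",
                      np.where(artifact, "artifact", "none"))
    out["exclusion_reason"] = reason
    return out


def secondary_confirm(replicate1: pd.DataFrame, replicate2: pd.DataFrame,
                      thresholds: Optional[ScreenThresholds] = None
                      ) -> pd.DataFrame:
    """Confirm candidates from two replicate plates normalized to mock.

    For each parameter, every sample well's value is divided by the mock-well
    mean of its replicate; per-gene folds are averaged across the two
    replicates.  A gene is confirmed iff its mean fold change is at least
    ``1 + confirm_min_increase`` (inclusive: a 30% increase confirms at the
    default) in either parameter.  Genes missing from one replicate are
    reported with status ``unconfirmable`` rather than dropped.
    """
    thresholds = thresholds or ScreenThresholds()
    folds = {}
    for i, rep in enumerate((replicate1, replicate2)):
        mock = rep[rep["role"] == "mock"]
        if mock.empty:
            raise ValueError(f"replicate {i + 1} has no mock wells")
        samples = rep[rep["role"] == "sample"]
        for _, row in samples.iterrows():
            entry = folds.setdefault(row["gene"], {})
            for param in ("fas_per_cell", "fa_area_mean"):
                ref = mock[param].mean()
                entry.setdefault(param, [None, None])[i] = row[param] / ref
    rows = []
    cutoff = 1.0 + thresholds.confirm_min_increase
    for gene in sorted(folds):
        entry = folds[gene]
        rec: Dict[str, object] = {"gene": gene}
        complete = True
        for param in ("fas_per_cell", "fa_area_mean"):
            pair = entry.get(param, [None, None])
            if None in pair or any(pd.isna(v) for v in pair):
                rec[f"mean_fold_{param}"] = np.nan
                complete = False
            else:
                rec[f"mean_fold_{param}"] = float(np.mean(pair))
        if not complete:
            rec["status"] = "unconfirmable"
            rec["confirmed"] = False
        else:
            eps = 1e-9  # inclusive threshold, robust to float rounding
            confirmed = (rec["mean_fold_fas_per_cell"] >= cutoff - eps
                         or rec["mean_fold_fa_area_mean"] >= cutoff - eps)
            rec["status"] = "confirmed" if confirmed else "not_confirmed"
            rec["confirmed"] = bool(confirmed)
        rows.append(rec)
    return pd.DataFrame(rows)


def aggregate_wells(field_quants: Iterable[FieldQuant],
                    layout: Dict[str, tuple],
                    plate_id: str = "plate01") -> pd.DataFrame:
    """Aggregate per-field quantifications to a per-well plate table.

    Per well: ``fas_per_cell`` is the mean over non-excluded fields,
    ``fa_area_mean`` the mean of per-FA areas pooled over the well's
    non-excluded fields, ``cell_count`` the summed nuclei of non-excluded
    fields.  Wells whose fields are all excluded carry NaN readouts.
    """
    by_well: Dict[str, List[FieldQuant]] = {}
    for fq in field_quants:
        by_well.setdefault(fq.well_id, []).append(fq)
    rows = []
    for well, (role, gene) in sorted(layout.items()):
        if role not in ROLES:
            raise ValueError(f"well {well}: unknown role {role!r}")
        quants = by_well.get(well, [])
        good = [q for q in quants if not q.excluded]
        pooled_areas = [a for q in good for a in q.fa_areas]
        rows.append(dict(
            plate_id=plate_id,
            well_id=well,
            role=role,
            gene=gene,
            fas_per_cell=(float(np.mean([q.fas_per_cell for q in good]))
                          if good else np.nan),
            fa_area_mean=(float(np.mean(pooled_areas))
                          if pooled_areas else np.nan),
            cell_count=(int(sum(q.n_nuclei for q in good)) if good else 0),
            excluded_fields=sum(1 for q in quants if q.excluded),
        ))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


@dataclass
class ScreenReport:
    """Machine-readable primary-screen summary."""

    plate_qc: pd.DataFrame  # plate_id, zprime, warn
    zscores: pd.DataFrame  # plate_id, well_id, gene, z_count, z_area
    hits: pd.DataFrame  # call_hits output
    exclusions: pd.DataFrame  # per-reason tallies
    reference: str


def screen_report(plates: Sequence[pd.DataFrame],
                  thresholds: Optional[ScreenThresholds] = None,
                  reference: str = "sample") -> ScreenReport:
    """Per-plate Z'-factor QC plus screen-wide Z-scores and hit calling.

    The Z'-factor compares mock and pos_ctrl wells per plate on
    ``fas_per_cell``; plates below ``zprime_warn`` are flagged but kept (the
    screen retained every plate).  Z-scores are computed within each plate
    against the ``reference`` population and hit calling pools all sample
    wells across plates.
    """
    if not plates:
        raise ValueError("need at least one plate")
    thresholds = thresholds or ScreenThresholds()
    qc_rows = []
    gene_rows = []
    for plate in plates:
        plate_id = plate["plate_id"].iloc[0]
        mock = plate.loc[plate["role"] == "mock", "fas_per_cell"].dropna()
        pos = plate.loc[plate["role"] == "pos_ctrl", "fas_per_cell"].dropna()
        zp = zprime(pos, mock)
        if zp < thresholds.zprime_warn:
            warnings.warn(
                f"{plate_id}: Z' = {zp:.3f} below {thresholds.zprime_warn}")
        qc_rows.append(dict(plate_id=plate_id, zprime=zp,
                            warn=zp < thresholds.zprime_warn))
        z_count = plate_zscores(plate, "fas_per_cell", reference)
        z_area = plate_zscores(plate, "fa_area_mean", reference)
        samples = plate[plate["role"] == "sample"]
        for _, row in samples.iterrows():
            gene_rows.append(dict(
                plate_id=plate_id, well_id=row["well_id"], gene=row["gene"],
                z_count=z_count[row["well_id"]],
                z_area=z_area[row["well_id"]],
                cell_count=row["cell_count"]))
    zscores = pd.DataFrame(gene_rows)
    hits = call_hits(zscores[["gene", "z_count", "z_area", "cell_count"]],
                     thresholds)
    tallies = (hits["exclusion_reason"].value_counts().rename_axis("reason")
               .reset_index(name="n_genes"))
    return ScreenReport(plate_qc=pd.DataFrame(qc_rows), zscores=zscores,
                        hits=hits, exclusions=tallies, reference=reference)
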