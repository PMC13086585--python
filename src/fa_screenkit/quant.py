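"""Focal-adhesion segmentation and per-field quantification.

Implements the two analysis dialects used for fixed-cell paxillin images:

* ``screen``: median filter (radius 2) -> rolling-ball/sliding-paraboloid
  background subtraction (radius 1) -> Otsu threshold -> 50-5000 px size
  filter; nuclei counted as prominence-100 maxima of the sigma-20 smoothed
  nucleus channel; fields QC'd on focus, raw object count and nuclei count.
* ``percell``: same FA preprocessing, 50-500 px size window plus a
  0.00-0.95 circularity filter, nuclei maxima with edge exclusion.

The background model is a true sliding paraboloid: the background at every
pixel is the upper envelope of paraboloid "domes" slid underneath the
intensity surface.  This equals a grayscale opening with the quadratic
structuring function ``-(d^2) / (2 * radius)``, which is separable and is
evaluated exactly with two 1-D erosions followed by two 1-D dilations.
"""
from __future__ import annotations

import warnings
from typing import List, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk, local_maxima

from .datatypes import FAQuantParams, FARecord, FieldImage, FieldQuant

_EIGHT = np.ones((3, 3), dtype=bool)


def _as_float_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0:
        raise ValueError("image contains negative values")
    return arr


def sliding_paraboloid_background(image: np.ndarray, radius: float,
                                  paraboloid: bool = True) -> np.ndarray:
    """Estimate the background by sliding a paraboloid (or ball) under the
    intensity surface.

    The paraboloid dome centred at ``c`` with apex ``z0`` is
    ``z0 - |x - c|^2 / (2 * radius)``; the background is the pointwise
    maximum over all domes that fit entirely below the image surface.
    Out-of-image pixels impose no constraint and out-of-image dome centres
    are not considered.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    f = np.asarray(image, dtype=float)
    if f.ndim != 2:
        raise ValueError("background subtraction requires a 2-D image")
    rng = float(f.max() - f.min()) if f.size else 0.0
    if rng == 0.0:
        return f.copy()
    if paraboloid:
        # support of the quadratic SE: beyond `half` the dome is below the
        # global minimum and cannot influence the envelope
        half = int(np.ceil(np.sqrt(2.0 * radius * rng)))
        half = max(1, min(half, max(f.shape)))
        x = np.arange(-half, half + 1, dtype=float)
        s = -(x ** 2) / (2.0 * radius)
        e = ndi.grey_erosion(f, structure=s[:, None], mode="constant", cval=np.inf)
        e = ndi.grey_erosion(e, structure=s[None, :], mode="constant", cval=np.inf)
        b = ndi.grey_dilation(e, structure=s[:, None], mode="constant", cval=-np.inf)
        b = ndi.grey_dilation(b, structure=s[None, :], mode="constant", cval=-np.inf)
        return b
    # spherical ball: not separable; use the bounded 2-D cap directly
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = (yy ** 2 + xx ** 2).astype(float)
    inside = d2 <= radius ** 2
    cap = np.where(inside, np.sqrt(np.maximum(radius ** 2 - d2, 0.0)) - radius,
                   -np.inf)
    e = ndi.grey_erosion(f, structure=cap, footprint=inside,
                         mode="constant", cval=np.inf)
    return ndi.grey_dilation(e, structure=cap, footprint=inside,
                             mode="constant", cval=-np.inf)


def preprocess_fa_channel(image: np.ndarray,
                          params: FAQuantParams) -> np.ndarray:
    """Median filter then rolling-ball/paraboloid background subtraction.

    Returns a non-negative float image of unchanged shape.
    """
    arr = _as_float_image(image)
    if params.median_radius > 0:
        arr = ndi.median_filter(arr, footprint=disk(params.median_radius))
    background = sliding_paraboloid_background(
        arr, params.rollball_radius, paraboloid=params.sliding_paraboloid)
    return np.maximum(arr - background, 0.0)


def _threshold_components(image: np.ndarray,
                          nbins: int) -> Tuple[np.ndarray, int]:
    """Otsu-threshold the image and label 8-connected foreground components.

    Returns ``(labels, n_components)``; a degenerate (single-valued)
    histogram yields zero components with a warning.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0 or float(arr.max() - arr.min()) == 0.0:
        warnings.warn("degenerate histogram: no objects segmented",
                      stacklevel=3)
        return np.zeros(arr.shape, dtype=np.int32), 0
    thresh = threshold_otsu(arr, nbins=nbins)
    labels, n = ndi.label(arr > thresh, structure=_EIGHT)
    return labels, n


def _filter_components(labels: np.ndarray, params: FAQuantParams
                       ) -> Tuple[np.ndarray, List[FARecord]]:
    """Apply the inclusive size window and optional circularity filter."""
    records: List[FARecord] = []
    out = np.zeros(labels.shape, dtype=np.int32)
    next_label = 0
    for prop in measure.regionprops(labels):
        area = int(prop.area)
        if area < params.min_area or area > params.max_area:
            continue
        perimeter = float(prop.perimeter)
        circ = 1.0 if perimeter == 0 else 4.0 * np.pi * area / perimeter ** 2
        circ = min(circ, 1.0)
        if params.circularity_range is not None:
            lo, hi = params.circularity_range
            if not (lo <= circ <= hi):
                continue
        next_label += 1
        out[labels == prop.label] = next_label
        records.append(FARecord(label=next_label, area=area,
                                centroid=tuple(prop.centroid),
                                circularity=circ))
    return out, records


def segment_fas(image: np.ndarray, params: FAQuantParams
                ) -> Tuple[np.ndarray, List[FARecord]]:
    """Segment focal adhesions in a preprocessed FA channel.

    Connected components (8-connectivity) above the Otsu threshold are
    filtered by the inclusive size window ``[min_area, max_area]`` and, if a
    circularity range is configured, by ``4*pi*area/perimeter^2`` (perimeter
    from the weighted pixel-boundary estimator of
    ``skimage.measure.regionprops``; values above 1 from discretization are
    clipped to 1.0 before range filtering).  Surviving objects are relabelled
    with consecutive positive integers in scan order.
    """
    labels, _ = _threshold_components(image, params.otsu_bins)
    return _filter_components(labels, params)


def prominence_maxima(image: np.ndarray, prominence: float,
                      ) -> List[Tuple[int, int, float]]:
    """Find local maxima with topographic prominence >= ``prominence``.

    The prominence of a maximum of height ``h`` is ``h`` minus the highest
    saddle connecting it to higher ground; a maximum is accepted iff its
    connected component of ``image > h - prominence`` contains no strictly
    higher pixel.  Of several equal-height maxima sharing a component, the
    one with the smallest (row, col) is kept.  Returns accepted maxima as
    ``(row, col, height)`` sorted by descending height.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0 or float(arr.max() - arr.min()) == 0.0:
        return []
    plateaus, n_plateaus = ndi.label(
        local_maxima(arr, connectivity=2, allow_borders=True),
        structure=_EIGHT)
    if n_plateaus == 0:
        return []
    candidates = []
    for idx in range(1, n_plateaus + 1):
        rows, cols = np.nonzero(plateaus == idx)
        order = np.lexsort((cols, rows))
        r, c = int(rows[order[0]]), int(cols[order[0]])
        candidates.append((float(arr[r, c]), r, c))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted: List[Tuple[int, int, float]] = []
    for h, r, c in candidates:
        comp_labels, _ = ndi.label(arr > h - prominence, structure=_EIGHT)
        comp = comp_labels == comp_labels[r, c]
        if float(arr[comp].max()) > h:
            continue
        if any(comp[ar, ac] for ar, ac, _ in accepted):
            continue
        accepted.append((r, c, h))
    return accepted


def count_nuclei(image: np.ndarray, params: FAQuantParams) -> int:
    """Count nuclei as prominent maxima of the smoothed nucleus channel.

    The channel is Gaussian-smoothed with ``sigma = nucleus_smooth_radius``
    and maxima are accepted at prominence >= ``maxima_threshold``; with edge
    exclusion, maxima whose smoothed peak lies within ``edge_margin`` pixels
    of the image border are rejected.  Prominence is offset-free, so adding a
    constant to the channel does not change the count.
    """
    arr = _as_float_image(image)
    smoothed = ndi.gaussian_filter(arr, sigma=params.nucleus_smooth_radius)
    maxima = prominence_maxima(smoothed, params.maxima_threshold)
    if params.edge_exclude_nuclei:
        m = params.edge_margin
        nrows, ncols = arr.shape
        maxima = [(r, c, h) for r, c, h in maxima
                  if m <= r < nrows - m and m <= c < ncols - m]
    return len(maxima)


def focus_score(image: np.ndarray, window: int) -> float:
    """Local normalized-variance focus statistic.

    The image is tiled into non-overlapping ``window x window`` blocks
    (trailing partial blocks are dropped); each block contributes
    ``variance / mean^2`` (0 where the mean is 0) and the score is the mean
    over blocks.  The score is exactly 0 for constant images and decreases
    when a textured image is blurred.  This is a documented monotone proxy
    for the CellProfiler local focus score, used with the same 0.03 default
    threshold.
    """
    arr = _as_float_image(image)
    if window < 2:
        raise ValueError("window must be >= 2 pixels")
    nrows, ncols = arr.shape
    if window > nrows or window > ncols:
        raise ValueError(
            f"window {window} larger than image {arr.shape}")
    br, bc = nrows // window, ncols // window
    blocks = (arr[:br * window, :bc * window]
              .reshape(br, window, bc, window)
              .transpose(0, 2, 1, 3)
              .reshape(br * bc, window * window))
    means = blocks.mean(axis=1)
    variances = blocks.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(means > 0, variances / means ** 2, 0.0)
    return float(scores.mean())


def quantify_field(field: FieldImage, params: FAQuantParams) -> FieldQuant:
    """Run the full per-field pipeline: preprocess -> segment -> count nuclei
    -> focus QC.

    QC flags: ``oversegmented`` if the raw (pre-size-filter) object count
    exceeds ``max_raw_objects``; ``low_nuclei`` if fewer than ``min_nuclei``
    nuclei are detected; ``focus_fail`` if the nucleus-channel focus score is
    below ``focus_threshold``.  Excluded fields carry no ``fas_per_cell``
    value.
    """
    fa_channel = field.channel("fa")
    nucleus_channel = field.channel("nucleus")

    preprocessed = preprocess_fa_channel(fa_channel, params)
    raw_labels, raw_count = _threshold_components(preprocessed,
                                                  params.otsu_bins)
    _, records = _filter_components(raw_labels, params)

    n_nuclei = count_nuclei(nucleus_channel, params)
    window = min(params.focus_window, min(nucleus_channel.shape))
    score = focus_score(nucleus_channel, window)

    qc = {
        "focus_fail": score < params.focus_threshold,
        "oversegmented": raw_count > params.max_raw_objects,
        "low_nuclei": n_nuclei < params.min_nuclei,
    }
    excluded = any(qc.values())
    fas_per_cell = (len(records) / n_nuclei
                    if not excluded and n_nuclei > 0 else None)
    return FieldQuant(
        n_fas=len(records),
        fa_areas=[r.area for r in records],
        n_nuclei=n_nuclei,
        fas_per_cell=fas_per_cell,
        qc=qc,
        focus_score=score,
        raw_object_count=raw_count,
        well_id=field.well_id,
        field_id=field.field_id,
    )
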