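"""Region-specific source densities over a voxel parcellation.

A parcellation assigns each sample (voxel) an integer region label, e.g. the
17-network cortical atlas plus an unassigned region for background voxels.
Sources are modelled as i.i.d. within a region but may be differently
distributed across regions: for component ``q`` a separate P-spline density
``f_{iq}`` is fitted to the component's values inside each region ``i``, and
every voxel contributes the log-density of its own region's model to the
ICA likelihood.  With a single region this reduces exactly to the global
algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import pspline_density as psd

logger = logging.getLogger(__name__)

__all__ = [
    "ParcellationMap",
    "merge_small_regions",
    "fit_region_densities",
    "per_voxel_log_density",
    "load_parcellation",
]


@dataclass(frozen=True)
class ParcellationMap:
    """Integer region label per sample.

    ``labels`` are 0-based region indices into ``region_ids`` (the original
    label values, sorted); ``region_sizes[i]`` counts the samples in region i.
    """

    labels: np.ndarray
    region_ids: np.ndarray
    region_sizes: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.region_ids.size

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @classmethod
    def from_labels(cls, raw_labels) -> "ParcellationMap":
        raw = np.asarray(raw_labels)
        if raw.ndim != 1 or raw.size == 0:
            raise ValueError("labels must be a nonempty 1-D integer vector")
        if not np.issubdtype(raw.dtype, np.integer):
            as_int = raw.astype(np.int64)
            if not np.array_equal(as_int, raw):
                raise ValueError("labels must be integers")
            raw = as_int
        ids, inverse, counts = np.unique(raw, return_inverse=True, return_counts=True)
        return cls(labels=inverse.astype(np.int64), region_ids=ids.astype(np.int64),
                   region_sizes=counts.astype(np.int64))

    @classmethod
    def single(cls, n_samples: int) -> "ParcellationMap":
        """Trivial one-region map covering all samples."""
        return cls(labels=np.zeros(n_samples, dtype=np.int64),
                   region_ids=np.array([1], dtype=np.int64),
                   region_sizes=np.array([n_samples], dtype=np.int64))


def merge_small_regions(pmap: ParcellationMap, min_size: int) -> ParcellationMap:
    """Merge regions smaller than ``min_size`` into the nearest-id region.

    Tiny regions make histogram fitting unstable; each undersized region is
    absorbed by the surviving region whose original id is numerically
    closest (ties toward the smaller id).  Idempotent once all regions meet
    the threshold.
    """
    ids = list(pmap.region_ids)
    sizes = dict(zip(ids, pmap.region_sizes.tolist()))
    raw = pmap.region_ids[pmap.labels]  # back to original id space
    merged = {i: i for i in ids}
    while len(ids) > 1:
        small = [i for i in ids if sizes[i] < min_size]
        if not small:
            break
        victim = min(small, key=lambda i: (sizes[i], i))
        others = [i for i in ids if i != victim]
        target = min(others, key=lambda i: (abs(i - victim), i))
        logger.warning("merging region %d (size %d < %d) into region %d",
                       victim, sizes[victim], min_size, target)
        sizes[target] += sizes.pop(victim)
        ids.remove(victim)
        for k, v in merged.items():
            if v == victim:
                merged[k] = target
    new_raw = np.array([merged[i] for i in raw], dtype=np.int64)
    return ParcellationMap.from_labels(new_raw)


def fit_region_densities(
    s_row,
    pmap: ParcellationMap,
    n_bins: int | None = None,
    n_knots: int = 25,
    degree: int = 3,
    diff_order: int = 3,
    epsilon_factor: float = 0.1,
    delta_grid=(1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3),
    deltas: list | None = None,
) -> list:
    """Fit one P-spline density per region of a component's source values.

    ``deltas`` (optional, mutated in place) caches the AIC-selected penalty
    per region so later refreshes reuse the first selection.  With a single
    region the output is identical to the global fit.
    """
    s_row = np.asarray(s_row, dtype=float)
    if s_row.size != pmap.n_samples:
        raise ValueError("source row length does not match parcellation")
    if deltas is None:
        deltas = [None] * pmap.n_regions
    if len(deltas) != pmap.n_regions:
        raise ValueError("deltas cache length does not match region count")
    models = []
    for i in range(pmap.n_regions):
        vals = s_row[pmap.labels == i]
        try:
            hist = psd.build_histogram(
                vals,
                n_bins=n_bins if n_bins is not None else psd.default_bins(vals.size),
                epsilon=epsilon_factor * float(vals.std()) if vals.size else None,
            )
        except psd.DegenerateSampleError as exc:
            raise psd.DegenerateSampleError(
                f"region {int(pmap.region_ids[i])} has degenerate (constant) values"
            ) from exc
        if deltas[i] is None:
            deltas[i] = psd.select_penalty(hist, delta_grid, n_knots=n_knots,
                                           degree=degree, diff_order=diff_order)
        models.append(psd.fit_penalized_poisson(hist, n_knots=n_knots, degree=degree,
                                                penalty=deltas[i], diff_order=diff_order))
    return models


def per_voxel_log_density(s_row, pmap: ParcellationMap, region_models) -> np.ndarray:
    """log f_{label(v),q}(s_v): each sample scored under its region's density."""
    s_row = np.asarray(s_row, dtype=float)
    if s_row.size != pmap.n_samples:
        raise ValueError("source row length does not match parcellation")
    region_models = list(region_models)
    if len(region_models) != pmap.n_regions:
        raise KeyError(
            f"{pmap.n_regions} regions but {len(region_models)} density models"
        )
    out = np.empty_like(s_row)
    for i, model in enumerate(region_models):
        sel = pmap.labels == i
        if np.any(sel):
            out[sel] = model.log_density(s_row[sel])
    return out


def load_parcellation(source, mask=None) -> ParcellationMap:
    """Build a ParcellationMap from a label volume/array or a label table.

    3-D arrays require a matching boolean mask and are vectorized in the
    same fastest-first-axis order as the data matrices; zero/background
    labels inside the mask become their own "unassigned" region.  1-D label
    vectors are used as-is.
    """
    arr = np.asarray(source)
    if arr.ndim == 1:
        return ParcellationMap.from_labels(np.round(arr).astype(np.int64))
    if arr.ndim == 3:
        if mask is None:
            raise ValueError("a 3-D label volume requires a mask")
        mask = np.asarray(mask)
        if mask.shape != arr.shape:
            raise ValueError(
                f"label volume shape {arr.shape} does not match mask {mask.shape}"
            )
        flat = arr.ravel(order="F")[mask.ravel(order="F") > 0]
        return ParcellationMap.from_labels(np.round(flat).astype(np.int64))
    raise ValueError(f"cannot interpret a {arr.ndim}-D label source")
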