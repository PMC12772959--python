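"""Projection of per-cell features through P into spatial fields.

A per-cell feature f (a gene's imputed expression, a 0/1 annotation
indicator, a regulon or gene-set activity score) projects to the per-bin
expectation sum_c P[c, i] f[c].  Because each bin's distribution is inferred
independently, transitions between adjacent bins are abrupt; a Gaussian
filter suppresses this high-frequency noise.  Thresholding the smoothed
expectation yields a "virtual in situ" image, either at a user percentile or
at an automatically detected elbow of the sorted value curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mapping import MappingMatrix

__all__ = [
    "SpatialField",
    "ThresholdResult",
    "project_feature",
    "project_indicator",
    "smooth",
    "threshold_percentile",
    "auto_threshold",
    "composite_render",
]


@dataclass
class SpatialField:
    """Per-bin scalar expectation of a per-cell feature."""

    values: np.ndarray
    feature: str = ""
    sigma: float = 0.0
    provenance: str = "gene"  # gene | indicator | score

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("field must be a 2-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


@dataclass
class ThresholdResult:
    """A threshold with the mask it induces (>= convention)."""

    threshold: float
    mask: np.ndarray
    method: str
    diagnostics: dict | None = None


def project_feature(P: MappingMatrix, f: np.ndarray, name: str = "",
                    provenance: str = "gene") -> SpatialField:
    """Expectation of feature ``f`` at every bin: field_i = sum_c P[c,i] f[c]."""
    return SpatialField(P.project(f), feature=name, provenance=provenance)


def project_indicator(
    P: MappingMatrix, labels: np.ndarray, target, name: str | None = None
) -> SpatialField:
    """Per-bin probability that the bin's cell carries a categorical label."""
    labels = np.asarray(labels)
    if labels.shape != (P.n_cells,):
        raise ValueError("labels length must match cell count")
    if target not in labels:
        raise KeyError(f"category {target!r} not present in labels")
    f = (labels == target).astype(float)
    return SpatialField(
        P.project(f), feature=name or str(target), provenance="indicator"
    )


def smooth(field: SpatialField, sigma: float = 1.0) -> SpatialField:
    """Gaussian-filter the field (reflective boundary); sigma=0 is identity."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        values = field.values.copy()
    else:
        values = ndimage.gaussian_filter(field.values, sigma=sigma, mode="reflect")
    return SpatialField(values, field.feature, sigma, field.provenance)


def threshold_percentile(field: SpatialField, q: float) -> ThresholdResult:
    """Threshold at the q-th percentile of the *nonzero* field values.

    Zeros dominate sparse fields and would collapse any percentile computed
    over all bins, so they are excluded.  The mask uses a >= comparison, so
    ties at the threshold can push the retained cardinality above nominal.
    """
    if not (0 <= q <= 100):
        raise ValueError(f"percentile q must be in [0, 100], got {q}")
    nz = field.values[field.values != 0]
    if nz.size == 0:
        raise ValueError("cannot threshold an all-zero field")
    thr = float(np.percentile(nz, q))
    return ThresholdResult(thr, field.values >= thr, method=f"percentile q={q}")


def auto_threshold(
    field: SpatialField, k: int = 20, anchor: str = "median"
) -> ThresholdResult:
    """Elbow threshold from the sorted unique nonzero expected values.

    The sorted curve typically has an inverted-sigmoid shape.  Two lines are
    fitted by least squares on the (index, value) plane: one to ``k``
    consecutive values starting at the median index (``anchor='median'``;
    ``anchor='smallest'`` starts at index 0 instead), the other to the ``k``
    largest values.  The threshold is the sorted value nearest the
    intersection abscissa of the two lines.
    """
    if k < 2:
        raise ValueError(f"window size k must be >= 2, got {k}")
    if anchor not in ("median", "smallest"):
        raise ValueError(f"unknown anchor {anchor!r}")
    v = np.unique(field.values[field.values != 0])
    n = v.size
    if n < 2 * k:
        raise ValueError(
            f"need at least 2k={2 * k} unique nonzero values, got {n}"
        )
    start = n // 2 if anchor == "median" else 0
    if start + k > n:
        start = n - k
    lo_idx = np.arange(start, start + k)
    hi_idx = np.arange(n - k, n)
    m1, b1 = np.polyfit(lo_idx, v[lo_idx], 1)
    m2, b2 = np.polyfit(hi_idx, v[hi_idx], 1)
    if np.isclose(m1, m2):
        raise ValueError(
            "fitted lines are parallel; try a larger window size k"
        )
    x_star = (b2 - b1) / (m1 - m2)
    idx = int(np.clip(round(x_star), 0, n - 1))
    thr = float(v[idx])
    return ThresholdResult(
        thr,
        field.values >= thr,
        method=f"auto-elbow k={k}",
        diagnostics={
            "slope_low": float(m1),
            "slope_high": float(m2),
            "intersection_index": float(x_star),
        },
    )


def composite_render(
    fields: list[SpatialField],
    colors: list,
    thresholds: list[ThresholdResult] | None = None,
    point_diameter_um: float = 15.0,
    um_per_bin: float = 3.2,
) -> np.ndarray:
    """Overlay thresholded fields into an RGBA image (purely presentational).

    Each field is rendered in its own color, with per-bin alpha proportional
    to the (masked) field value; fields are composited in list order
    (later fields over earlier).  The point diameter (default 15 um, an
    average mammalian cell) controls a small dilation so isolated bins stay
    visible at print scale.
    """
    from matplotlib.colors import to_rgba

    if len(fields) != len(colors):
        raise ValueError("one color per field is required")
    if not fields:
        raise ValueError("no fields to render")
    shape = fields[0].values.shape
    for f in fields:
        if f.values.shape != shape:
            raise ValueError("all fields must share a grid")
    if thresholds is not None and len(thresholds) != len(fields):
        raise ValueError("one threshold per field is required when given")

    radius_bins = max(int(round(point_diameter_um / um_per_bin / 2)), 0)
    img = np.zeros(shape + (4,), dtype=float)
    for i, (f, c) in enumerate(zip(fields, colors)):
        vals = f.values.copy()
        if thresholds is not None:
            vals = np.where(thresholds[i].mask, vals, 0.0)
        if radius_bins > 0:
            vals = ndimage.grey_dilation(vals, size=2 * radius_bins + 1)
        vmax = vals.max()
        alpha = vals / vmax if vmax > 0 else vals
        rgba = np.array(to_rgba(c))
        layer = np.empty(shape + (4,))
        layer[..., :3] = rgba[:3]
        layer[..., 3] = alpha * rgba[3]
        # standard "over" compositing
        a = layer[..., 3:4]
        img[..., :3] = layer[..., :3] * a + img[..., :3] * (1 - a)
        img[..., 3:4] = a + img[..., 3:4] * (1 - a)
    return img
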