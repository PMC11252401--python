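"""Time-series preprocessing and functional-connectivity construction.

Implements the standard resting-state coupling pipeline: global-mean signal
regression, parcellation of vertex data, Fisher z-transformed Pearson
correlation matrices between hippocampal vertices and cortical parcels
(and cortex with itself), group averaging, and simple summary maps
(column-maximum connectivity, flatmap-sector connectivity, temporal SNR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import FlatmapGrid

# Fisher z is undefined at |r| = 1; correlations are clipped just inside.
FISHER_CLIP = 1.0 - 1e-7

SPACE_KINDS = (
    "hippocampal-vertex",
    "cortical-vertex",
    "cortical-parcel",
    "concatenated",
)


@dataclass
class TimeSeries:
    """A space x time data matrix for one subject and one structure."""

    values: np.ndarray
    space_kind: str
    subject_id: str = ""
    species_tag: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D space x time matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.space_kind not in SPACE_KINDS:
            raise ValueError(f"unknown space_kind {self.space_kind!r}")

    @property
    def n_space(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Fisher z-transformed correlation matrix between two vertex/parcel sets."""

    values: np.ndarray
    row_kind: str
    col_kind: str
    species_tag: str = ""
    averaged_over: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("connectivity values must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


def fisher_z(r):
    """Fisher r-to-z transform, ``arctanh(r)``, with |r| clipped to 1 - 1e-7.

    Accepts scalars or arrays.  Values with ``|r| > 1`` (beyond a 1e-12
    numerical slack) are rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    return float(z) if z.ndim == 0 else z


def regress_global_mean(ts: TimeSeries) -> TimeSeries:
    """Regress the spatial-mean time series (plus intercept) out of each row.

    Each row is replaced by its least-squares residual after regression on
    the mean-over-space series and a constant; residuals are orthogonal to
    both regressors.  If the mean series has zero variance, only the
    intercept is regressed (rows are demeaned) and a warning is emitted.
    """
    X = ts.values
    g = X.mean(axis=0)
    if np.ptp(g) < 1e-300 or np.std(g) == 0.0:
        warnings.warn(
            "global mean series is constant; regressing intercept only",
            RuntimeWarning,
        )
        design = np.ones((X.shape[1], 1))
    else:
        design = np.column_stack([g, np.ones_like(g)])
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    resid = X - (design @ beta).T
    return replace(ts, values=resid)


def parcellate_timeseries(ts: TimeSeries, labels, expected_labels=None) -> TimeSeries:
    """Average vertex series within parcels.

    Parameters
    ----------
    labels : array of int, one per vertex (row of ``ts``)
        Parcel membership.  Output parcels are ordered by ascending label.
    expected_labels : optional iterable of int
        If given, every listed parcel must be non-empty; an empty parcel
        raises an error naming it.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != ts.n_space:
        raise ValueError("one label per vertex required")
    present = np.unique(labels)
    if expected_labels is not None:
        for lab in expected_labels:
            if lab not in present:
                raise ValueError(f"parcel {lab} has no member vertices")
    out = np.stack([ts.values[labels == lab].mean(axis=0) for lab in present])
    return replace(ts, values=out, space_kind="cortical-parcel")


def _standardize_rows(X):
    """Rows z-scored with sample (n-1) normalisation; zero-variance rows -> 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = Xc / sd_safe[:, None]
    Z[degenerate] = 0.0
    return Z, degenerate


def pearson_rows(a_values: np.ndarray, b_values: np.ndarray) -> np.ndarray:
    """Pearson r between every row of ``a`` and every row of ``b``.

    Zero-variance rows yield correlation 0 (with a warning), not NaN.
    """
    if a_values.shape[1] != b_values.shape[1]:
        raise ValueError("time dimensions differ")
    T = a_values.shape[1]
    Za, dega = _standardize_rows(a_values)
    Zb, degb = _standardize_rows(b_values)
    if dega.any() or degb.any():
        warnings.warn(
            f"{int(dega.sum()) + int(degb.sum())} zero-variance rows set to "
            "zero correlation",
            RuntimeWarning,
        )
    R = (Za @ Zb.T) / (T - 1)
    return np.clip(R, -1.0, 1.0)


def connectivity_matrix(a: TimeSeries, b: TimeSeries) -> ConnectivityMatrix:
    """Fisher z of the row-by-row Pearson correlation of two series sets.

    With ``b is a`` this yields the square (symmetric) cortico-cortical
    matrix whose diagonal is the clipped-maximum Fisher z.
    """
    R = pearson_rows(a.values, b.values)
    Z = fisher_z(R)
    if a is b or (a.space_kind == b.space_kind and a.values is b.values):
        Z = (Z + Z.T) / 2.0
    tags = a.species_tag if a.species_tag == b.species_tag else f"{a.species_tag}+{b.species_tag}"
    return ConnectivityMatrix(
        values=Z, row_kind=a.space_kind, col_kind=b.space_kind, species_tag=tags
    )


def group_average(matrices) -> ConnectivityMatrix:
    """Element-wise mean of per-subject connectivity matrices.

    The per-subject matrices are already Fisher z-transformed; averaging is
    therefore performed on the z scale (z first, then mean).
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.shape != first.shape:
            raise ValueError("matrices have mismatched shapes")
        if (m.row_kind, m.col_kind) != (first.row_kind, first.col_kind):
            raise ValueError("matrices have mismatched space kinds")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(
        values=mean,
        row_kind=first.row_kind,
        col_kind=first.col_kind,
        species_tag=first.species_tag,
        averaged_over=len(matrices),
    )


def max_connectivity_map(dense: ConnectivityMatrix) -> np.ndarray:
    """Per-cortical-element maximum coupling with any hippocampal vertex.

    ``dense`` must have hippocampal rows; the result is the column-wise max.
    """
    if dense.row_kind != "hippocampal-vertex":
        raise ValueError("rows must be hippocampal vertices")
    return dense.values.max(axis=0)


# Quadrant sector names.  "Medial"/"lateral" follow the distal-proximal
# flatmap coordinate: medial = distal (pd < 0.5), lateral = proximal.
SECTOR_NAMES = (
    "anterior-medial",
    "anterior-lateral",
    "posterior-medial",
    "posterior-lateral",
)


def sector_masks(grid: FlatmapGrid) -> dict:
    """Boolean vertex masks of the four flatmap quadrants (split at 0.5)."""
    ant = grid.ap_coord >= 0.5
    med = grid.pd_coord < 0.5
    masks = {
        "anterior-medial": ant & med,
        "anterior-lateral": ant & ~med,
        "posterior-medial": ~ant & med,
        "posterior-lateral": ~ant & ~med,
    }
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"sector {name!r} is empty on this grid")
    return masks


def sector_connectivity(hippo_ts: TimeSeries, cortex_ts: TimeSeries, grid: FlatmapGrid) -> dict:
    """Coupling of each cortical element with the mean series of each of the
    four hippocampal flatmap sectors (anterior/posterior x medial/lateral).

    Returns a dict of sector name -> per-cortical-element Fisher z map.
    """
    if hippo_ts.n_space != grid.n_vertices:
        raise ValueError("grid does not match hippocampal series")
    masks = sector_masks(grid)
    maps = {}
    for name, mask in masks.items():
        sector_mean = hippo_ts.values[mask].mean(axis=0)[None, :]
        r = pearson_rows(sector_mean, cortex_ts.values)[0]
        maps[name] = fisher_z(r)
    return maps


def tsnr_map(ts: TimeSeries):
    """Temporal SNR per row: temporal mean over sample SD (ddof=1).

    Returns ``(tsnr, valid)``; rows with zero temporal variance get
    ``tsnr = +inf`` and ``valid = False``.
    """
    mean = ts.values.mean(axis=1)
    sd = ts.values.std(axis=1, ddof=1)
    valid = sd > 0.0
    tsnr = np.full_like(mean, np.inf)
    tsnr[valid] = mean[valid] / sd[valid]
    return tsnr, valid


def smooth_flatmap_timeseries(ts: TimeSeries, grid: FlatmapGrid, sigma: float) -> TimeSeries:
    """Optional isotropic Gaussian smoothing on the flatmap lattice.

    ``sigma`` is in grid units (vertices); 0 disables smoothing.  This is a
    grid approximation of surface smoothing; physical kernel widths in mm
    are mesh-dependent and intentionally not modelled.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return ts
    if ts.n_space != grid.n_vertices:
        raise ValueError("grid does not match series")
    cube = ts.values.reshape(grid.n_ap, grid.n_pd, ts.n_time)
    smoothed = ndimage.gaussian_filter(cube, sigma=(sigma, sigma, 0), mode="nearest")
    return replace(ts, values=smoothed.reshape(grid.n_vertices, ts.n_time))
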