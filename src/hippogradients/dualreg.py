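"""Dual regression of the hippocampal flatmap axes and reprojection of the
cortex into the 2D intrinsic hippocampal coordinate space.

Stage 1 projects each subject's concatenated (cortex + hippocampus) data
onto an orthogonal design holding the binned AP and PD axis regressors,
yielding one time series per axis; stage 2 regresses those time series back
into the data, yielding per-element coupling maps.  The two cortical axis
maps then serve as coordinates of a 2D embedding that mirrors the
hippocampal flatmap itself, in which regions can be compared across species
with two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .connectivity import TimeSeries
from .grids import FlatmapGrid


@dataclass
class AxisDesign:
    """Orthogonal (AP, PD, intercept) spatial design over cortex + hippocampus.

    The element order is the cortical block followed by the hippocampal
    block; the axis columns are zero on every cortical element, lie in
    [-1, 1], and sum to zero over the hippocampal block.
    """

    matrix: np.ndarray  # (n_cortex + n_hippo, 3)
    ap_bins: int
    pd_bins: int
    n_cortex: int

    @property
    def n_elements(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AxisMaps:
    """Per-cortical-element coupling with the two hippocampal axes."""

    ap_map: np.ndarray
    pd_map: np.ndarray
    species_tag: str = ""


@dataclass
class Embedding2D:
    """Cortical elements placed in the rescaled 2D hippocampal space."""

    x: np.ndarray  # AP coordinate in [0, 1]
    y: np.ndarray  # PD coordinate in [0, 1]
    aspect_ratio: float = 1.0
    bounds: dict = field(default_factory=dict)
    species_tag: str = ""


def _bin_values(coord: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each vertex to the nearest of ``n_bins`` coordinate bins and
    return the bin's linearly spaced value in [-1, 1]."""
    idx = np.clip(np.floor(coord * n_bins).astype(int), 0, n_bins - 1)
    return -1.0 + 2.0 * idx / (n_bins - 1)


def build_axis_design(
    grid: FlatmapGrid, n_cortex: int, ap_bins: int = 16, pd_bins: int = 8
) -> AxisDesign:
    """Binned-axis design matrix over concatenated cortex + hippocampus.

    Hippocampal vertices in AP bin ``i`` of ``B`` get the value
    ``-1 + 2i/(B-1)`` (most posterior = -1, most anterior = +1); likewise
    for PD (most distal = -1, most proximal = +1).  Cortical elements are 0
    on both axis columns; the intercept column is all ones.  Axis columns
    are mean-centred within the hippocampal block, which keeps the cortical
    zeros intact and makes all three columns mutually orthogonal on any
    evenly binned grid.
    """
    if ap_bins < 2 or pd_bins < 2:
        raise ValueError("need at least 2 bins per axis")
    if n_cortex < 0:
        raise ValueError("n_cortex must be non-negative")
    ap = _bin_values(grid.ap_coord, ap_bins)
    pd = _bin_values(grid.pd_coord, pd_bins)
    ap = ap - ap.mean()
    pd = pd - pd.mean()
    V = grid.n_vertices
    X = np.zeros((n_cortex + V, 3))
    X[n_cortex:, 0] = ap
    X[n_cortex:, 1] = pd
    X[:, 2] = 1.0
    return AxisDesign(matrix=X, ap_bins=ap_bins, pd_bins=pd_bins, n_cortex=n_cortex)


def dual_regress(data: TimeSeries, design: AxisDesign):
    """Two-stage dual regression of the axis design into subject data.

    Stage 1: ``T3 = pinv(X) @ D`` gives one time series per regressor.
    Stage 2: ``B = D @ pinv(T3)`` gives per-element coefficients.  Returns
    ``(axis_time_series, AxisMaps)`` where the maps are the cortical block
    of the AP and PD coefficient columns.
    """
    D = data.values
    X = design.matrix
    if D.shape[0] != X.shape[0]:
        raise ValueError(
            f"data has {D.shape[0]} elements but design expects {X.shape[0]}"
        )
    if D.shape[1] < 3:
        raise ValueError("need at least 3 time points for 3 regressors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    T3 = np.linalg.pinv(X) @ D
    B = D @ np.linalg.pinv(T3)
    nC = design.n_cortex
    maps = AxisMaps(
        ap_map=B[:nC, 0].copy(),
        pd_map=B[:nC, 1].copy(),
        species_tag=data.species_tag,
    )
    return T3, maps


def group_mean_axis_maps(maps_list) -> AxisMaps:
    """Unweighted subject mean of per-subject axis maps."""
    maps_list = list(maps_list)
    if not maps_list:
        raise ValueError("no subject maps to average")
    return AxisMaps(
        ap_map=np.mean([m.ap_map for m in maps_list], axis=0),
        pd_map=np.mean([m.pd_map for m in maps_list], axis=0),
        species_tag=maps_list[0].species_tag,
    )


def reproject_to_flatmap_space(
    ap_map, pd_map, grid: FlatmapGrid, exclude: float = 0.10, species_tag: str = ""
) -> Embedding2D:
    """Use the two axis maps as 2D coordinates in hippocampal space.

    Each axis is linearly rescaled so that its ``exclude`` and
    ``1 - exclude`` percentiles map to 0 and 1; values beyond them are
    clipped (the top/bottom 10% of elements on either end are excluded from
    the rescaling fit).  The aspect ratio mirrors the flatmap grid.
    """
    out = {}
    bounds = {}
    for name, v in (("x", np.asarray(ap_map, float)), ("y", np.asarray(pd_map, float))):
        lo, hi = np.percentile(v, [100 * exclude, 100 * (1 - exclude)])
        if hi <= lo:
            raise ValueError("constant axis map cannot be rescaled")
        out[name] = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
        bounds[name] = (float(lo), float(hi))
    return Embedding2D(
        x=out["x"],
        y=out["y"],
        aspect_ratio=grid.n_ap / grid.n_pd,
        bounds=bounds,
        species_tag=species_tag,
    )


def ks_region_comparison(
    embeddings_a,
    embeddings_b,
    roi,
    axis: str = "AP",
    n_comparisons: int = 1,
):
    """Two-sample two-sided KS test of a region's position across species.

    Each subject contributes one summary value: the mean coordinate of the
    ROI's elements along the chosen axis in that subject's 2D embedding.
    The two species' subject-level summaries are compared with an exact
    small-sample KS test; the p-value is Bonferroni-corrected by
    ``n_comparisons``.  Returns ``(D, p, p_corrected)``.
    """
    roi = np.asarray(roi, dtype=int)
    if roi.size == 0:
        raise ValueError("empty ROI")
    if axis not in ("AP", "PD"):
        raise ValueError("axis must be 'AP' or 'PD'")
    if len(embeddings_a) < 2 or len(embeddings_b) < 2:
        raise ValueError("need at least 2 subjects per species")

    def summaries(embs):
        attr = "x" if axis == "AP" else "y"
        return np.array([getattr(e, attr)[roi].mean() for e in embs])

    sa, sb = summaries(embeddings_a), summaries(embeddings_b)
    if np.array_equal(np.sort(sa), np.sort(sb)):
        return 0.0, 1.0, 1.0
    res = ks_2samp(sa, sb, alternative="two-sided", method="exact")
    p_corr = min(1.0, res.pvalue * n_comparisons)
    return float(res.statistic), float(res.pvalue), float(p_corr)
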