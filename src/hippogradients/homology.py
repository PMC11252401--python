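"""Searchlight homology index between species' hippocampal connectivity.

For each parcel of species A, registered into species B's spherical frame
by a given cross-species correspondence, the index is the median Pearson
correlation between its hippocampal connectivity fingerprint and the
fingerprints of all species-B parcels within a geodesic searchlight.  Low
values mark cortical territory whose hippocampal coupling has been
reorganised between the species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix


@dataclass
class CorrespondenceMap:
    """For each species-A parcel, a location on species B's unit sphere."""

    locations: np.ndarray  # (n_parcels_a, 3)

    def __post_init__(self):
        self.locations = np.asarray(self.locations, dtype=float)
        if self.locations.ndim != 2 or self.locations.shape[1] != 3:
            raise ValueError("locations must be (n, 3)")
        norms = np.linalg.norm(self.locations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("correspondence locations must be unit vectors")

    @classmethod
    def identity(cls, sphere_coords) -> "CorrespondenceMap":
        """The identity correspondence (pre-matched parcel frames)."""
        return cls(locations=np.array(sphere_coords, dtype=float))


@dataclass
class HomologyMap:
    """Per-parcel homology values in [-1, 1], with searchlight metadata."""

    values: np.ndarray
    missing: np.ndarray
    radius: float
    neighbor_counts: np.ndarray
    network_summary: dict = field(default_factory=dict)


def searchlight_neighbors(
    corr: CorrespondenceMap,
    target_coords,
    radius: float,
    sphere_radius: float = 1.0,
):
    """Species-B parcels within geodesic ``radius`` of each registered parcel.

    Distances are great-circle arcs on a sphere of physical radius
    ``sphere_radius`` (same units as ``radius``).  Parcels with no neighbor
    are flagged by an empty list, not an error.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tgt = np.asarray(target_coords, dtype=float)
    tgt = tgt / np.linalg.norm(tgt, axis=1, keepdims=True)
    cos = np.clip(corr.locations @ tgt.T, -1.0, 1.0)
    dist = sphere_radius * np.arccos(cos)
    return [np.flatnonzero(row <= radius) for row in dist]


def _corr_one_to_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc)
    Yn = np.linalg.norm(Yc, axis=1)
    ok = (xn > 0) & (Yn > 0)
    out = np.full(Y.shape[0], np.nan)
    out[ok] = (Yc[ok] @ xc) / (Yn[ok] * xn)
    return np.clip(out, -1.0, 1.0)


def homology_index(
    C_A: ConnectivityMatrix,
    C_B: ConnectivityMatrix,
    neighbors,
    radius: float = np.nan,
) -> HomologyMap:
    """Median searchlight correlation of hippocampal fingerprints.

    ``C_A`` and ``C_B`` are parcels x hippocampal-vertex matrices sharing
    the hippocampal vertex order (the matched flatmap).  Parcel ``p`` of
    species A gets the median Pearson r between its fingerprint and every
    neighboring species-B fingerprint; parcels with no neighbors or a
    zero-variance fingerprint are flagged missing.
    """
    A, B = C_A.values, C_B.values
    if A.shape[1] != B.shape[1]:
        raise ValueError("matrices must share the hippocampal vertex set")
    if len(neighbors) != A.shape[0]:
        raise ValueError("one neighbor list per species-A parcel required")
    n = A.shape[0]
    values = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    counts = np.zeros(n, dtype=int)
    for p in range(n):
        nbrs = np.asarray(neighbors[p], dtype=int)
        counts[p] = nbrs.size
        if nbrs.size == 0:
            missing[p] = True
            continue
        r = _corr_one_to_many(A[p], B[nbrs])
        r = r[np.isfinite(r)]
        if r.size == 0:
            missing[p] = True
            continue
        values[p] = np.median(r)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} parcels flagged missing (no neighbors or "
            "zero-variance fingerprint)",
            RuntimeWarning,
        )
    return HomologyMap(values=values, missing=missing, radius=radius, neighbor_counts=counts)


def network_mean_homology(hmap: HomologyMap, network_label) -> dict:
    """Unweighted mean homology per cortical network, skipping missing
    parcels; a fully missing network yields None with a warning."""
    labels = np.asarray(network_label, dtype=int)
    if labels.shape[0] != hmap.values.shape[0]:
        raise ValueError("one network label per parcel required")
    summary = {}
    for k in np.unique(labels):
        sel = (labels == k) & ~hmap.missing
        if not sel.any():
            warnings.warn(f"network {k} has no valid parcels", RuntimeWarning)
            summary[int(k)] = None
        else:
            summary[int(k)] = float(hmap.values[sel].mean())
    hmap.network_summary = summary
    return summary
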