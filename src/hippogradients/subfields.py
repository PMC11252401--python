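"""Similarity and proportion statistics for categorical subfield flatmaps.

Because subfields form vertical stripes along the distal-proximal axis, two
maps are compared through their per-row extent profiles: each AP row is a
4-vector of subfield fractions, rows are compared by cosine distance, and
the global similarity is one minus the mean row distance.  Relative
subfield sizes and their cross-species percentage change quantify
proportion shifts that a plain overlap score would miss.
"""

from __future__ import annotations

import warnings

import numpy as np

from .synth import SUBFIELD_NAMES, SubfieldFlatmap


def subfield_extent_profile(sf: SubfieldFlatmap) -> np.ndarray:
    """Per-AP-row fractions of the four subfields, shape (n_ap, 4).

    Row ``i``, subfield ``s`` = (# vertices of ``s`` in row ``i``) / n_pd;
    rows sum to 1 exactly.
    """
    grid = sf.grid
    lab = sf.labels.reshape(grid.n_ap, grid.n_pd)
    prof = np.stack([(lab == s).sum(axis=1) for s in range(4)], axis=1)
    return prof / grid.n_pd


def _resample_rows(profile: np.ndarray, n_ap: int) -> np.ndarray:
    """Linear interpolation of a profile onto ``n_ap`` rows along the
    normalized AP coordinate."""
    src = (np.arange(profile.shape[0]) + 0.5) / profile.shape[0]
    dst = (np.arange(n_ap) + 0.5) / n_ap
    return np.stack([np.interp(dst, src, profile[:, s]) for s in range(4)], axis=1)


def flatmap_similarity(a: np.ndarray, b: np.ndarray, mode: str = "one-minus-mean-distance") -> float:
    """Similarity of two extent profiles via per-row cosine distance.

    Row ``i`` contributes the cosine distance ``d_i = 1 - cos(a_i, b_i)``
    in the 4D subfield-extent space.  The default similarity is
    ``1 - mean_i d_i``; ``mode="mean-cosine"`` returns ``mean_i cos`` (the
    two coincide for profiles, since rows are non-negative).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 4 or b.ndim != 2 or b.shape[1] != 4:
        raise ValueError("profiles must be (n_ap, 4)")
    if a.shape[0] != b.shape[0]:
        n = min(a.shape[0], b.shape[0])
        warnings.warn(
            f"unequal row counts; resampling both profiles to {n} rows",
            RuntimeWarning,
        )
        a, b = _resample_rows(a, n), _resample_rows(b, n)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if (na == 0).any() or (nb == 0).any():
        raise ValueError("zero row vector in extent profile")
    cos = np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)
    if mode == "one-minus-mean-distance":
        return float(1.0 - np.mean(1.0 - cos))
    if mode == "mean-cosine":
        return float(np.mean(cos))
    raise ValueError(f"unknown mode {mode!r}")


def relative_subfield_size(profile: np.ndarray) -> np.ndarray:
    """4x4 table of total-extent ratios between subfields.

    Entry (s, t) = total extent of subfield s / total extent of t; a
    zero-extent subfield produces NaN entries with a warning.
    """
    profile = np.asarray(profile, dtype=float)
    totals = profile.sum(axis=0)
    table = np.full((4, 4), np.nan)
    zero = totals == 0
    if zero.any():
        names = [SUBFIELD_NAMES[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-extent subfields {names}; ratios set to NaN", RuntimeWarning)
    ok = ~zero
    table[np.ix_(ok, ok)] = totals[ok][:, None] / totals[ok][None, :]
    return table


def percent_change(ratio_a: np.ndarray, ratio_b: np.ndarray) -> np.ndarray:
    """Element-wise percentage change ``100 * (a - b) / b``; NaNs propagate."""
    ratio_a = np.asarray(ratio_a, dtype=float)
    ratio_b = np.asarray(ratio_b, dtype=float)
    if ratio_a.shape != ratio_b.shape:
        raise ValueError("ratio tables must have matching shapes")
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * (ratio_a - ratio_b) / ratio_b
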