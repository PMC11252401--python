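"""Matching a target gradient map against candidate cortical gradient maps.

Covers the full matching recipe: rank-based gaussianization of the maps,
L1-penalised (LASSO) feature selection over the candidates, per-candidate
univariate OLS goodness of fit, spin-test significance with Bonferroni
correction, and a threshold-Dice analysis over all singletons, pairs and
triplets of candidates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import ndtri
from scipy.stats import pearsonr, rankdata, special_ortho_group
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

DEFAULT_Q_GRID = tuple(np.round(np.arange(0.70, 0.951, 0.05), 2))


@dataclass
class MatchReport:
    """Results of matching one target map against candidate maps."""

    lasso_coefs: np.ndarray | None = None
    ols_coefs: np.ndarray | None = None
    r_squared: np.ndarray | None = None
    spin_p: np.ndarray | None = None
    spin_p_corrected: np.ndarray | None = None
    dice_table: dict = field(default_factory=dict)  # (subset, q) -> dice
    best_set: tuple = ()
    best_q: float | None = None
    best_dice: float | None = None
    notes: dict = field(default_factory=dict)


def quantile_gaussianize(values) -> np.ndarray:
    """Map the empirical distribution onto standard-normal quantiles.

    Rank-based and monotone; ties receive averaged ranks, so the transform
    is idempotent up to tie handling.  Requires >= 3 non-constant items.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1D map with at least 3 items")
    if np.ptp(x) == 0:
        raise ValueError("cannot gaussianize a constant map")
    ranks = rankdata(x, method="average")
    return ndtri(ranks / (x.size + 1))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant map cannot be standardized")
    return (v - v.mean()) / sd


def lasso_select(target, candidates, penalty: float = 0.1) -> np.ndarray:
    """L1-penalised regression of the target on all candidates.

    Inputs are z-scored; returns the (sparse) per-candidate coefficient
    vector at the given penalty (scikit-learn ``Lasso`` parameterisation).
    """
    y = _standardize(np.asarray(target, dtype=float))
    X = np.column_stack([_standardize(np.asarray(c, dtype=float)) for c in candidates])
    if X.shape[0] != y.size:
        raise ValueError("target and candidates must have the same length")
    model = Lasso(alpha=penalty, fit_intercept=True, max_iter=200_000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"LASSO failed to converge (penalty={penalty}, "
                f"n={y.size}, p={X.shape[1]}): {exc}"
            ) from exc
    return model.coef_


def ols_fit(target, candidate):
    """Univariate OLS with intercept: returns ``(coefficient, r_squared)``."""
    y = np.asarray(target, dtype=float)
    x = np.asarray(candidate, dtype=float)
    if x.size != y.size:
        raise ValueError("maps must have the same length")
    if np.ptp(x) == 0:
        raise ValueError("constant candidate map")
    xc = x - x.mean()
    beta = float(xc @ (y - y.mean()) / (xc @ xc))
    r = float(pearsonr(x, y).statistic)
    return beta, r * r


def random_rotations(n: int, seed) -> np.ndarray:
    """n rotations drawn uniformly from SO(3)."""
    rng = np.random.default_rng(seed)
    rots = special_ortho_group.rvs(3, size=n, random_state=rng)
    return rots.reshape(n, 3, 3)


def spin_test(map_a, map_b, sphere_coords, n_perm: int = 1000, seed=None) -> float:
    """Spatial-permutation (spin) test of the correlation of two maps.

    The null is built by rotating ``map_b``'s sphere coordinates by uniform
    random rotations, reassigning values by nearest rotated neighbour, and
    recomputing Pearson r.  Two-sided p with the add-one permutation rule:
    ``p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1)``.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    coords = np.asarray(sphere_coords, dtype=float)
    if not (a.size == b.size == coords.shape[0]):
        raise ValueError("maps and coordinates must be aligned")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.allclose(coords, coords[0]):
        raise ValueError("degenerate sphere coordinates")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map has no defined correlation")
    r_obs = pearsonr(a, b).statistic
    rots = random_rotations(n_perm, seed)
    count = 0
    for R in rots:
        rotated = coords @ R.T
        _, idx = cKDTree(rotated).query(coords, k=1)
        b_null = b[idx]
        if np.ptp(b_null) == 0:
            continue
        r_null = pearsonr(a, b_null).statistic
        if abs(r_null) >= abs(r_obs):
            count += 1
    return (1 + count) / (n_perm + 1)


def _supra_mask(v: np.ndarray, q: float) -> np.ndarray:
    """Strictly-above-own-quantile mask; ties at the quantile are excluded."""
    return v > np.quantile(v, q)


def dice_at_quantile(map_a, map_b, q: float) -> float:
    """Dice overlap of the two maps' own suprathreshold (> q-quantile) sets."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != b.size:
        raise ValueError("maps must have the same length")
    if not 0.0 <= q < 1.0:
        raise ValueError("q must lie in [0, 1)")
    ma, mb = _supra_mask(a, q), _supra_mask(b, q)
    denom = ma.sum() + mb.sum()
    if denom == 0:
        warnings.warn("empty suprathreshold sets; Dice set to 0", RuntimeWarning)
        return 0.0
    return 2.0 * np.logical_and(ma, mb).sum() / denom


def best_map_combination(target, candidates, q_grid=DEFAULT_Q_GRID) -> MatchReport:
    """Dice of the target's suprathreshold mask against the mask union of
    every singleton, pair and triplet of candidates, over a threshold grid.

    Returns a MatchReport whose ``dice_table`` maps ``(subset, q)`` to Dice
    and whose ``best_*`` fields hold the arg-max.
    """
    t = np.asarray(target, dtype=float)
    cands = [np.asarray(c, dtype=float) for c in candidates]
    if len(cands) < 2:
        raise ValueError("need at least 2 candidate maps")
    report = MatchReport(notes={"combination_rule": "union-of-masks"})
    best = (-1.0, (), None)
    for q in q_grid:
        tm = _supra_mask(t, q)
        masks = [_supra_mask(c, q) for c in cands]
        for size in (1, 2, 3):
            for subset in itertools.combinations(range(len(cands)), size):
                union = np.logical_or.reduce([masks[i] for i in subset])
                denom = tm.sum() + union.sum()
                dice = 0.0 if denom == 0 else 2.0 * np.logical_and(tm, union).sum() / denom
                report.dice_table[(subset, float(q))] = float(dice)
                if dice > best[0]:
                    best = (dice, subset, float(q))
    report.best_dice, report.best_set, report.best_q = best
    return report


def match_maps(
    target,
    candidates,
    sphere_coords=None,
    penalty: float = 0.1,
    n_perm: int = 1000,
    q_grid=DEFAULT_Q_GRID,
    seed=None,
) -> MatchReport:
    """Full matching report for a target map against candidate maps.

    Gaussianizes all maps, runs LASSO selection and per-candidate OLS on the
    gaussianized maps, spin-tests each candidate (if sphere coordinates are
    supplied) with Bonferroni correction across candidates, and performs the
    threshold-Dice combination analysis on the raw maps.
    """
    gt = quantile_gaussianize(target)
    gc = [quantile_gaussianize(c) for c in candidates]
    report = best_map_combination(target, candidates, q_grid=q_grid)
    report.lasso_coefs = lasso_select(gt, gc, penalty=penalty)
    ols = [ols_fit(gt, c) for c in gc]
    report.ols_coefs = np.array([o[0] for o in ols])
    report.r_squared = np.array([o[1] for o in ols])
    if sphere_coords is not None:
        seeds = np.random.SeedSequence(seed).spawn(len(gc))
        report.spin_p = np.array(
            [
                spin_test(gt, c, sphere_coords, n_perm=n_perm, seed=s)
                for c, s in zip(gc, seeds)
            ]
        )
        report.spin_p_corrected = np.minimum(1.0, report.spin_p * len(gc))
        report.notes["correction"] = "bonferroni"
    return report
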