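"""Affinity kernels and diffusion-map embedding of connectivity matrices.

Connectivity gradients are the leading non-trivial eigenvectors of a
degree-normalised Markov transition operator built from a normalised-angle
affinity between connectivity fingerprints.  The module provides the kernel,
the embedding, and the three gradient constructions used in the analysis:
species-specific hippocampal gradients, the joint two-species embedding of
cortical parcels, and cortico-cortical gradients.

Conventions (all configurable): rows are sparsified to their top 10% of
entries before the kernel; the diffusion normalisation exponent is
``alpha = 0.5``; components use the automatic-diffusion-time scaling
``lambda / (1 - lambda)``; each component's sign is fixed so that its
largest-magnitude element is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .connectivity import ConnectivityMatrix, TimeSeries, connectivity_matrix, group_average

DENSE_EIG_LIMIT = 2000


@dataclass
class AffinityMatrix:
    """Symmetric normalised-angle similarity matrix with unit diagonal."""

    values: np.ndarray
    kernel: str = "normalized-angle"
    sparsity: float = 0.9

    def __post_init__(self):
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("affinity must be square")
        if np.abs(V - V.T).max() > 1e-10:
            raise ValueError("affinity must be symmetric within 1e-10")
        if V.min() < -1e-12 or V.max() > 1.0 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        if np.abs(np.diag(V) - 1.0).max() > 1e-12:
            raise ValueError("affinity diagonal must be 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Ordered spectral components (gradients) with their eigenvalues.

    ``components`` has shape (k, n): component ``i`` is ``components[i]``.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    alpha: float
    n_components: int
    source: str = ""

    def component(self, i: int) -> np.ndarray:
        return self.components[i]


def normalized_angle_affinity(M: np.ndarray, sparsity: float = 0.9) -> AffinityMatrix:
    """Normalised-angle affinity between the rows of a feature matrix.

    Per row the smallest ``sparsity`` fraction of entries is zeroed, then
    ``S_ij = 1 - arccos(cos(row_i, row_j)) / pi`` on the sparsified rows,
    symmetrised as ``(S + S^T) / 2``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("feature matrix must be 2D")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    n, p = M.shape
    X = M.copy()
    n_zero = int(np.floor(sparsity * p))
    if n_zero > 0:
        idx = np.argpartition(X, n_zero - 1, axis=1)[:, :n_zero]
        np.put_along_axis(X, idx, 0.0, axis=1)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise ValueError(f"rows {bad.tolist()} are zero after sparsification")
    Xn = X / norms[:, None]
    C = np.clip(Xn @ Xn.T, -1.0, 1.0)
    S = 1.0 - np.arccos(C) / np.pi
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return AffinityMatrix(values=S, kernel="normalized-angle", sparsity=sparsity)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|.| element is positive."""
    out = components.copy()
    for i, c in enumerate(out):
        j = int(np.argmax(np.abs(c)))
        if c[j] < 0:
            out[i] = -c
    return out


def diffusion_map_embed(
    S: AffinityMatrix,
    n_components: int = 10,
    alpha: float = 0.5,
    seed: int | None = None,
) -> GradientSet:
    """Diffusion-map embedding of an affinity matrix.

    The affinity is degree-normalised on both sides by ``d^-alpha``, row
    normalised into a Markov transition matrix, and eigendecomposed.  The
    trivial constant eigenvector (eigenvalue 1) is dropped; the remaining
    leading eigenvectors are scaled by ``lambda / (1 - lambda)`` (the
    automatic diffusion-time convention) and returned sorted by eigenvalue.

    Uses a dense symmetric eigensolver up to n = 2000 and a seeded Lanczos
    solver above; the two agree to 1e-8 by contract.
    """
    W0 = S.values
    n = S.n
    if not 1 <= n_components < n:
        raise ValueError("need 1 <= n_components < n")
    # connectivity of the affinity graph
    graph = csr_matrix((W0 > 1e-12).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected; component sizes {sizes}")
    if np.ptp(W0) < 1e-12:
        raise ValueError("degenerate affinity: all pairwise similarities equal")

    d = W0.sum(axis=1)
    W = W0 / np.outer(d**alpha, d**alpha)
    d2 = W.sum(axis=1)
    # symmetric conjugate of the transition matrix P = D2^-1 W
    inv_sqrt = 1.0 / np.sqrt(d2)
    Msym = W * np.outer(inv_sqrt, inv_sqrt)
    Msym = (Msym + Msym.T) / 2.0

    k = n_components + 1  # keep the trivial pair for removal
    if n <= DENSE_EIG_LIMIT:
        evals, evecs = eigh(Msym, subset_by_index=[n - k, n - 1])
        evals, evecs = evals[::-1], evecs[:, ::-1]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        try:
            evals, evecs = eigsh(Msym, k=k, which="LA", v0=v0)
        except Exception as exc:  # pragma: no cover - solver failure path
            raise RuntimeError(f"eigensolver did not converge: {exc}") from exc
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]

    psi = evecs * inv_sqrt[:, None]  # right eigenvectors of P
    # rescale so the trivial eigenvector is the constant 1
    psi = psi / psi[:, 0].mean()
    lam = evals[1:]
    comps = psi[:, 1:]
    if np.any(lam >= 1.0 - 1e-12):
        raise ValueError("non-trivial eigenvalue reached 1; affinity graph degenerate")
    lam = np.clip(lam, 0.0, None)
    scaled = comps * (lam / (1.0 - lam))[None, :]
    components = _fix_signs(scaled.T)
    return GradientSet(
        components=components,
        eigenvalues=lam,
        alpha=alpha,
        n_components=n_components,
        source=f"diffusion-map(alpha={alpha}, n={n})",
    )


def hippocampal_gradients(
    C: ConnectivityMatrix,
    n_components: int = 10,
    sparsity: float = 0.9,
    alpha: float = 0.5,
    seed: int | None = None,
) -> GradientSet:
    """Gradients over hippocampal vertices from a hippocampus x cortex
    connectivity matrix: affinity over hippocampal fingerprints, then
    diffusion-map embedding."""
    if C.row_kind != "hippocampal-vertex":
        raise ValueError("rows must be hippocampal vertices")
    S = normalized_angle_affinity(C.values, sparsity=sparsity)
    g = diffusion_map_embed(S, n_components=n_components, alpha=alpha, seed=seed)
    g.source = f"hippocampal-gradients[{C.species_tag}]"
    return g


def joint_cross_species_embed(
    C_H: ConnectivityMatrix,
    C_M: ConnectivityMatrix,
    n_components: int = 10,
    sparsity: float = 0.9,
    alpha: float = 0.5,
    seed: int | None = None,
):
    """Joint two-species embedding of cortical parcels.

    The two hippocampus x cortex matrices are concatenated along the
    cortical dimension; cortical parcels of both species become the items,
    with their hippocampal connectivity fingerprints as features.  A single
    affinity + embedding is computed and the component values are split back
    into the two species' parcel sets, yielding directly comparable
    gradients G_H and G_M.
    """
    if C_H.values.shape[0] != C_M.values.shape[0]:
        raise ValueError("species matrices must share the hippocampal vertex set")
    if C_H.row_kind != "hippocampal-vertex" or C_M.row_kind != "hippocampal-vertex":
        raise ValueError("rows must be hippocampal vertices")
    items = np.vstack([C_H.values.T, C_M.values.T])
    S = normalized_angle_affinity(items, sparsity=sparsity)
    g = diffusion_map_embed(S, n_components=n_components, alpha=alpha, seed=seed)
    nH = C_H.values.shape[1]
    g_h = GradientSet(
        components=g.components[:, :nH],
        eigenvalues=g.eigenvalues,
        alpha=alpha,
        n_components=n_components,
        source=f"joint-embed[{C_H.species_tag}]",
    )
    g_m = GradientSet(
        components=g.components[:, nH:],
        eigenvalues=g.eigenvalues,
        alpha=alpha,
        n_components=n_components,
        source=f"joint-embed[{C_M.species_tag}]",
    )
    return g_h, g_m


def corticocortical_gradients(
    cortex_ts_list: list,
    n_components: int = 10,
    sparsity: float = 0.9,
    alpha: float = 0.5,
    seed: int | None = None,
) -> GradientSet:
    """Cortico-cortical gradients: per-subject square parcel x parcel
    connectivity, group average, affinity, embedding."""
    mats = [connectivity_matrix(ts, ts) for ts in cortex_ts_list]
    C = group_average(mats)
    S = normalized_angle_affinity(C.values, sparsity=sparsity)
    g = diffusion_map_embed(S, n_components=n_components, alpha=alpha, seed=seed)
    g.source = f"corticocortical-gradients[{C.species_tag}]"
    return g
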