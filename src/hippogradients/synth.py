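"""Synthetic two-species datasets with planted connectivity structure.

The generator emulates the statistical skeleton of paired human/macaque
resting-state data: a small set of latent network time courses shared by
hippocampus and cortex, two additional latent factors tied to the intrinsic
hippocampal flatmap axes, species-specific attenuation of one network's
hippocampal coupling (the planted "evolutionary divergence"), Gaussian
observation noise, and striped categorical subfield maps.  Every planted
quantity is stored as ground truth so downstream stages can be validated
against it.

Generative model
----------------
Latent factors ``u_k(t)`` are iid standard normal (optionally AR(1)):
one factor per cortical network plus two axis factors.  Hippocampal vertex
``v`` loads ``2*ap(v) - 1`` on the AP axis factor and ``2*pd(v) - 1`` on the
PD axis factor; its loading on network factor ``k`` is a smooth Gaussian
bump along the AP axis (bump centres tile the axis), orthogonalised against
the two linear axis loadings, and scaled by the species coupling gain for
that network.  Cortical parcels load 1 on their own network factor and load
smooth unit-sphere coordinate maps on the two axis factors.  Species H and M
share the per-subject latent draws and all loadings except the coupling
gain of the divergent network, which is attenuated by ``1 - divergence`` in
species M.  Observations are ``loadings @ u + noise_sd * eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import TimeSeries
from .grids import FlatmapGrid

SUBFIELD_NAMES = ("subicular complex", "CA1", "CA2", "CA3/4")

# Frozen generator amplitudes (see docs/methods.md): network bump amplitude,
# bump width as a fraction of the AP axis per network (wide enough that
# adjacent networks' hippocampal territories overlap and the coupling
# changes gradually along AP), and the amplitude of the cortical
# axis-factor loading maps.
NETWORK_BUMP_AMP = 0.9
NETWORK_BUMP_WIDTH = 0.6  # sigma = NETWORK_BUMP_WIDTH / n_networks
# Each network factor drives a small blend of neighbouring spatial profiles
# (Gaussian in network index, sd in index units), so hippocampal coupling
# varies gradually along AP and attenuating one coupling row changes the
# shape, not just the scale, of that network's fingerprint.
NETWORK_COUPLING_BLEND = 0.4
# The long (AP) axis dominates the short (PD) axis in the cortical coupling,
# mirroring the pronounced anterior-posterior organisation of the system.
CORTEX_AP_AMP = 1.2
CORTEX_PD_AMP = 0.4


@dataclass
class CortexModel:
    """A species' cortical parcellation on the registration sphere."""

    n_parcels: int
    sphere_coords: np.ndarray  # (n_parcels, 3), unit norm
    network_label: np.ndarray  # (n_parcels,), values in 1..K
    species_tag: str

    def __post_init__(self):
        norms = np.linalg.norm(self.sphere_coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sphere coordinates must have unit norm")
        counts = np.bincount(self.network_label)[1:]
        if (counts == 0).any():
            raise ValueError("every network must have at least one parcel")

    @property
    def n_networks(self) -> int:
        return int(self.network_label.max())


@dataclass
class SubfieldFlatmap:
    """Categorical subfield labels (0..3) on a flatmap grid."""

    labels: np.ndarray
    grid: FlatmapGrid
    provenance: str = "synthetic"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.grid.n_vertices,):
            raise ValueError("one label per grid vertex required")
        if self.labels.min() < 0 or self.labels.max() > 3:
            raise ValueError("labels must index the fixed 4-subfield set")


@dataclass
class SpeciesDataset:
    """One species' simulated subjects plus the planted ground truth."""

    grid: FlatmapGrid
    cortex: CortexModel
    subjects: list  # list of (hippocampal TimeSeries, cortical TimeSeries)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        for hip, ctx in self.subjects:
            if hip.n_time != ctx.n_time:
                raise ValueError("hippocampal and cortical series must share T")
            if hip.n_space != self.grid.n_vertices:
                raise ValueError("hippocampal series does not match grid")
            if ctx.n_space != self.cortex.n_parcels:
                raise ValueError("cortical series does not match cortex model")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform lattice of n points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_cortex(n_parcels: int, n_networks: int, species_tag: str = "", seed: int = 0) -> CortexModel:
    """Place ``n_parcels`` on a deterministic Fibonacci sphere lattice with
    contiguous network territories.

    Network labels 1..K are assigned by the nearest of K network centres
    that are themselves a Fibonacci lattice, so networks form compact,
    roughly equal-area contiguous patches on the sphere.  The construction
    is fully deterministic; ``seed`` is accepted for interface stability
    and reproducibility bookkeeping.
    """
    if n_networks < 1 or n_parcels < n_networks:
        raise ValueError("need n_parcels >= n_networks >= 1")
    coords = _fibonacci_sphere(int(n_parcels))
    centers = _fibonacci_sphere(int(n_networks))
    labels = np.argmax(coords @ centers.T, axis=1) + 1
    return CortexModel(
        n_parcels=int(n_parcels),
        sphere_coords=coords,
        network_label=labels.astype(int),
        species_tag=species_tag,
    )


def _network_bumps(grid: FlatmapGrid, n_networks: int) -> np.ndarray:
    """Smooth AP-axis bump profiles, one per network, orthogonalised against
    the constant and the two linear axis loadings so the axis factors stay
    identifiable."""
    sigma = NETWORK_BUMP_WIDTH / n_networks
    centers = (np.arange(n_networks) + 0.5) / n_networks
    H = NETWORK_BUMP_AMP * np.exp(
        -((grid.ap_coord[:, None] - centers[None, :]) ** 2) / (2.0 * sigma**2)
    )
    basis = np.column_stack(
        [np.ones(grid.n_vertices), 2 * grid.ap_coord - 1, 2 * grid.pd_coord - 1]
    )
    beta, *_ = np.linalg.lstsq(basis, H, rcond=None)
    return H - basis @ beta


def base_coupling_matrix(n_networks: int) -> np.ndarray:
    """K x K species coupling matrix: entry (k, f) is how strongly spatial
    profile k contributes to the hippocampal loading of network factor f
    (Gaussian blend over network index)."""
    k = np.arange(n_networks)
    return np.exp(-((k[:, None] - k[None, :]) ** 2) / (2.0 * NETWORK_COUPLING_BLEND**2))


def planted_loadings(grid: FlatmapGrid, cortex: CortexModel, coupling: np.ndarray):
    """Hippocampal and cortical loading matrices over the K+2 latent factors.

    Factor order: network 1..K, then AP axis, then PD axis.  ``coupling``
    is the K x K species coupling matrix (profiles x factors).
    """
    K = cortex.n_networks
    coupling = np.asarray(coupling, dtype=float)
    if coupling.shape != (K, K):
        raise ValueError("coupling must be a K x K matrix")
    bumps = _network_bumps(grid, K) @ coupling
    L_hip = np.column_stack(
        [bumps, 2 * grid.ap_coord - 1, 2 * grid.pd_coord - 1]
    )
    net_ind = (cortex.network_label[:, None] == np.arange(1, K + 1)[None, :]).astype(float)
    L_ctx = np.column_stack(
        [
            net_ind,
            CORTEX_AP_AMP * cortex.sphere_coords[:, 2],
            CORTEX_PD_AMP * cortex.sphere_coords[:, 0],
        ]
    )
    return L_hip, L_ctx


def _draw_latents(rng: np.random.Generator, n_factors: int, T: int, ar_coef: float) -> np.ndarray:
    u = rng.standard_normal((n_factors, T))
    if ar_coef != 0.0:
        if not -1.0 < ar_coef < 1.0:
            raise ValueError("ar_coef must lie in (-1, 1)")
        innov = u * np.sqrt(1.0 - ar_coef**2)
        out = np.empty_like(u)
        out[:, 0] = u[:, 0]
        for t in range(1, T):
            out[:, t] = ar_coef * out[:, t - 1] + innov[:, t]
        u = out
    return u


def simulate_two_species(
    grid: FlatmapGrid,
    cortex_h: CortexModel,
    cortex_m: CortexModel,
    n_subjects: int = 10,
    n_timepoints: int = 600,
    noise_sd: float = 1.0,
    divergent_network: int | None = None,
    divergence: float = 0.8,
    ar_coef: float = 0.0,
    seed: int = 0,
):
    """Simulate paired datasets for species H and M.

    Per-subject latent factor draws are shared across species, so with
    ``noise_sd = 0`` and ``divergence = 0`` (and matched cortices) the two
    species are realisation-identical; all species differences then come
    from the planted coupling attenuation.  Observation noise is drawn
    independently per species.

    Parameters
    ----------
    divergent_network : int, optional
        Network label (1..K) whose hippocampal coupling is attenuated by
        ``1 - divergence`` in species M.  Defaults to the equatorial
        middle network ``(K+1)//2``, the stand-in for the heteromodal
        association (default-mode-like) network whose cross-species
        reorganisation is the target contrast.
    divergence : float in [0, 1]
        0 = species identical, 1 = coupling fully removed in species M.
    """
    if cortex_h.n_networks != cortex_m.n_networks:
        raise ValueError("species must share the number of networks")
    K = cortex_h.n_networks
    if divergent_network is None:
        # default: an equatorial network territory, the stand-in for the
        # heteromodal association network whose reorganisation is probed
        divergent_network = (K + 1) // 2
    if not 1 <= divergent_network <= K:
        raise ValueError(f"divergent_network must be in 1..{K}, got {divergent_network}")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    n_factors = K + 2
    if n_timepoints <= n_factors:
        raise ValueError("n_timepoints must exceed the number of latent factors")

    coupling_h = base_coupling_matrix(K)
    coupling_m = coupling_h.copy()
    coupling_m[divergent_network - 1, :] *= 1.0 - divergence

    Lh_hip, Lh_ctx = planted_loadings(grid, cortex_h, coupling_h)
    Lm_hip, Lm_ctx = planted_loadings(grid, cortex_m, coupling_m)

    rng = np.random.default_rng(seed)
    subjects_h, subjects_m = [], []
    for s in range(n_subjects):
        u = _draw_latents(rng, n_factors, n_timepoints, ar_coef)
        for tag, L_hip, L_ctx, bucket in (
            ("H", Lh_hip, Lh_ctx, subjects_h),
            ("M", Lm_hip, Lm_ctx, subjects_m),
        ):
            hip = L_hip @ u
            ctx = L_ctx @ u
            if noise_sd > 0:
                hip = hip + noise_sd * rng.standard_normal(hip.shape)
                ctx = ctx + noise_sd * rng.standard_normal(ctx.shape)
            bucket.append(
                (
                    TimeSeries(hip, "hippocampal-vertex", f"sub-{s:02d}", tag),
                    TimeSeries(ctx, "cortical-parcel", f"sub-{s:02d}", tag),
                )
            )

    params = dict(
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        noise_sd=noise_sd,
        divergent_network=int(divergent_network),
        divergence=divergence,
        ar_coef=ar_coef,
        seed=seed,
    )
    gt_h = dict(
        hippo_loadings=Lh_hip,
        cortex_loadings=Lh_ctx,
        coupling=coupling_h,
        **params,
    )
    gt_m = dict(
        hippo_loadings=Lm_hip,
        cortex_loadings=Lm_ctx,
        coupling=coupling_m,
        **params,
    )
    ds_h = SpeciesDataset(grid=grid, cortex=cortex_h, subjects=subjects_h, ground_truth=gt_h)
    ds_m = SpeciesDataset(grid=grid, cortex=cortex_m, subjects=subjects_m, ground_truth=gt_m)
    return ds_h, ds_m


def write_dataset_bundle(dataset: SpeciesDataset, out_dir) -> dict:
    """Write a species dataset to disk: per-subject TSV time-series tables
    (rows = vertices/parcels, columns = time), ground-truth loading maps,
    and a JSON manifest with grid dimensions, the parcel table and the
    generative parameters.  Returns the manifest."""
    import json
    from pathlib import Path

    from .io import write_matrix_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = dataset.ground_truth
    for hip, ctx in dataset.subjects:
        sid = hip.subject_id
        write_matrix_table(out / f"{sid}_hippocampus.tsv", hip.values)
        write_matrix_table(out / f"{sid}_cortex.tsv", ctx.values)
    write_matrix_table(out / "ground_truth_hippo_loadings.tsv", gt["hippo_loadings"])
    write_matrix_table(out / "ground_truth_cortex_loadings.tsv", gt["cortex_loadings"])
    write_matrix_table(out / "ground_truth_coupling.tsv", gt["coupling"])
    manifest = {
        "species_tag": dataset.cortex.species_tag,
        "grid": {"n_ap": dataset.grid.n_ap, "n_pd": dataset.grid.n_pd},
        "parcels": [
            {"id": i, "x": float(x), "y": float(y), "z": float(z), "network": int(k)}
            for i, ((x, y, z), k) in enumerate(
                zip(dataset.cortex.sphere_coords, dataset.cortex.network_label)
            )
        ],
        "subjects": [hip.subject_id for hip, _ in dataset.subjects],
        "parameters": {
            k: gt[k]
            for k in (
                "n_subjects", "n_timepoints", "noise_sd",
                "divergent_network", "divergence", "ar_coef", "seed",
            )
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_subfield_map(
    grid: FlatmapGrid,
    boundaries=(0.25, 0.5, 0.75),
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> SubfieldFlatmap:
    """Striped subfield map: 4 vertical stripes along the PD axis.

    Stripe order from distal (pd = 0) to proximal: subicular complex, CA1,
    CA2, CA3/4 — the flattened counterpart of the spiral subfield
    configuration.  Each AP row's three stripe boundaries are jittered by a
    clipped Gaussian so stripes stay ordered; deterministic given ``seed``.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.shape != (3,) or not (np.diff(b) > 0).all() or b[0] <= 0 or b[-1] >= 1:
        raise ValueError("boundaries must be 3 strictly increasing fractions in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.empty(grid.n_vertices, dtype=int)
    eps = 1e-6
    for i in range(grid.n_ap):
        row_b = b + (rng.normal(0.0, jitter_sd, size=3) if jitter_sd > 0 else 0.0)
        row_b = np.clip(row_b, eps, 1.0 - eps)
        # restore strict ordering after clipping
        row_b = np.maximum.accumulate(row_b + np.arange(3) * eps)
        row_b = np.clip(row_b, eps, 1.0 - eps)
        sl = slice(i * grid.n_pd, (i + 1) * grid.n_pd)
        labels[sl] = np.searchsorted(row_b, grid.pd_coord[sl], side="right")
    return SubfieldFlatmap(labels=labels, grid=grid, provenance="synthetic-stripes")
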