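"""End-to-end driver: simulate -> preprocess -> gradients -> joint embed ->
match -> dual regression -> reprojection -> homology -> subfields.

Every numeric artifact is written as TSV with a JSON provenance sidecar
(config hash, seed, package version); the run is deterministic given the
seed.  The returned dictionary carries the headline quantities of each
stage, including agreement with the generator's planted ground truth.
"""

from __future__ import annotations

import logging
import shutil
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr

from . import __version__
from .config import RunConfig
from .connectivity import (
    TimeSeries,
    connectivity_matrix,
    group_average,
    max_connectivity_map,
    regress_global_mean,
    sector_connectivity,
    tsnr_map,
)
from .dualreg import (
    build_axis_design,
    dual_regress,
    group_mean_axis_maps,
    ks_region_comparison,
    reproject_to_flatmap_space,
)
from .embedding import (
    corticocortical_gradients,
    hippocampal_gradients,
    joint_cross_species_embed,
)
from .grids import make_flatmap_grid
from .homology import (
    CorrespondenceMap,
    homology_index,
    network_mean_homology,
    searchlight_neighbors,
)
from .io import config_hash, write_matrix_table, write_sidecar
from .matching import match_maps
from .subfields import (
    flatmap_similarity,
    percent_change,
    relative_subfield_size,
    subfield_extent_profile,
)
from .synth import make_cortex, make_subfield_map, simulate_two_species

log = logging.getLogger("hippogradients")


def _abs_corr(a, b) -> float:
    return float(abs(pearsonr(np.asarray(a, float), np.asarray(b, float)).statistic))


def preprocess_subject(hip: TimeSeries, ctx: TimeSeries):
    """Global-mean regression using one mean series over the concatenated
    hippocampal + cortical data of the subject, then split back."""
    concat = TimeSeries(
        np.vstack([ctx.values, hip.values]),
        "concatenated",
        ctx.subject_id,
        ctx.species_tag,
    )
    clean = regress_global_mean(concat)
    nC = ctx.n_space
    ctx2 = TimeSeries(clean.values[:nC], ctx.space_kind, ctx.subject_id, ctx.species_tag)
    hip2 = TimeSeries(clean.values[nC:], hip.space_kind, hip.subject_id, hip.species_tag)
    return hip2, ctx2, clean


def simulate_stage(config: RunConfig):
    sim = config.simulation
    grid = make_flatmap_grid(sim.n_ap, sim.n_pd)
    # both species share the lattice seed: the synthetic stand-in for the
    # cross-species surface registration is the identity on parcel index
    cortex_h = make_cortex(sim.n_parcels, sim.n_networks, "H", seed=config.seed)
    cortex_m = make_cortex(sim.n_parcels, sim.n_networks, "M", seed=config.seed)
    ds_h, ds_m = simulate_two_species(
        grid,
        cortex_h,
        cortex_m,
        n_subjects=sim.n_subjects,
        n_timepoints=sim.n_timepoints,
        noise_sd=sim.noise_sd,
        divergent_network=sim.divergent_network,
        divergence=sim.divergence,
        ar_coef=sim.ar_coef,
        seed=config.seed,
    )
    return grid, ds_h, ds_m


def species_group_connectivity(ds, preprocess: bool = True):
    """Per-subject preprocessed hippocampus x parcel matrices, group mean,
    and the preprocessed series (for later stages)."""
    mats, cleaned = [], []
    for hip, ctx in ds.subjects:
        if preprocess:
            hip, ctx, concat = preprocess_subject(hip, ctx)
        else:
            concat = TimeSeries(
                np.vstack([ctx.values, hip.values]), "concatenated",
                ctx.subject_id, ctx.species_tag,
            )
        mats.append(connectivity_matrix(hip, ctx))
        cleaned.append((hip, ctx, concat))
    return group_average(mats), cleaned


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> dict:
    """Execute the full synthetic two-species analysis.

    Returns a result dictionary; artifacts (TSV + JSON sidecars) go to
    ``config.out_dir``.  A failure in any stage raises a RuntimeError naming
    the stage; artifacts completed up to that point remain on disk next to
    a ``.partial`` marker.
    """
    out = Path(config.out_dir)
    marker = out / ".partial"
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        marker.write_text("run in progress\n")
    meta = {
        "config_hash": config_hash(config.to_dict()),
        "seed": config.seed,
        "version": __version__,
    }
    results: dict = {"meta": dict(meta)}

    def artifact(name, values, row_labels=None, col_labels=None, extra=None):
        if not write_artifacts:
            return
        p = write_matrix_table(out / name, np.atleast_2d(values), row_labels, col_labels)
        write_sidecar(p, {**meta, **(extra or {})})

    stage = "simulate"
    try:
        grid, ds_h, ds_m = simulate_stage(config)
        results["n_vertices"] = grid.n_vertices
        results["n_parcels"] = ds_h.cortex.n_parcels
        div_net = ds_h.ground_truth["divergent_network"]
        K = ds_h.cortex.n_networks

        stage = "preprocess+connectivity"
        C_h, cleaned_h = species_group_connectivity(ds_h)
        C_m, cleaned_m = species_group_connectivity(ds_m)
        artifact("group_connectivity_H.tsv", C_h.values)
        artifact("group_connectivity_M.tsv", C_m.values)

        tsnr_h = np.mean([tsnr_map(hip)[0] for hip, _, _ in cleaned_h], axis=0)
        results["median_hippocampal_tsnr_H"] = float(np.median(tsnr_h))
        results["max_connectivity_map_H_mean"] = float(max_connectivity_map(C_h).mean())
        sector_maps = sector_connectivity(cleaned_h[0][0], cleaned_h[0][1], grid)
        results["sector_names"] = sorted(sector_maps)

        stage = "hippocampal-gradients"
        emb = config.embedding
        g_h = hippocampal_gradients(
            C_h, emb.n_components, emb.sparsity, emb.alpha, seed=config.seed
        )
        g_m = hippocampal_gradients(
            C_m, emb.n_components, emb.sparsity, emb.alpha, seed=config.seed
        )
        ap_truth = 2 * grid.ap_coord - 1
        results["grad1_vs_planted_ap_H"] = _abs_corr(g_h.component(0), ap_truth)
        results["grad1_vs_planted_ap_M"] = _abs_corr(g_m.component(0), ap_truth)
        artifact("hippocampal_gradients_H.tsv", g_h.components,
                 extra={"eigenvalues": g_h.eigenvalues})
        artifact("hippocampal_gradients_M.tsv", g_m.components,
                 extra={"eigenvalues": g_m.eigenvalues})

        stage = "joint-embedding"
        j_h, j_m = joint_cross_species_embed(
            C_h, C_m, emb.n_components, emb.sparsity, emb.alpha, seed=config.seed
        )
        results["joint_grad1_cross_species_r"] = _abs_corr(
            j_h.component(0), j_m.component(0)
        )
        gaps = {}
        labels = ds_h.cortex.network_label
        for k in range(1, K + 1):
            sel = labels == k
            gaps[k] = float(
                np.abs(j_h.component(0)[sel] - j_m.component(0)[sel]).mean()
            )
        results["joint_grad1_network_gaps"] = gaps
        results["divergent_network"] = int(div_net)
        results["divergent_network_has_max_gap"] = max(gaps, key=gaps.get) == div_net
        artifact("joint_gradients_H.tsv", j_h.components)
        artifact("joint_gradients_M.tsv", j_m.components)

        stage = "cortical-gradients+matching"
        ctx_m_series = [ctx for _, ctx, _ in cleaned_m]
        cg_m = corticocortical_gradients(
            ctx_m_series, emb.n_components, emb.sparsity, emb.alpha, seed=config.seed
        )
        mt = config.matching
        report = match_maps(
            j_m.component(0),
            list(cg_m.components),
            sphere_coords=ds_m.cortex.sphere_coords,
            penalty=mt.penalty,
            n_perm=mt.n_perm,
            q_grid=mt.q_grid,
            seed=config.seed,
        )
        results["match_lasso_coefs"] = report.lasso_coefs.tolist()
        results["match_best_set"] = [int(i) for i in report.best_set]
        results["match_best_dice"] = report.best_dice
        results["match_best_q"] = report.best_q
        results["match_min_spin_p"] = float(report.spin_p.min())
        best_r2 = int(np.argmax(report.r_squared))
        results["match_best_r2"] = float(report.r_squared[best_r2])
        results["match_best_ols_coef"] = float(report.ols_coefs[best_r2])

        stage = "dual-regression"
        dr = config.dualreg
        design = build_axis_design(grid, ds_h.cortex.n_parcels, dr.ap_bins, dr.pd_bins)
        subj_maps = {"H": [], "M": []}
        for tag, cleaned in (("H", cleaned_h), ("M", cleaned_m)):
            for _, _, concat in cleaned:
                _, maps = dual_regress(concat, design)
                subj_maps[tag].append(maps)
        group_maps = {t: group_mean_axis_maps(ms) for t, ms in subj_maps.items()}
        gt_ap = ds_h.ground_truth["cortex_loadings"][:, K]
        gt_pd = ds_h.ground_truth["cortex_loadings"][:, K + 1]
        results["dualreg_ap_vs_planted_H"] = _abs_corr(group_maps["H"].ap_map, gt_ap)
        results["dualreg_pd_vs_planted_H"] = _abs_corr(group_maps["H"].pd_map, gt_pd)
        for t in ("H", "M"):
            artifact(
                f"axis_maps_{t}.tsv",
                np.column_stack([group_maps[t].ap_map, group_maps[t].pd_map]),
                col_labels=["ap", "pd"],
            )

        stage = "reprojection+ks"
        embeddings = {
            t: [
                reproject_to_flatmap_space(
                    m.ap_map, m.pd_map, grid, dr.exclude, species_tag=t
                )
                for m in subj_maps[t]
            ]
            for t in ("H", "M")
        }
        n_comp = K * 2
        ks_results = {}
        for k in range(1, K + 1):
            roi = np.flatnonzero(labels == k)
            for axis in ("AP", "PD"):
                D, p, pc = ks_region_comparison(
                    embeddings["H"], embeddings["M"], roi, axis, n_comparisons=n_comp
                )
                ks_results[f"network{k}_{axis}"] = {"D": D, "p": p, "p_corrected": pc}
        results["ks_regions"] = ks_results
        results["ks_divergent_ap_D"] = ks_results[f"network{div_net}_AP"]["D"]
        results["ks_divergent_ap_p_corrected"] = ks_results[f"network{div_net}_AP"][
            "p_corrected"
        ]

        stage = "homology"
        hm_cfg = config.homology
        corr_map = CorrespondenceMap.identity(ds_h.cortex.sphere_coords)
        nbrs = searchlight_neighbors(
            corr_map, ds_m.cortex.sphere_coords, hm_cfg.radius, hm_cfg.sphere_radius
        )
        fp_h = connectivity_transpose(C_h)
        fp_m = connectivity_transpose(C_m)
        hmap = homology_index(fp_h, fp_m, nbrs, radius=hm_cfg.radius)
        net_hom = network_mean_homology(hmap, labels)
        results["network_mean_homology"] = net_hom
        valid = {k: v for k, v in net_hom.items() if v is not None}
        results["min_homology_network"] = min(valid, key=valid.get)
        results["homology_range"] = float(max(valid.values()) - min(valid.values()))
        artifact("homology_map.tsv", hmap.values[:, None], col_labels=["homology"],
                 extra={"network_summary": net_hom, "radius": hm_cfg.radius})

        stage = "subfields"
        sf = config.subfields
        sf_h = make_subfield_map(grid, sf.boundaries_h, sf.jitter_sd, seed=config.seed)
        sf_m = make_subfield_map(grid, sf.boundaries_m, sf.jitter_sd, seed=config.seed + 1)
        prof_h = subfield_extent_profile(sf_h)
        prof_m = subfield_extent_profile(sf_m)
        results["subfield_similarity"] = flatmap_similarity(prof_h, prof_m)
        ratio_h = relative_subfield_size(prof_h)
        ratio_m = relative_subfield_size(prof_m)
        results["subfield_percent_change_ca34_vs_sub"] = float(
            percent_change(ratio_h, ratio_m)[3, 0]
        )
        artifact("subfield_profile_H.tsv", prof_h)
        artifact("subfield_profile_M.tsv", prof_m)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if write_artifacts:
        write_sidecar(out / "summary", {**meta, "results": _jsonable(results)})
        marker.unlink(missing_ok=True)
    return results


def connectivity_transpose(C):
    """Parcels x hippocampal-vertex view of a hippocampus x parcel matrix."""
    from .connectivity import ConnectivityMatrix

    return ConnectivityMatrix(
        values=C.values.T.copy(),
        row_kind=C.col_kind,
        col_kind=C.row_kind,
        species_tag=C.species_tag,
        averaged_over=C.averaged_over,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
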