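#!/usr/bin/env python
"""Reproject the cortex into the 2D hippocampal coordinate space and test
region positions across species.

Each subject's AP and PD coupling maps become 2D coordinates (rescaled
between their 10th and 90th percentiles).  Per network and axis, the two
species' subject-level region means are compared with exact two-sample KS
tests, Bonferroni corrected across the 14 comparisons.
"""
import argparse
from pathlib import Path

import numpy as np

from hippogradients.config import RunConfig
from hippogradients.dualreg import (
    build_axis_design, dual_regress, ks_region_comparison, reproject_to_flatmap_space,
)
from hippogradients.io import write_matrix_table
from hippogradients.pipeline import simulate_stage, species_group_connectivity

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--out", default="results/analysis")
args = parser.parse_args()
out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

cfg = RunConfig(seed=args.seed)
grid, ds_h, ds_m = simulate_stage(cfg)
design = build_axis_design(grid, ds_h.cortex.n_parcels,
                           cfg.dualreg.ap_bins, cfg.dualreg.pd_bins)
embs = {}
for tag, ds in (("H", ds_h), ("M", ds_m)):
    _, cleaned = species_group_connectivity(ds)
    embs[tag] = [
        reproject_to_flatmap_space(m.ap_map, m.pd_map, grid,
                                   cfg.dualreg.exclude, species_tag=tag)
        for m in (dual_regress(c, design)[1] for _, _, c in cleaned)
    ]
labels = ds_h.cortex.network_label
K = ds_h.cortex.n_networks
div = ds_h.ground_truth["divergent_network"]
rows = []
print("network  axis    KS D      p   p_corr")
for k in range(1, K + 1):
    roi = np.flatnonzero(labels == k)
    for axis in ("AP", "PD"):
        D, p, pc = ks_region_comparison(embs["H"], embs["M"], roi, axis,
                                        n_comparisons=2 * K)
        mark = "  <- divergent" if k == div else ""
        print(f"  {k}      {axis}   {D:6.2f} {p:7.4f} {pc:7.4f}{mark}")
        rows.append([k, 1.0 if axis == "AP" else 2.0, D, p, pc])
write_matrix_table(out / "ks_region_comparisons.tsv", np.array(rows),
                   col_labels=["network", "axis", "D", "p", "p_corrected"])
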