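# hippogradients

Cross-species comparison of hippocampal functional organisation through
connectivity gradients — a tested, reusable implementation of the full
analysis chain, exercised end-to-end on synthetic two-species data with
planted ground truth.

## The scientific problem

The primate hippocampus is organised along two intrinsic axes that become
explicit when the structure is unfolded into a 2D flatmap: the long
anterior–posterior (AP) axis and the short distal–proximal (PD) axis
(distal = subicular end, proximal = dentate gyrus). Comparative questions —
which parts of the cortex couple to which part of the hippocampus, and how
that embedding was reorganised between species such as human and macaque —
require statistics that work on a *shared* coordinate system even though
the two cortices have no vertex-wise correspondence. This package
implements that toolkit for researchers in comparative neuroimaging:

1. **Connectivity gradients.** From a Fisher-z coupling matrix
   `C ∈ R^{V×P}` between `V` hippocampal vertices and `P` cortical
   parcels, build the normalised-angle affinity
   `S_ij = 1 − arccos(cos(C_i, C_j))/π`, and embed it with diffusion maps:
   degree-normalise `W = D^{-α} S D^{-α}` (α = 0.5), row-normalise to a
   Markov operator, take the leading non-trivial eigenvectors `ψ_k` scaled
   by `λ_k/(1−λ_k)`. The first gradient of `C` recovers the dominant AP
   axis of hippocampal functional organisation.
2. **Joint two-species embedding.** Concatenate `C_H` and `C_M` along the
   cortical dimension and embed all parcels of both species as one item
   set (features = hippocampal fingerprints on the matched flatmap). The
   resulting gradients `G_H`, `G_M` are directly comparable across species.
3. **Gradient matching.** Match the joint gradient against cortico-cortical
   gradient maps: quantile gaussianization, LASSO selection (α = 0.1),
   univariate OLS `r²`, spin-test significance (uniform SO(3) rotations of
   the sphere coordinates, Bonferroni corrected), and a threshold-Dice
   analysis over all singletons, pairs and triplets of candidate maps.
4. **Dual regression of the flatmap axes.** An orthogonal spatial design
   (binned AP and PD regressors, 16/8 bins, values −1…+1, zero on cortex)
   is regressed through the concatenated data in two stages
   (`T = X⁺D`, `B = D T⁺`), giving each cortical parcel an AP and a PD
   coupling map; the two maps also serve as 2D coordinates that reproject
   the cortex into hippocampal space, where region positions are compared
   across species with exact two-sample Kolmogorov–Smirnov tests.
5. **Searchlight homology index.** Per parcel, the median correlation of
   hippocampal connectivity fingerprints with all other-species parcels
   inside a geodesic searchlight on the registration sphere, summarised
   per cortical network — low values mark reorganised territory.
6. **Subfield flatmap metrics.** Striped subfield maps (subicular complex,
   CA1, CA2, CA3/4) are compared through per-AP-row extent profiles:
   similarity = 1 − mean row-wise cosine distance, plus relative subfield
   size ratios and their cross-species percentage change.

Because the original imaging datasets are restricted and large, the
package ships a first-class synthetic generator (`hippogradients.synth`)
that emulates their statistical structure — latent network time courses,
hippocampal loadings varying smoothly along the flatmap axes, a
species-specific coupling attenuation for one network, Gaussian
observation noise — so every stage can be validated against known ground
truth. See `docs/methods.md` for the generative model and all numerical
conventions.

## Worked example

The numbered drivers under `analysis/` run the full chain at the default
study conditions (200 parcels/species in 7 networks, 32×16 flatmap, 10
subjects/species, T = 600, unit noise, 80% coupling attenuation of
network 4 in species M):

```bash
python analysis/01_simulate.py --seed 7
python analysis/03_hippocampal_gradients.py --seed 7
python analysis/04_joint_embedding.py --seed 7
python analysis/08_homology.py --seed 7
```

prints (abridged):

```
species H: eigenvalues [0.117 0.095 0.081 0.072]; gradient 1 vs planted AP loading rho = -0.970
species M: eigenvalues [0.119 0.107 0.097 0.044]; gradient 1 vs planted AP loading rho = -0.931

joint gradient 1: cross-species parcel correlation rho = +0.974
per-network mean |G_H - G_M| on gradient 1:
  network 4: 0.0809  <- planted divergent network   (all others <= 0.0069)

network-mean homology:
  network 1: 0.982 ... network 4: 0.783  <- planted divergent network
```

Reading: the first hippocampal gradient recovers the planted AP axis in
both species (|ρ| > 0.93; the gradient's sign is arbitrary); matched
parcels agree on the joint gradient except in the attenuated network,
which shows a ten-fold larger cross-species gap; and the searchlight
homology index singles out that same network as the least conserved.
`analysis/06_dual_regression.py` recovers the planted cortical AP/PD
coupling maps with |ρ| ≥ 0.997, and `analysis/09_subfields.py` reports a
flatmap similarity of 0.955 between the two species' subfield maps.

The whole pipeline is also available as one call:

```python
from hippogradients import RunConfig, run_pipeline
results = run_pipeline(RunConfig(seed=7))
```

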