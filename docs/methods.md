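# Methods

This note documents the models, numerical conventions and design choices
behind `hippogradients`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic two-species generator

### Generative model

All simulated signals derive from `K + 2` latent factors `u(t)`, iid
standard normal by default (an AR(1) coefficient is exposed, default 0,
with innovations scaled to keep unit marginal variance — temporal
autocorrelation is irrelevant to the statistics under test). One factor
per cortical network, plus one factor per hippocampal flatmap axis.

Hippocampal vertex `v` (flatmap coordinates `ap, pd ∈ [0,1]`) has loadings

* AP axis factor: `2·ap − 1` (fixed; −1 = posterior, +1 = anterior),
* PD axis factor: `2·pd − 1` (fixed; −1 = distal, +1 = proximal),
* network factor `f`: `Σ_k A[k,f] · b_k(ap)`, where `b_k` is a Gaussian
  bump along AP (centre `(k−0.5)/K`, sd `0.6/K`, amplitude 0.9) and `A`
  is the `K × K` species **coupling matrix**, a Gaussian blend over
  network index (sd 0.4): each network factor drives mostly its own
  spatial profile plus a small admixture of its neighbours'.

The bump profiles are jointly orthogonalised against
`{1, 2·ap−1, 2·pd−1}` so the network channel cannot masquerade as an axis
factor; this keeps the axis factors identifiable and the dual-regression
stage clean.

Cortical parcel `p` sits on a deterministic Fibonacci lattice on the unit
sphere; network labels 1..K are assigned by the nearest of K lattice
centres, producing compact, roughly equal-area contiguous network
territories. Parcel loadings are 1 on the parcel's own network factor,
`1.2·z_p` on the AP factor and `0.4·x_p` on the PD factor (`z, x` =
sphere coordinates): the cortical reflections of the axes are smooth
sphere maps, and the long axis dominates the short one, mirroring the
pronounced anterior–posterior organisation of the system.

Observed series are `loadings @ u + noise_sd · ε` with iid Gaussian ε.
**Latent draws are shared between species within a subject**; species
differ only through loadings. Consequently, with `noise_sd = 0` and
`divergence = 0` the two species are realisation-identical, and every
species contrast has an exact null — the property the null-calibration
tests rely on. Observation noise is always drawn independently per
species.

Species divergence is planted by attenuating the divergent network's
*row* of the coupling matrix by `1 − divergence` in species M. Because
each factor mixes neighbouring profiles, attenuating one row changes the
*shape* of the affected fingerprints, not merely their scale — a pure
rescaling would be invisible to the correlation-based homology index.
The default divergent network is the equatorial territory `(K+1)//2`,
where the shared axis-loading channels are weakest and the divergence is
therefore expressed most cleanly; it stands in for the heteromodal
association network whose cross-species reorganisation is the contrast of
interest.

### Default study conditions

| parameter | default | meaning |
|---|---|---|
| flatmap | 32 × 16 | AP × PD vertices (512) |
| parcels / networks | 200 / 7 | per species |
| subjects | 10 per species | independent latent draws |
| time points | 600 | per subject |
| `noise_sd` | 1.0 | observation noise sd (signal loadings are O(1)) |
| `divergence` | 0.8 | coupling attenuation in species M |
| bump amplitude / width | 0.9 / 0.6·K⁻¹ | network→hippocampus coupling profile |
| coupling blend sd | 0.4 | network-index mixing in the coupling matrix |
| cortical AP / PD amplitude | 1.2 / 0.4 | axis-factor loadings on the sphere |

The amplitudes were fixed once, at design time, so that the planted
structure is recoverable at this noise level (the generator's stated
purpose); they are module constants, not run-time knobs.

### What the generator does and does not emulate

Emulated: low-rank latent network structure shared between hippocampus
and cortex; smooth axis-organised hippocampal loadings; species-specific
coupling differences on a matched flatmap; observation noise; striped
subfield maps with jittered boundaries. Not emulated: haemodynamics and
autocorrelated scanner noise spectra, motion artefacts, volumetric and
surface geometry, inter-subject loading variability, hemispheres. Passing
tests therefore validate the *statistical machinery* — recovery,
calibration, invariances — not robustness to real-data artefacts.

## Connectivity

Global-signal removal regresses each row on the spatial-mean series plus
an intercept (a constant mean series degrades to intercept-only with a
warning). Correlations use sample (n−1) normalisation; zero-variance rows
yield correlation 0 with a logged warning rather than NaN. Fisher z clips
|r| at `1 − 1e-7` to keep self-correlations finite. Group averaging is
performed on the z scale (z per subject, then mean). Sector maps split
the flatmap into quadrants at `ap = 0.5`, `pd = 0.5`; the medial/lateral
naming maps onto the distal–proximal coordinate (medial = distal).
Optional isotropic Gaussian smoothing is provided on the flatmap lattice
(sigma in grid units, default off); physical mm kernels are
mesh-dependent and out of scope. tSNR is temporal mean over sample sd;
note the synthetic signals are zero-mean by construction, so tSNR is a
pure diagnostic here.

## Embedding

* Row sparsification default 0.9 (keep the top 10% of entries per row,
  by signed value), matching common practice for affinity construction;
  exposed in the configuration.
* Normalised-angle kernel on the sparsified rows, symmetrised; unit
  diagonal enforced.
* Diffusion maps with `α = 0.5`; the symmetric conjugate
  `D₂^{-1/2} W D₂^{-1/2}` is eigendecomposed (dense `scipy.linalg.eigh`
  up to n = 2000, seeded Lanczos above, identical to 1e-8 by contract);
  right eigenvectors are recovered as `ψ = D₂^{-1/2} v`, rescaled so the
  trivial eigenvector is the constant 1, and the non-trivial components
  are scaled by `λ/(1−λ)` (automatic diffusion time).
* Sign convention: each component is flipped so its largest-magnitude
  element is positive; gradient signs are otherwise arbitrary.
* A disconnected affinity graph raises with the component sizes; an
  affinity with no variation (identical fingerprints) is rejected as
  degenerate.
* `n_components` defaults to 10.

## Gradient matching

Gaussianization maps average ranks onto standard-normal quantiles
(`Φ⁻¹(rank/(n+1))`); it is monotone and idempotent up to ties. LASSO uses
scikit-learn's coordinate descent on z-scored inputs (penalty 0.1
default); non-convergence raises with diagnostics. OLS is univariate with
intercept on the gaussianized maps; `r²` is the squared Pearson
correlation. The spin test rotates the *candidate* map's sphere
coordinates by rotations drawn uniformly from SO(3), reassigns values by
nearest rotated neighbour, and uses the add-one two-sided permutation
p-value `(1 + #{|r_null| ≥ |r_obs|})/(n_perm + 1)`. Multiple-comparison
correction across candidates is Bonferroni. Threshold masks keep strictly
greater-than-quantile items (ties excluded); pair/triplet combinations
use the union of the member masks, and the Dice analysis enumerates all
subsets of size ≤ 3 over thresholds 0.70–0.95 in steps of 0.05.

## Dual regression and reprojection

Axis bin values are linearly spaced, `−1 + 2i/(B−1)` for bin `i` of `B`
(16 AP, 8 PD bins by default; vertices are assigned to the nearest bin by
coordinate). The axis columns are mean-centred *within the hippocampal
block*, which preserves the zero cortical entries, makes the columns sum
to zero over the hippocampus, and on any evenly occupied grid renders the
design exactly orthogonal. Stage 1 is `T = X⁺D`, stage 2 `B = D T⁺`;
group maps are unweighted subject means.

Reprojection rescales each axis map linearly so that its 10th and 90th
percentiles map to 0 and 1, clipping beyond (the extreme 10% of elements
at either end are thereby excluded from the rescaling fit); the embedding
records the bounds and uses the flatmap aspect ratio. Region comparisons
reduce each subject to the ROI-mean coordinate per axis (a subject-level
summary is what makes an n = 10 per species test meaningful), use the
exact two-sample two-sided KS distribution, and Bonferroni-correct by the
number of comparisons (#ROIs × 2 axes by default).

## Homology

Distances are great-circle arcs on the registration sphere; the
searchlight radius is a required parameter in units of the sphere radius,
never hard-coded, because physical radii are mesh- and species-dependent.
The synthetic default of 0.35 rad keeps searchlights mostly inside one
network territory (≈ 6–9 of 200 parcels), which is what makes the
network-mean summary interpretable; the median over neighbours tolerates
a minority of mismatched parcels. Fingerprints are correlated on raw
Fisher-z values (Pearson is location/scale invariant); the median is over
signed correlations. Parcels with no neighbours or zero-variance
fingerprints are flagged missing, not fatal, and excluded from the
unweighted network means.

## Subfield metrics

Row distance is the conventional cosine distance `1 − cos θ` in the 4D
extent space; the reported similarity is `1 − mean row distance` (for
non-negative extent rows this equals the mean cosine, which is also
exposed as a mode). Maps with unequal AP resolution are aligned by linear
interpolation of the profiles along the normalised AP coordinate. The
default species boundary sets, (0.25, 0.50, 0.70) vs (0.30, 0.60, 0.80)
with 0.02 row jitter, plant a relative expansion of CA2 and CA3/4 in
species H.

## Calibration problem sizes

The seed-replicated calibration checks use deliberately scaled problem
sizes chosen as a sensible compute budget for routine test runs: the
null-species KS calibration runs 200 simulations at a 16×8 flatmap, 60
parcels and T = 150 (test validity does not depend on problem size; the
subject count stays at 10 so the exact KS distribution matches the study
conditions), the spin-test calibration uses 200 smooth map pairs at 200
rotations, and the divergence-detection rate uses 20 simulations at the
full default conditions.

## Known limitations

* The identity parcel correspondence and the shared cortical lattice make
  the synthetic registration error-free; real cross-species registrations
  contribute their own uncertainty, which is not modelled.
* Shared latent draws across species make null contrasts conservative
  (positively correlated species summaries); this is intentional for
  exact-null testing but understates between-species sampling
  variability.
* Gradient magnitudes depend on the sparsification fraction and the
  `λ/(1−λ)` scaling; only ordering, sign-aligned correlations and
  cross-species gaps are interpreted.
* The pipeline is hemisphere-agnostic and runs per labelled structure;
  hemispheres, if present, are processed as separate runs.
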