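# Methods

## Model and pipeline

`crossmorph` treats each species' sample as a non-negative matrix
`X (m voxels × n subjects)` of modulated gray-matter (GM) values on a
template grid, assembled from per-subject volumes after optional Gaussian
smoothing and GM-probability masking. The pipeline is:

1. **OPNMF parcellation.** Minimize `‖X − W WᵀX‖²_F` subject to `WᵀW = I`,
   `W ≥ 0`, by multiplicative updates from an NNDSVD initialization;
   subject weights are the projection `H = WᵀX`. The orthogonality and
   non-negativity constraints push columns of `W` toward sparse,
   minimally overlapping spatial components; winner-takes-all over the
   columns gives a hard parcellation. The model assumes that voxels of a
   functional/anatomical unit covary across subjects and that this
   covariance is expressible with non-negative loadings.
2. **Granularity selection.** For each candidate k, the mean
   reconstruction error (MRE = squared-Frobenius residual / (m·n)) is
   bootstrapped by resampling subjects with replacement (voxels fixed —
   the subjects, not the voxels, are the sampling units). The change
   `Δ_k = MRE_{k−1} − MRE_k` flattens once additional factors model noise.
   Cross-species similarity is the adjusted Rand index (ARI) between one
   species' labels transported into the other's space and the target
   species' labels, on the intersection of both masks. The selected k is
   the ARI argmax restricted to the plateau window.
3. **Expansion maps.** The Jacobian determinant of the cross-species
   deformation (central differences in the interior, one-sided at edges)
   divided by the global brain-size ratio (target/source template mask
   volume) gives the relative expansion; 1 means proportional scaling.
   Parcel means are z-scored across parcels (population SD).
4. **Aging statistics.** Per parcel, average GM volume (ml; parcel mean ×
   voxel count × voxel volume) is the response in an OLS model with age
   (years), sex (0/1), TIV (ml) and scanner field strength (0/1).
   The age t-statistics are Holm-corrected across parcels. A whole-brain
   model regresses 100·GM/TIV on age. For interspecies comparison the
   faster-aging species' sample is truncated at
   `ceil(reference_max_age × 1.15)` years (50-year-old reference → 58).
5. **Association.** Pearson's r between per-parcel aging statistics
   (|t| by default; signed t available) and expansion z-scores, with a
   permutation p-value: parcels are the exchangeable units, one vector is
   permuted, `p = (1 + #extreme)/(1 + n_perm)` (add-one, so p is never 0);
   for ≤ 8 parcels all permutations are enumerated and p is exact.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `max_iter` | 10000 | cap on multiplicative updates per fit |
| `tol` | 1e-5 | relative MRE change declaring convergence |
| `k_range` | 2–40 | candidate granularities for the curve |
| `n_boot` | 100 | bootstrap replicates for the MRE curve |
| `plateau_fraction` | 0.15 | Δ-MRE threshold as a fraction of the largest Δ |
| mask threshold | 0.3 / 0.2 | GM probability cutoff (chimpanzee-like / human-like) |
| smoothing FWHM | 4–6 mm | Gaussian kernel; σ = FWHM / (2√(2 ln 2)) |
| `alpha` | 0.05 | FWE level for parcel significance |
| `n_perm` | 100000 | permutations for the association test |
| age factor | 1.15 | interspecies aging-rate ratio for range matching |

## Numerical choices

- **Normalization of W.** The multiplicative rule fixes no scale. The
  package rescales `W` by its spectral norm after each update and reports
  the orthogonality residual `max|WᵀW − I|` on unit-normalized columns.
  Per-column unit normalization during iteration was tried and rejected:
  it stalls the fit far above the noise floor and breaks the monotone
  decrease of the reconstruction error, while spectral rescaling keeps the
  descent strictly monotone (asserted to 1e-10 relative in the tests).
  At convergence `WᵀW ≈ I`, so the two scalings coincide.
- **Denominator floor** of 1e-16 in the update avoids division by zero
  without perturbing converged ratios.
- **Memory:** products are evaluated as `X(XᵀW)` and `W(Wᵀ(X(XᵀW)))`; the
  m×m Gram matrix is never formed.
- **Dead-factor rescue.** The multiplicative dynamics occasionally
  converge with a factor that wins (almost) no voxels — a weak dense
  component descended from the global-mean NNDSVD component — while two
  covariance blocks share one factor. Analogous to empty-cluster
  re-seeding in k-means, factors winning fewer than 5% of their fair
  share m/k of voxels are re-seeded on the worst-reconstructed voxel
  quartile and the fit is continued (up to 3 rounds); a rescue is kept
  only if it lowers the reconstruction error. The procedure is
  deterministic; the core fit involves no random state at all.
- **Convergence guard.** The relative-change denominator is floored at
  1e-12 of the total data energy so exact fits (error ≈ 0) register as
  converged instead of comparing rounding noise.
- **Plateau indexing.** A granularity k belongs to the plateau when the
  improvement *beyond* it (Δ at k+1) is sub-threshold: the window starts
  at the k past which gains are noise, so the beginning of the plateau —
  the natural candidate — is inside the window. Indexing the rule on the
  incoming Δ instead would exclude exactly the elbow granularity.
- **Ties.** Winner-takes-all ties break to the lowest factor index;
  granularity ties break to the smaller k (parsimony).
- **Degenerate inputs.** Zero-variance subjects are flagged by QC with an
  explicit reason rather than producing NaN correlations; uniform
  expansion (zero SD across parcel means) raises instead of returning
  undefined z-scores; rank-deficient aging designs raise naming the
  collinear columns; empty masks and disjoint species masks raise.
- **Voxel ordering** is the ascending C-order linear index of the mask,
  fixing the row semantics of `W` across runs.

## Design choices where the procedure was open

- **Per-parcel ARI** is computed by binary max-overlap matching: each
  source parcel's indicator is compared (ARI) with the indicator of the
  target parcel it overlaps most.
- **FWE correction** is Holm's step-down procedure: it controls the FWE
  under arbitrary dependence and uniformly dominates Bonferroni.
- **Association tail** defaults to two-sided; one-sided variants are
  available where the direction of the hypothesis is fixed in advance.
- **Smoothing before downsampling** in the preprocessing helper chain, to
  reduce aliasing; both operations are also exposed separately.
- **Expansion summary space.** Expansion is computed on the source grid
  and summarized with the source-space parcellation; which space carries
  the summary is a pipeline option in principle, and the synthetic
  workflow keeps everything in the source space.
- **Label transport** between species spaces uses nearest-neighbor
  pull-back through the (invertible) deformation.

## The synthetic generator

`generate_species` emulates modulated GM probability maps: contiguous
parcels (slabs along the first grid axis) whose voxels share a per-subject
profile `base_j + slope_j·age + sex/TIV/scanner terms + u_{j,subject}`
plus i.i.d. Gaussian voxel noise, truncated at zero to respect the
non-negativity of VBM data. The per-parcel random effect `u`
(SD `parcel_effect_sd`, default 0.1) plants the structural covariance the
factorization exploits; the ratio `parcel_effect_sd / noise_sd` is the
parcel SNR (default 0.1/0.02 = 5). Defaults: 200 subjects, ages uniform
20–60 (9–50 for a chimpanzee-like sample), TIV Gaussian (1400 ± 120 ml),
sex and scanner Bernoulli with configurable imbalance, base GM 0.6 with a
±25% spread of per-parcel baselines.

`generate_deformation` builds a monotone stretch of the parcel axis whose
derivative blends per-parcel expansion factors through a partition of
unity (linear ramps at slab boundaries, half-width ≤ min(0.75 voxel,
10% of the narrowest slab)). The Jacobian determinant is therefore exactly
the blended factor profile — closed form, positive whenever the factors
are — and parcel means equal the requested factors up to the narrow ramps
(within 2%). An axis-aligned construction was chosen over a 3-D isotropic
blend precisely because the latter has no closed-form determinant to test
against.

What the generator does **not** emulate: MRI acquisition physics, bias
fields, segmentation error, registration error, spatially correlated
noise, hemispheric structure, or realistic cortical geometry. Passing
recovery tests therefore demonstrates the correctness and calibration of
the estimators under the stated generative model, not performance on real
images.

## Problem sizes used in the test suite

Recovery and calibration checks run at deliberately modest sizes chosen as
the smallest scales at which the phenomena are well separated: OPNMF
recovery at SNR 5 uses k_true = 5, m = 4096 voxels, n = 100 subjects;
granularity selection uses two species of 40 subjects on 12×9×9 grids over
k = 2..8 with 2 bootstraps and 20 seeds; regression calibration uses 1000
null parcel fits (n = 60) and 200 coverage replicates (n = 300, planted
slope −0.5); permutation calibration uses 2000 null datasets of 17 parcels
at 999 permutations. Production-scale settings (k to 40, 100 bootstraps,
100,000 permutations, 10,000 iterations) remain the library defaults.

## Known limitations

- OPNMF is a local optimizer; distinct covariance blocks with very similar
  profiles can still merge at unlucky draws even with the rescue step.
- The bootstrap MRE curve inherits optimizer noise: with few bootstraps a
  single poorly converged fit can distort Δ-MRE near the plateau edge.
- The analytic deformation varies along one axis only; it validates the
  Jacobian/expansion machinery but is not a stand-in for realistic
  nonlinear registration output.
- Aging models are cross-sectional OLS; no longitudinal, mixed-effects or
  nonlinear age trajectories.
- Permutation tests treat parcels as exchangeable; spatial autocorrelation
  between parcels is not modeled (no "spin"-style nulls).
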