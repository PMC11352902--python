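# crossmorph

Comparative neuroanatomy asks how brain organization differs between
primate species and what those differences cost: regions that expanded
most in recent evolution may be the ones most vulnerable to age-related
gray-matter (GM) decline. `crossmorph` implements a data-driven pipeline
for that question, aimed at researchers working with voxel-based
morphometry (VBM) data from two or more species:

1. **Species-wise parcellation** of modulated GM volumes by orthogonal
   projective non-negative matrix factorization (OPNMF),
2. **cross-species granularity selection** combining reconstruction-error
   plateaus with adjusted-Rand-index (ARI) similarity between species,
3. **relative cerebral expansion maps** from deformation-field Jacobians,
4. **parcel-wise brain-aging regression** with family-wise error control,
5. **permutation-tested association** between aging and expansion.

Because suitable multi-species imaging data are rarely at hand, the
package ships a first-class synthetic-data module that generates
two-species GM stacks with planted parcels, aging effects and an analytic
deformation with closed-form Jacobian — every pipeline stage is testable
by recovery against known ground truth.

## The model

OPNMF factorizes the non-negative voxels-by-subjects matrix
`X (m x n)` by solving

```
min_W  || X − W Wᵀ X ||²_F    s.t.  WᵀW = I,  W ≥ 0
```

with `W (m x k)` found by multiplicative updates

```
W'_ij = W_ij · (X Xᵀ W)_ij / (W Wᵀ X Xᵀ W)_ij
```

from a non-negative double-SVD (NNDSVD) start; subject weights follow by
projection, `H = Wᵀ X`. Winner-takes-all on `W`'s columns yields a hard
parcellation. The comparative granularity is chosen where the bootstrapped
change in mean reconstruction error (MRE) plateaus *and* the cross-species
ARI peaks. Expansion is the Jacobian determinant of the cross-species
deformation divided by the global brain-size ratio (value 1 = a region
grew in proportion to the whole brain); per-parcel means are z-scored and
correlated with per-parcel aging t-statistics, with significance from
permutation of the parcel assignment.

## Worked example

`examples/` contains one short script per capability. Recovering a planted
five-parcel organization (`examples/02_opnmf_parcellation.py`):

```
converged after 1795 iterations (rescues: 0)
mean reconstruction error: 0.000399
orthogonality residual |W^T W - I|: 0.0152
ARI vs planted parcels: 1.000  (1.0 = perfect recovery)
```

The reconstruction error sits at the noise floor of the generator
(noise SD 0.02 → MRE ≈ 4·10⁻⁴) and the parcellation matches the planted
labels exactly. Granularity selection on two synthetic species
(`examples/03_granularity_selection.py`):

```
k:          [2, 3, 4, 5, 6, 7, 8]
delta MRE:  [    nan 0.00285 0.00224 0.00184 0.      0.      0.     ]
mean ARI:   [0.02 0.17 1.   1.   1.   0.94 0.91]
plateau window: [5, 6, 7, 8]
selected granularity: k = 5 (planted k_true = 5)
```

Error improvements collapse beyond the planted k = 5, the plateau window
opens there, and the cross-species ARI selects 5. The remaining scripts
demonstrate expansion maps, aging regression (including the 1.15×
interspecies age-range matching with its 58-year human cutoff), the
permutation association test, and the end-to-end pipeline with its
file-based stages and manifest.

A thin CLI mirrors the pipeline stages for shell-driven runs:

```sh
crossmorph run-all --config config.yaml        # or: simulate, fit, ...
```

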