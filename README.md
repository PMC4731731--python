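# psica — parcellation-based nonparametric ICA

`psica` performs likelihood-based independent component analysis for
spatial signals — its motivating use is group spatial ICA of resting-state
fMRI, where the rows of the source matrix are brain-wide spatial maps and
the mixing matrix holds their time courses.  It is aimed at neuroimaging
and signal-processing researchers who want a blind-source-separation
method that (a) makes no parametric assumption about the source
distributions and (b) can relax the "identically distributed across all
voxels" assumption by giving each brain region its own source density.

## The model

Observed signals are noise-free linear mixtures of independent sources,

    X = A S,    B = A⁻¹,    Var S(q,·) = 1,   E S = 0,

and the joint log-likelihood over the V samples is

    L(B, f) = Σᵥ Σ_q log f_q(B(q,·) X(·,v)) + V log |det B| .

The source densities `f_q` are estimated by **P-spline histogram
smoothing**: bin counts of the source histogram are modelled as Poisson
with a log-linear cubic B-spline intensity plus a difference penalty on
adjacent spline coefficients (Eilers–Marx).  The exponentiated,
renormalized spline is a proper smooth density whose score
`ψ = (log f)′` is available analytically, so `L` has closed-form gradient
and Hessian in `B` and is maximized by safeguarded **Newton–Raphson**
steps alternating with density refreshes.  Convergence is monitored with
the **Amari metric** between successive unmixing matrices, which is blind
to the permutation and scaling indeterminacies of ICA.

With a voxel parcellation (e.g. a functional atlas), the density of each
component is fitted **per region** (`f_{iq}` on region `i`) and every
voxel is scored under its own region's density — sources need only be
i.i.d. within a region.  With one region this reduces exactly (bit for
bit) to the global algorithm.

Multi-subject data are handled by temporal concatenation with a two-stage
SVD reduction (within-subject rank `R`, group rank `Q`); subject-level
mixing matrices are back-reconstructed from the stored operators.

See `docs/methods.md` for the full method description and the reasoning
behind the defaults.

## Worked example

Two sources whose *overall* distributions are both approximately standard
normal, but which are uniform / Laplace within each of the ten
equal-probability intervals of the normal — the regime where
contrast-function ICA fails and region-specific densities are essential:

```python
import numpy as np
from psica import gen_setting2, run_ica, amari_error_vs_truth, spatial_correlation

ds = gen_setting2(V=10_000, seed=1)          # region-structured sources, A = [[2,1],[3,2]]
state = run_ica(ds.X, parcellation=ds.parcellation)

print(f"converged: {state.converged} after {state.iteration} iterations")
print(f"final log-likelihood: {state.loglik_trace[-1]:.1f}")
print(f"Amari error vs truth: {amari_error_vs_truth(state.B, ds.A_true[0]):.4f}")
corr = spatial_correlation(state.S, ds.S_true)
print(f"matched |correlation| per component: {np.round(corr, 4)}")
print("estimated mixing matrix (columns up to order/scale):")
print(np.round(state.mixing, 3))
```

prints

```
converged: True after 14 iterations
final log-likelihood: 20487.3
Amari error vs truth: 0.0497
matched |correlation| per component: [1.     0.9997]
estimated mixing matrix (columns up to order/scale):
[[-2.06   0.944]
 [-3.131  1.876]]
```

The Amari error of 0.05 means the estimated unmixing matrix is a
near-perfect scaled permutation of `A⁻¹`; both recovered spatial maps
correlate ≥ 0.9997 with the truth, and the mixing-matrix columns match
`[[2,1],[3,2]]` up to the usual sign/order indeterminacy.  Running the
same data through `run_ica(ds.X)` *without* the parcellation leaves the
Amari error around 0.8 — the sources are too close to Gaussian overall
for any global-density method.

## Command line

```bash
psica simulate --scenario 2 --V 10000 --seed 1 --out-dir sim/
psica fit --input sim/X.csv --parcellation sim/labels.txt --out-dir fit/
psica fit --nifti data4d.nii.gz --mask mask.nii.gz --n-components 20 --out-dir out/
psica benchmark --scenario 2 --reps 50 --methods pspline,pspline-parc,fastica --out bench.csv
psica density-fit --input samples.txt --out density.tsv
```

Every run writes a `manifest.json` (inputs, settings, seed, package
version); outputs are deterministic given inputs and seed.

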