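# mnsf — multi-sample non-negative spatial factorization

Spatially resolved transcriptomics experiments increasingly span several
tissue sections: serial sections of one donor, replicate sections across
donors, even different platforms. Classic spatial factorization operates on
one section at a time, and combining sections usually requires aligning them
into a consensus coordinate system — which is ill-posed when sections are
rotated, differently sized, distorted, or come from disjoint anatomy.

`mnsf` factorizes multi-sample spot-by-gene count matrices **without any
spatial alignment**. The model shares one non-negative gene-loading matrix
across samples while giving every sample its own spatial process per factor:

```
Y_m[i, g]  ~  NB( sz_m[i] * Σ_l W[g, l] · exp(F_m[i, l]) ,  φ_m )
F_m[·, l]  ~  GP( β0_ml + β1_ml · x ,  k_ml )          k_ml(a, b) = α_ml · exp(−‖a−b‖ / B_ml)
```

- `W` (genes × factors, `W ≥ 0`) is shared: factors carry the same gene-level
  meaning in every sample.
- `F_m` (spots × factors, log scale) is sample-specific: each factor's spatial
  field is a Gaussian process with its own amplitude `α_ml`, lengthscale
  `B_ml`, and affine mean — samples never need to live in a common
  coordinate system.
- Counts are negative-binomial with per-spot size factors `sz` and per-sample
  dispersion `φ_m` (variance `μ + μ²/φ`; Poisson as `φ → ∞`).

Fitting maximizes a sparse-variational evidence lower bound with inducing
points (default 35% of spots) and optional random chunking of large samples.
Because samples are independent given `W`, the objective decomposes per
sample; each outer iteration takes one Adam step per sample (or chunk) on its
own negative ELBO — including a private copy of `W` — then averages the
per-sample `W` updates and projects negative entries to zero. Gradients are
fully analytic (NumPy); the expected likelihood uses reparameterized
Monte-Carlo draws of the factors.

A non-spatial variant (`fit_pnmf`) replaces the GP prior with an iid normal
prior — multi-sample probabilistic NMF — using the same observation layer and
training loop.

## Worked example

Simulate the rotated-factor benchmark — two 12×12-grid samples, 200 genes,
four block-shaped latent factors, with sample 2's patterns rotated 90°
anticlockwise — then fit and evaluate recovery:

```python
import numpy as np
from mnsf import (FitConfig, design_preset, fit, match_factors, morans_i,
                  simulate_dataset)

design = design_preset("fig1a", grid_shape=((12, 12), (12, 12)),
                       n_genes=200, seed=1)
samples, truth = simulate_dataset(design)

config = FitConfig(L=4, max_iter=500, convergence_tol=0.0,
                   inducing_fraction=1.0, seed=1)
result = fit(samples, config)

matching = match_factors([f.usage for f in result.factors], truth.true_factors)
print("estimated -> true factor:", matching.permutation)
print("matched |r|:", np.round(matching.correlations, 3))
for m, sample in enumerate(samples):
    I = [morans_i(result.factors[m].values[:, l], sample.coords)
         for l in range(4)]
    print(f"Moran's I, {sample.sample_id}:", np.round(I, 3))
```

Output:

```
estimated -> true factor: [2 1 0 3]
matched |r|: [0.913 0.91  0.936 0.926]
Moran's I, sample1: [0.738 0.845 0.802 0.733]
Moran's I, sample2: [0.788 0.726 0.757 0.785]
```

Factor order out of a factorization is arbitrary, so estimated factors are
paired to ground truth by a Hungarian assignment on |Pearson r| (first line).
Every true factor is recovered at |r| ≥ 0.91 despite the 90° rotation between
samples, and every recovered factor field shows strong spatial
autocorrelation (Moran's I ≈ 0.73–0.85) in both samples.

## Command line

```sh
mnsf simulate --design fig1a --out sim/            # counts/coords TSVs + truth
mnsf fit --manifest sim/manifest.json --factors 4 \
         --inducing-fraction 0.35 --seed 1 --out fit/
mnsf evaluate --fit fit/ --truth sim/ --out metrics.json
```

`mnsf fit` reads a JSON manifest listing samples in either Visium-style
directories (MatrixMarket counts + barcodes/features + tissue positions) or
plain counts/coords TSV pairs, and writes per-sample factor CSVs, the loading
matrix, the loss trajectory and a config echo. `mnsf evaluate` computes
Moran's I per factor, recovery correlations against simulation truth, marker
genes per factor, and (given labels) multinomial layer-prediction accuracy
and deviance.

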