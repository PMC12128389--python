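# Methods

## Model

For sample `m` with `N_m` spots at 2-D locations `X_m`, `G` genes shared
across samples and `L` latent factors, the observed count for gene `g` at
spot `i` is

    Y_m[i, g] ~ NB( mu_m[i, g], phi_m ),
    mu_m[i, g] = sz_m[i] * Σ_l W[g, l] * exp(F_m[i, l]).

The NB is parameterized by mean and shape with variance `mu + mu^2/phi`, so
`phi -> inf` recovers Poisson counts. `sz_m` are known per-spot size factors
(library size divided by its mean, so `mean(sz) = 1`). The loading matrix
`W >= 0` is shared by all samples; everything else is sample-specific.

Each log-scale factor column follows a Gaussian process over the sample's own
coordinates with affine mean `beta0_ml + beta1_ml . x` and exponential
(Matern-1/2) covariance

    k_ml(a, b) = alpha_ml * exp( -||a - b|| / B_ml ),

`alpha_ml` the amplitude (prior variance) and `B_ml` the lengthscale. The
kernel uses a negative exponent — covariance decays with distance — and the
amplitude multiplies the exponential while the lengthscale divides the
distance. Coordinates are centered and scaled per sample to maximum absolute
value 1 before kernel evaluation (aspect ratio preserved, transform recorded
and invertible), so lengthscales are comparable across samples of different
physical sizes.

Because samples are conditionally independent given `W`, no cross-sample
spatial correspondence is assumed anywhere: rotated, resized, distorted or
entirely disjoint sections are all handled by their sample-specific
processes.

A non-spatial variant replaces the GP prior with `F_m[., l] ~ N(mu_l,
sigma2_l)` iid over spots, with factor-level parameters shared across samples
(multi-sample probabilistic NMF). It reuses the observation layer, a
mean-field Gaussian over `F`, and the same training loop; the prior
parameters are combined across samples by the same averaging step as `W`.

## Sparse variational inference

Each (sample, factor) GP is parameterized at `n_m` inducing locations `Z_m`
(a seeded uniform subset of the spots; fraction 0.35 by default) through a
free Gaussian `q(U) = N(m, C C^T)` with a full lower-triangular Cholesky
factor `C` (log-parameterized diagonal). The factor at observed spots enters
through the exact conditional

    F | U ~ N( mu(X) + Kxu Kuu^{-1} (U - mu(Z)),  Kxx - Kxu Kuu^{-1} Kux ),

with jitter `1e-6 * alpha` added to the diagonal of `Kuu`. The ELBO is

    E_q[ log p(Y | F) ] - KL( q(U) || p(U) ),

where the KL is the closed-form Gaussian divergence and the expected NB
log-likelihood is estimated per spot from the marginal `q(F)` (mean and
variance) by reparameterized Monte-Carlo draws — one draw per iteration by
default (`mc_samples`). A deterministic alternative
(`objective="delta"`) replaces `E[exp F]` with the lognormal mean
`exp(mean + var/2)`.

The stochastic estimator is the default deliberately, not only for fidelity
to stochastic variational practice: the deterministic objective's exact
optimum over-smooths factors that carry no signal in a given sample. A factor
that is active in one sample but absent in another is, in the absent sample,
only weakly constrained by the likelihood, and the GP prior then dominates,
producing a spurious smooth field with high spatial autocorrelation. The
gradient noise of the MC estimator keeps those loss-neutral degrees of
freedom at the per-spot noise level, so an absent factor is estimated as
spatially unstructured — which is the scientifically correct readout.

All gradients — variational means and Cholesky factors, kernel amplitude and
lengthscale, mean coefficients, loadings, and optionally dispersion — are
derived analytically and implemented in NumPy (positivity via unconstrained
logs except `W`; see below). Both objective branches are verified against
central finite differences in the test suite.

## Multi-sample training loop

One outer iteration:

1. For each fitting unit (a sample, or one random chunk of a sample), take
   one Adam step on the unit's own negative ELBO, updating the unit's GP and
   variational parameters and a private copy of `W` (per-unit Adam moments).
2. Set `W` to the average of the per-unit updated copies.
3. Set negative entries of the averaged `W` to zero (average first, then
   project).

This exploits the additivity of the objective across samples: the sum of
per-unit losses recorded each iteration equals the total loss. With one
sample the loop degenerates exactly to single-sample training (tested step
for step). Training runs up to `max_iter` iterations (default 1000) or until
the relative change of a 10-iteration moving average of the loss falls below
`convergence_tol` (default 1e-4). Note the loss-based check can fire while
loss-neutral parameters (e.g. null-factor fields, above) are still evolving;
the benchmark studies therefore run their full iteration budget
(`convergence_tol=0`).

Chunking partitions a sample's spots into random near-equal subsets fitted
as separate units with their own inducing points and GP hyperparameters,
sharing `W` through the averaging step (uniform weight per unit). It trades
runtime for memory on large samples. Reported per-sample hyperparameters for
chunked fits are across-chunk means; posterior factors are stitched back by
spot index.

Initialization: multiplicative-update NMF (KL loss, scikit-learn) on the
column-concatenated, size-factor-normalized counts gives `W` and non-negative
per-spot scores; `q` means start at the log scores at inducing spots, kernel
amplitude at 1, lengthscale at 0.1 x the (rescaled) coordinate range,
`C = 0.1 I`. All randomness — NMF, inducing selection, chunk partition, MC
draws — derives from one master seed through named substreams, making the
whole pipeline deterministic given the seed.

## Defaults and their rationale

| parameter | default | units / meaning | rationale |
|---|---|---|---|
| `L` | 4 | factors | matches the benchmark designs; real analyses typically use 10–20 |
| `inducing_fraction` | 0.35 | fraction of spots | standard operating point balancing cost and accuracy |
| `n_chunks` | 1 | chunks per sample | chunking only needed for memory-limited fits |
| `learning_rate` | 0.05 | Adam step size | full-batch analytic gradients tolerate larger steps than minibatch settings; converges the benchmarks within 500 iterations |
| `max_iter` | 1000 | iterations | upper bound; convergence check may stop earlier |
| `mc_samples` | 1 | draws/iteration | single-draw reparameterization, standard for SVI |
| `dispersion_init` | 10 | NB shape | mild overdispersion; factorization is insensitive over a wide range, so it is fixed unless `optimize_dispersion=True` |
| `jitter` | 1e-6 | x amplitude | numerical floor for `Kuu` |
| Moran's I `k` | 6 | neighbors | hexagonal-lattice (Visium-like) neighborhood, row-standardized |

## Synthetic data

The generator emulates multi-sample designs on rectangular grids: `L`
disjoint block patterns (quadrants for L=4, stripes for L=2) with exp-scale
contrast 10:1 (high 1.0, background 0.1); per-sample pattern rotation in
quarter turns; per-sample null factors (pattern replaced by the constant
background); per-sample size scaling, smooth sinusoidal coordinate warps, and
log-scale Gaussian noise (sd 0.3 by default). Loadings give each factor an
exclusive block of marker genes (`Gamma(2, 2.5)`, mean 5) over a flat 0.05
background; counts are drawn from the model's own NB observation layer
(dispersion 10, unit size factors). Defaults: 2 samples, 36x36 grids, 500
genes, 4 factors; presets `fig1a` (rotation), `fig1c` (null factor in sample
2), `figS1a/b/c` (size, distortion, noise asymmetries).

What the generator does not emulate: hexagonal Visium geometry, segmentation
artifacts, zero-inflation, gene-specific dispersion, cell-type mixtures with
realistic co-expression, platform batch effects. Passing recovery tests on
these simulations demonstrates that the estimator identifies rotated,
sample-specific and distorted spatial programs under NB noise — not that it
resolves the subtler structure of real tissue data.

## Benchmark studies (tests and acceptance script)

The recovery studies are scaled down for desk-scale runtimes: two 12x12
grids, 200 genes, 4 factors, 500 iterations. At this size the sparse
approximation is unnecessary, so the recovery fits use all spots as inducing
points; a 35%-fraction fit is run separately for the stability comparison,
and a two-chunk fit for the chunking comparison. Factor matching uses
exp-scale factors (the non-negative usage); Moran's I is computed on the
log-scale latent fields with k=6 neighbors. Typical results: matched |r|
around 0.9, Moran's I of recovered active factors 0.7–0.9, null-sample
Moran's I near zero (roughly 0.05–0.15 across seeds), and total Poisson
deviance decreasing with rank.

## Numerical choices and degenerate inputs

- `Kuu` solves use Cholesky factorization; jitter scales with amplitude; a
  non-positive-definite system raises with the inducing-point count in the
  message.
- Conditional variances are floored at 1e-12 (gradient masked where the floor
  binds); NB means are floored at 1e-10.
- `W` non-negativity is enforced by projection (not log-parameterization) to
  keep exact zeros reachable — sparse loadings are scientifically meaningful.
- Spots with zero total counts are rejected by size-factor computation
  (explicitly listed), with a flag to mark-and-drop instead.
- All-zero genes are excluded from NMF initialization (zero loadings) and
  from marker ranking, with warnings.
- Gene selection ties break by original gene order; marker-assignment ties
  break toward the lower factor index.
- `elbo()` validates that `W` has at least one strictly positive column; a
  loading-free model is rejected rather than silently degenerate.

## Limitations

- The ELBO is non-convex; different seeds give different local optima.
  Factor order and sign of correlations are arbitrary (hence Hungarian
  matching on |r|).
- Dispersion is per sample, not per gene; strongly gene-specific
  overdispersion is absorbed into loadings and factors.
- The exponential kernel implies rough (non-differentiable) sample paths;
  other Matern orders are not implemented.
- Loss-based convergence detection is unreliable for loss-neutral parameter
  drift (see above); fixed iteration budgets are recommended for comparable
  runs.
- Runtime scales linearly in genes and iterations and cubically in inducing
  points per (sample, factor); the NumPy implementation targets desk-scale
  and moderate (10^3–10^4 spots) samples.
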