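# Methods

This note describes the method implemented by `spagate` and the concrete
choices made in this implementation, in the notation used throughout the
code. Spots are indexed `i = 1..N`; `c_i` is the 2-D coordinate of spot
`i` and `x_i` its preprocessed expression profile over `M` genes.

## Preprocessing

Raw counts pass through three steps, in order: selection of `M` highly
variable genes on the raw matrix (Seurat-style binned normalized
dispersion: genes are binned by mean expression, the variance/mean
dispersion is z-scored within each bin, and the top `M` genes are kept
in their original order; default `M = 3000`), library-size normalization
of each spot to a total of 10,000, and `log(1 + x)`. Spots with zero
total counts are dropped with a warning; negative input values are
rejected.

## Hybrid neighbor graph

Two similarity kernels are computed for every pair of spots within
Euclidean radius `d` of each other:

- spatial: `ES_ij = exp(-||c_i - c_j||^2 / (2 eta^2))`,
- expression: `CS_ij = (x_i . x_j) / (||x_i|| ||x_j||)`,

and blended as `S_h = alpha * ES + beta * CS` (defaults
`alpha = beta = 0.5`). Pairs beyond the radius, and pairs whose blended
weight is not strictly positive, carry no edge. The default radius is
chosen as the smallest pairwise distance at which the mean degree of the
radius graph reaches 6, and the default bandwidth is `eta = d / 2`, so
an immediate neighbor at distance `d` retains weight `exp(-2) ~ 0.135`
under the spatial kernel. The graph is symmetric with a zero diagonal.

A practical note: after normalization and `log1p` the expression
vectors are non-negative, so `CS >= 0` and the positivity pruning rule
can only fire when `alpha` or `beta` is modified away from the defaults
(e.g. by centering expression or reweighting the kernels). On such data
the graph topology is driven by the radius gate, and the kernels shape
the edge *weights* available to downstream consumers.

## Graph attention auto-encoder

The encoder stacks attention layers. Layer `k` with weight `W_k` maps
the hidden features `h` to `z = h W_k` and aggregates them over each
spot's neighbor set `G_i` (plus a self-edge):

```
u_i = sigma( sum_{j in G_i} a_ij z_j ),
e_ij = phi( delta_s . z_i + delta_r . z_j ),
a_ij = exp(e_ij) / sum_{j' in G_i} exp(e_ij'),
```

with `sigma = ELU`, attention nonlinearity `phi = logistic`, and
trainable attention vectors `delta_s, delta_r`. The softmax runs over
each spot's neighbor set, so every attention row sums to one. The
decoder mirrors the encoder in reverse order (independent weights by
default; transposed encoder weights optionally) with a linear final
layer so reconstructions live on the input scale. Default architecture:
`[M, 128, 30]` (the hidden width is a desk-scale sizing choice and is
config-exposed, as are all dimensions). Weights are Xavier-uniform
initialized from the run seed.

Attention uses the graph *topology*; edge weights select which pairs are
connected but do not enter the attention scores directly.

## Training objectives

The total loss is `L = lambda * L_rec + mu * L_gcl + gamma * L_sr`, with
defaults `lambda = 1`, `mu = 1`, `gamma = 0.1`.

**Reconstruction.** `L_rec = sum_i ||x_i - x_hat_i||^2`, a sum (not a
mean) over spots and genes.

**Contrastive (infomax-style).** Each epoch draws a corruption: the rows
of the expression matrix are shuffled while the graph topology is kept
fixed. Both views are encoded with the same weights, giving positive
embeddings `U` and negative embeddings `U'`. A summary vector
`r = logistic(mean_i(U_i))` represents the whole graph, and a bilinear
discriminator `D(u, r) = logistic(u^T W_D r)` scores embeddings against
it:

```
L_gcl = -(1/2N) sum_i [ log D(U_i, r) + log(1 - D(U'_i, r)) ]
```

Probabilities are clamped at `1e-8` before the log.

**Spatial regularization.** With `H_ij` the cosine similarity of the
embeddings of spots `i` and `j` and `psi` the logistic function:

```
L_sr = - sum_i [ sum_{j in N_i} log psi(H_ij)
               + sum_{o in S_i} log(1 - psi(H_io)) ]
```

where `N_i` is the neighbor set and `S_i` a per-spot uniform sample of
non-neighbors (default 30 per spot, resampled each epoch; an exhaustive
mode enumerates every non-neighbor and is used by the test oracles).

**Optimization.** Full-batch Adam (lr `1e-3`, L2 weight decay `1e-4`),
200 epochs by default. One run seed drives initialization, per-epoch
corruption permutations, and negative sampling through a single seed
stream, so runs are bit-reproducible. Gradients come from a small
reverse-mode automatic differentiation engine over numpy
(`spagate/_autodiff.py`); neighbor aggregation is evaluated as sparse
CSR matrix products for speed.

**Loss scales.** On the default fixture `L_rec` is of order `1e6` while
`L_gcl` is of order 1, yet their encoder gradients are comparable in
magnitude (the contrastive signal flows through the saturating
discriminator, the reconstruction signal through many small residuals),
so `mu = 1` already gives the contrastive term real influence on early
training; raising `mu` by orders of magnitude degrades domain recovery
on the synthetic fixtures. The spatial term, though small in value,
measurably improves domain recovery on noisy data (disabling it lowers
mean ARI in the ablation battery). The weights are exposed
(`lambda_rec`, `mu_contrastive`, `gamma_spatial`) for rebalancing.

**Ablations.** Five variants are wired through one switch: `full`;
`no_cs` (expression kernel off, `beta = 0`); `no_es` (spatial kernel
off, `alpha = 0`); `no_cl` (`mu = 0`); `no_reg` (`gamma = 0`). The
ablations that alter the graph require a graph built with the matching
kernel weights. Note that on non-negative log-normalized data `no_cs`
and `no_es` leave the radius-gated topology unchanged (see the pruning
remark above); since training consumes the topology, on such data these
two variants only change the edge weights exported for downstream
inspection, not the learned model.

## Downstream

The final embeddings are a single clean encoder pass with the trained
weights. Domains come from a full-covariance Gaussian mixture (best of
10 initializations; latent spaces wider than 20 dimensions are first
PCA-reduced to 20), or from the reference R `mclust` implementation
(model `EEE`) through an `Rscript` subprocess when available. External
quality is measured by the adjusted Rand index and normalized mutual
information; internal structure by the Davies-Bouldin index and the
cophenetic correlation coefficient (average-linkage hierarchy on
Euclidean embedding distances). Denoised expression is the trained
decoder's reconstruction of the input.

## Synthetic fixtures

Ground-truth data places spots on a regular grid partitioned into `K`
spatially contiguous domains (vertical bands by default, Voronoi patches
optionally). Each domain elevates its own block of marker genes by a
constant over a shared baseline; Gaussian (clipped at zero) or Poisson
noise and independent dropout give count-like sparsity. The pinned
default fixture is a 20x20 grid, 4 domains, 600 genes, 40 markers per
domain, signal strength 2 over baseline 1, Gaussian noise sd 1, dropout
0.2, seed 7; a noisy variant (sd 2, dropout 0.3) is used for ablation
and denoising evaluation.
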