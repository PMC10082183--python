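# Methods

## Model overview and assumptions

`spotdecon` treats spot-level deconvolution as semi-supervised transfer
learning: an annotated scRNA-seq reference defines K cell types, and the
spots are unlabeled mixtures to be placed in the same latent space. The
approach assumes (i) spots that are physically close and histologically
similar have similar composition, which justifies local smoothing of the
noisy spot expression; (ii) the reference and the spatial data measure
comparable transcriptional states, so that after per-matrix
standardization a common embedding is meaningful; and (iii) the soft
assignment of a spot's embedding to pure-type centroids under a
Student's-t kernel approximates its mixing proportions. The last
assumption is the method's core simplification: proportions are read off
a similarity kernel rather than estimated by an explicit generative
mixture model, which is what makes the method fast but also means
proportions are calibrated only up to the kernel's geometry.

## Graph smoothing

The histology coordinate of a spot is the variance-weighted average of
its window-mean RGB channels; the channel that varies most across the
tissue dominates, on the grounds that it carries the most morphological
contrast. Windows are 50×50 full-resolution pixels by default and are
clamped at image borders (partial windows average over the available
pixels); border spots therefore use slightly smaller windows rather than
failing. The channel variances are computed over the per-spot window
means, not over all raw pixels — the spot is the unit of analysis
throughout, so spot-level granularity is the consistent choice.

Scaling (`z* = (z − μ_z)/σ_z · max(σ_x, σ_y) · s`) uses the population
(÷N) convention for every variance and standard deviation in the
package; the convention must simply be fixed once for reproducibility.
A numerically constant `z` (relative spread below 1e−12) yields
`z* = 0`: constant histology carries no information and the method
degrades gracefully to 2-D smoothing, as it also does when the image or
pixel coordinates are absent. With no spatial coordinates at all the
smoothing step is skipped entirely (`A = I`).

The mean off-diagonal row sum of the adjacency matrix is monotone
increasing in the length scale `l`, so calibration to the target (0.5 by
default: neighbors jointly get half the self-weight) uses bisection on
`log l` with an initial bracket of [1e−3, 1e3] times the median
nearest-neighbor distance, tolerance 1e−3 on the achieved mean weight,
and a 100-iteration cap. An unreachable target raises an error that
reports the achievable range. Kernel values that underflow to exact zero
for very distant spot pairs are accepted (mathematically the kernel is
strictly positive).

## Preprocessing

Highly variable genes are ranked by the dispersion (variance/mean) of
log1p counts, with ties broken by input gene order so runs are
reproducible; dispersion is preferred to raw variance because count
variance grows with the mean. The default panel size is min(5000, M).
After intersecting the panel with the reference's genes, both matrices
are log1p-transformed and z-scored per gene *within each matrix
independently*; this removes platform scale differences before the joint
embedding, which is the entire point of standardizing. Genes constant in
either matrix are dropped from both so no standardized column is
degenerate.

## Embedding network

The encoder is a stacked denoising autoencoder trained on the stacked
(spots + cells) × genes matrix. Defaults: architecture [p, 256, 64] for
fewer than 10,000 rows and [p, 512, 128, 64] above (the bottleneck
shrinks for small gene panels so dimensions stay strictly decreasing);
corruption by masking 20% of features to zero, redrawn every epoch;
Adam at 1e−3, batch size 256; 100 epochs per layer of pretraining and
200 of end-to-end fine-tuning. Hidden activations are ReLU; the
bottleneck and the final decoder layer are tanh because latent features
and reconstructed z-scores must take both signs. All weights initialize
Glorot-uniform from a seeded generator, and every batch order and
corruption mask flows from the same seed, so training is bit-reproducible.
The implementation is plain NumPy with hand-derived backpropagation —
the network is small enough that a deep-learning framework would add
nothing but a dependency.

## Clustering layer and its target distribution

The target matrix R assigns each cell mass on its labeled type plus
`Uniform(0, 1e−5)` noise everywhere (the noise keeps `log r` finite and
breaks exact ties), then normalizes every **column** to sum to 1, so each
cell type contributes equal total mass regardless of its cell count.
Noise is added in both branches (own-type and other-type entries alike)
and R is drawn once per run from the seed.

Two consequences of the column normalization are worth stating
explicitly. First, the loss `L = Σ r log(r/q)` compares measures with
different totals (R sums to K, Q row-normalized sums to N), so L is not
bounded below by zero and goes negative as Q concentrates on the correct
types; its minimum over row-normalized Q is `Σ_i s_i log s_i` with
`s_i` the row mass of R. L = 0 iff R = Q still holds for matched
normalized pairs. Second, every gradient carries the factor `s_i ≈ K/N`
relative to the row-normalized convention of classic deep embedded
clustering, so the SGD learning rate defaults to 0.1 rather than the
classic 0.01 — at 0.01 the per-epoch loss decrease sits below the
convergence threshold from the first epoch and training would stop at
initialization. Momentum is 0.9, updates are full-batch, and the
gradients of the t-kernel KL objective are closed-form (verified against
finite differences in the test suite).

Training stops when the loss decrease between consecutive epochs falls
below 0.01, or at 2000 epochs. "Consecutive updates" is read as
consecutive epochs, the natural unit under full-batch updates. If the
loss instead rises for more than 20 consecutive epochs the best
checkpoint is restored with a warning. Centroids are initialized at the
per-type mean embeddings and thereafter updated by gradient only, the
convention of deep embedded clustering. The spots are excluded from this
supervised phase; they only pass through the trained encoder at
inference, where each row of Q is the spot's proportion estimate.

## Pseudo-spot benchmark construction

Reference cells are first rescaled so each cell's counts sum to a common
divisor (1000), mirroring TPM-scale data brought down to spot-like
depth; at a mean UMI budget of 2400 this draws about 2.4 cells per spot.
For spot i and type j, `n_ij = (U_i/1000)·p_ij` cells are required;
`n*_ij = ⌈n_ij⌉` cells are sampled **with replacement** (sampling
without replacement would fail whenever `n*_ij` exceeds the type's pool)
and their counts are multiplied by `n_ij/n*_ij`. The pre-rounding spot
total then equals `U_i` exactly — an algebraic identity, since
`Σ_j n*_ij·1000·(n_ij/n*_ij) = 1000·Σ_j n_ij = U_i` — and the final
matrix rounds half-to-even (NumPy's default), keeping totals within the
number of sampled cells of `U_i`. Consensus benchmark proportions take
the per-spot minimum across methods for the `n_rare = 2` types with the
smallest across-method mean (a conservative score for rare types,
computed before any renormalization) and the per-spot mean elsewhere,
then renormalize rows once.

MSE is computed per cell type (mean over spots of squared error); JSD is
computed per spot with logarithms base 2 so values live in [0, 1], with
`0·log 0 := 0`.

## Synthetic fixture

The fixture generator emulates the structure the method exploits: K = 3
cell types, each with a 200-gene marker block upregulated 8-fold over a
shared lognormal base-rate profile, plus 400 background genes;
negative-binomial counts via a gamma–Poisson mixture with shape 2 (a
realistic overdispersion for UMI data); 300 reference cells; 400 spots
on a 20×20 grid whose true compositions vary smoothly as a softmax of
negative distance to K random region centers (sharpness 0.35, giving
dominant proportions around 0.6–0.9 with graded boundaries); per-spot
UMI budgets normal around 2400; spot counts assembled by the pseudo-spot
sampler; and a 400×400 RGB raster whose regions are colored by distinct
palettes blended through the same spatial mixture, plus pixel noise, so
histology genuinely correlates with composition. What the fixture does
*not* emulate: batch effects between reference and spots, ambient RNA,
segmentation artifacts, cell types absent from the reference, or
marker-gene overlap between types. Passing tests therefore demonstrate
correct mechanics and recovery under clean, well-separated conditions —
not performance on tissue with subtle type boundaries.

## Problem sizes and numerical choices

The test suite runs most module tests on a miniature fixture (49 spots,
90 cells, 110 genes, shortened training) and reserves the full-size
fixture (400 spots, 300 cells, 1000 genes, default training) for the
acceptance tests; the full fit takes well under a minute on one CPU.
Degenerate inputs are handled by explicit conventions rather than
errors where information is merely absent (constant histology, missing
image, missing coordinates) and by errors where the request is
contradictory (positive proportion for a type with no cells, empty gene
intersection, unreachable calibration target). Dispersion of an all-zero
gene is defined as 0; z-scoring uses a relative threshold of 1e−12 to
classify a column as constant.

## Known limitations

Proportion estimates inherit the t-kernel's geometry: very sharp
compositions are shrunk toward the interior of the simplex, and a type
whose centroid sits close to another's will bleed proportion mass into
it. The method does not estimate absolute cell counts per spot, does not
segment cells, and assumes the reference covers every type present in
the tissue.
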