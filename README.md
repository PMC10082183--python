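# spotdecon

Semi-supervised cell-type deconvolution for spatial barcoding-based
spatial transcriptomics (10x Visium, Spatial Transcriptomics and
similar platforms).

Spatial barcoding measures expression at *spots* that each contain
roughly 1–30 cells, so a spot's profile is a mixture over cell types.
`spotdecon` estimates the mixing proportions of each spot using three
sources of information: the spot expression matrix, the spots' spatial
coordinates, and the H&E histology image — together with an annotated
scRNA-seq reference that defines the K cell types.

## Method

1. **Histology-aware smoothing.** Each spot gets a scalar histology
   coordinate `z_v = (r_v·V_r + g_v·V_g + b_v·V_b) / (V_r + V_g + V_b)`
   from the mean RGB of the 50×50-pixel window around it (`V_c` are the
   across-spot channel variances), scaled so that at `s = 1` its variance
   matches the wider spatial axis. Spot similarity is a Gaussian kernel
   on the 3-D distance, `a(u,v) = exp(−d(u,v)² / 2l²)`, with the length
   scale `l` calibrated automatically so the mean off-diagonal row sum of
   the adjacency matrix `A` equals 0.5; expression is smoothed as
   `X* = A X`.
2. **Joint embedding.** Smoothed spots and reference cells are reduced
   to shared highly variable genes, log1p-transformed, z-scored, stacked
   and mapped to a d=64-dimensional latent space by a stacked denoising
   autoencoder (layer-wise pretraining, then end-to-end fine-tuning).
3. **Clustering layer.** One centroid per cell type is initialized at the
   type's mean embedding. Soft assignments use a Student's-t kernel,
   `q_ij ∝ (1 + ‖z_i − μ_j‖²)⁻¹`, and the encoder and centroids are
   trained on the labeled cells only, minimizing
   `KL(R‖Q) = Σ r_ij log(r_ij/q_ij)` against a fixed label-derived
   target `R` by SGD with momentum, stopping when the loss decrease
   falls below 0.01 per epoch (max 2000 epochs).
4. **Inference.** Each spot's embedding is soft-assigned to the
   centroids; the resulting row of `Q` is its cell-type proportion
   estimate.

The package also ships the benchmarking toolkit: a pseudo-spot simulator
that mixes reference cells at known proportions while conserving each
spot's UMI budget exactly, consensus benchmark-proportion construction
from multiple methods' outputs, and evaluation by per-type mean squared
error and per-spot Jensen–Shannon divergence (base 2).

## Worked example

```python
from spotdecon import SpotDeconvolution
from spotdecon.benchmark import generate_synthetic_fixture

ref, srt, truth = generate_synthetic_fixture(seed=1)   # 400 spots, 3 types
results = SpotDeconvolution(srt, ref).fit(seed=1)
print(results.summary())
report = results.evaluate(truth)
print({k: round(v, 3) for k, v in report.summary.items()})
```

prints

```
Spot-level cell-type deconvolution results
==============================================
spots:                  400
cell types:             3
genes used:             1000
smoothing:              on (with histology)
calibrated length scale: 0.5241
mean neighbor weight:    0.4997
training epochs:        53 (converged: loss decrease 0.009886 < 0.01 at epoch 52)
final KL loss:          -13.4185

mean proportion per cell type:
  type_0                   0.4227
  type_1                   0.3259
  type_2                   0.2515
{'mean_mse': 0.011, 'median_mse': 0.01, 'mean_jsd': 0.027, 'median_jsd': 0.02}
```

The calibrated length scale gives neighboring spots, on average, half
the weight of the spot itself during smoothing; the low per-type MSE and
per-spot JSD show the estimated compositions track the fixture's known
truth closely.

The same pipeline is available from the shell:

```bash
spotdecon simulate --mode fixture --out fixture/ --seed 1
spotdecon run --srt fixture/srt --layout csv \
    --ref fixture/reference_counts.csv --labels fixture/reference_labels.csv \
    --out proportions.csv --truth fixture/truth.csv --seed 1
spotdecon evaluate --est proportions.csv --truth fixture/truth.csv --out-prefix eval/run
spotdecon calibrate --srt fixture/srt --layout csv
```

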