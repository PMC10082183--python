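"""Pseudo-spot benchmark construction, evaluation metrics, and the
synthetic fixture generator.

Pseudo-spots with known composition are assembled by sampling annotated
reference cells: each cell is first rescaled so its counts sum to a common
``scale_divisor`` (1000 by default), the number of cells of type j drawn
for spot i is n_ij = (U_i / scale_divisor) * p_ij rounded up to n*_ij, and
the sampled cells' counts are multiplied by n_ij / n*_ij so that the
pre-rounding spot total equals the requested UMI budget U_i exactly.  The
final integer matrix rounds half-to-even.

Estimates are scored against the truth by per-cell-type mean squared error
and per-spot Jensen-Shannon divergence (log base 2, so JSD lies in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ProportionMatrix, SCReference, SRTDataset

__all__ = [
    "BenchmarkSpec",
    "PseudoSRT",
    "EvalReport",
    "build_benchmark_proportions",
    "sample_pseudo_spot",
    "build_pseudo_srt",
    "mse_per_celltype",
    "jsd_per_spot",
    "generate_synthetic_fixture",
]


@dataclass
class BenchmarkSpec:
    """Recipe for a pseudo-spot dataset: per-spot UMI budgets plus truth."""

    umi_totals: np.ndarray
    proportions: ProportionMatrix
    scale_divisor: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.umi_totals = np.asarray(self.umi_totals, dtype=float)
        if np.any(self.umi_totals <= 0):
            raise ValueError("UMI totals must be positive")
        if self.umi_totals.shape[0] != self.proportions.n_spots:
            raise ValueError("one UMI total per spot is required")


@dataclass
class PseudoSRT:
    """Assembled pseudo-spot matrix, before and after integer rounding."""

    counts: np.ndarray              # rounded, integer-valued
    counts_unrounded: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    provenance: list[list[str]]     # sampled reference cell ids per spot


@dataclass
class EvalReport:
    """Per-type MSE and per-spot JSD with scalar summaries."""

    mse_per_type: dict[str, float]
    jsd_per_spot: np.ndarray
    spot_ids: list[str] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, float]:
        mse = np.array(list(self.mse_per_type.values()))
        return {
            "mean_mse": float(mse.mean()),
            "median_mse": float(np.median(mse)),
            "mean_jsd": float(self.jsd_per_spot.mean()),
            "median_jsd": float(np.median(self.jsd_per_spot)),
        }


def build_benchmark_proportions(
    method_outputs: list[ProportionMatrix], n_rare: int = 2
) -> ProportionMatrix:
    """Consensus truth from several methods' estimates.

    The ``n_rare`` cell types with the smallest across-method, across-spot
    mean proportion are scored conservatively by the per-spot minimum over
    methods; every other type takes the per-spot mean.  Rows are then
    renormalized to sum to 1.
    """
    if not method_outputs:
        raise ValueError("at least one method output is required")
    ref = method_outputs[0]
    aligned = [ref] + [m.aligned_to(ref) for m in method_outputs[1:]]
    stack = np.stack([m.proportions for m in aligned])   # (methods, spots, types)
    mean_over_methods = stack.mean(axis=0)
    type_means = mean_over_methods.mean(axis=0)
    rare = set(np.argsort(type_means, kind="stable")[:n_rare].tolist())
    bench = mean_over_methods.copy()
    for j in rare:
        bench[:, j] = stack[:, :, j].min(axis=0)
    bench /= bench.sum(axis=1, keepdims=True)
    return ProportionMatrix(
        proportions=bench, spot_ids=list(ref.spot_ids), cell_types=list(ref.cell_types)
    )


def sample_pseudo_spot(
    reference: SCReference,
    umi_total: float,
    proportions: np.ndarray,
    rng: np.random.Generator,
    scale_divisor: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Draw one pseudo-spot; returns (unrounded counts, rounded, cell ids).

    ``reference`` must already be rescaled so every cell's counts sum to
    ``scale_divisor`` (see :meth:`SCReference.rescaled`); under that
    premise the pre-rounding total equals ``umi_total`` exactly, since
    sum_j n*_ij * scale_divisor * (n_ij / n*_ij) = scale_divisor * sum_j n_ij.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape[0] != reference.n_types:
        raise ValueError(
            f"proportion vector has {proportions.shape[0]} entries but the "
            f"reference has {reference.n_types} cell types: positive "
            "proportions would map to types with no reference cells"
        )
    label_idx = reference.label_indices()
    vec = np.zeros(reference.counts.shape[1])
    sampled: list[str] = []
    for j, p in enumerate(proportions):
        if p <= 0:
            continue
        pool = np.flatnonzero(label_idx == j)
        if pool.size == 0:
            raise ValueError(
                f"type {reference.cell_types[j]!r} has positive proportion "
                "but no reference cells"
            )
        n_ij = (umi_total / scale_divisor) * p
        n_star = int(np.ceil(n_ij))
        chosen = rng.choice(pool, size=n_star, replace=True)
        vec += reference.counts[chosen].sum(axis=0) * (n_ij / n_star)
        sampled.extend(reference.cell_ids[c] for c in chosen)
    return vec, np.rint(vec), sampled


def build_pseudo_srt(spec: BenchmarkSpec, reference: SCReference) -> PseudoSRT:
    """Assemble every spot of the pseudo-spot dataset (seeded, reproducible)."""
    ref = reference.rescaled(spec.scale_divisor)
    rng = np.random.default_rng(spec.seed)
    n = spec.proportions.n_spots
    unrounded = np.empty((n, ref.counts.shape[1]))
    provenance: list[list[str]] = []
    for i in range(n):
        vec, _, cells = sample_pseudo_spot(
            ref, spec.umi_totals[i], spec.proportions.proportions[i], rng,
            scale_divisor=spec.scale_divisor,
        )
        unrounded[i] = vec
        provenance.append(cells)
    return PseudoSRT(
        counts=np.rint(unrounded),
        counts_unrounded=unrounded,
        spot_ids=list(spec.proportions.spot_ids),
        gene_ids=list(ref.gene_ids),
        provenance=provenance,
    )


def mse_per_celltype(
    est: ProportionMatrix, truth: ProportionMatrix
) -> dict[str, float]:
    """Mean over spots of the squared proportion error, per cell type."""
    est = est.aligned_to(truth)
    err = (est.proportions - truth.proportions) ** 2
    return {t: float(err[:, j].mean()) for j, t in enumerate(truth.cell_types)}


def _kl_bits(p: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Row-wise KL(p || m) in bits with 0*log0 := 0."""
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = p[mask] * np.log2(p[mask] / m[mask])
    return out.sum(axis=1)


def jsd_per_spot(est: ProportionMatrix, truth: ProportionMatrix) -> np.ndarray:
    """Per-spot Jensen-Shannon divergence, log base 2 (range [0, 1]).

    JSD(X || Y) = KL(X || M)/2 + KL(Y || M)/2 with M = (X + Y)/2, applied
    row-wise to the two proportion matrices.
    """
    est = est.aligned_to(truth)
    X = est.proportions
    Y = truth.proportions
    if np.any(X < 0) or np.any(Y < 0):
        raise ValueError("proportions must be nonnegative")
    M = 0.5 * (X + Y)
    return 0.5 * _kl_bits(X, M) + 0.5 * _kl_bits(Y, M)


def evaluate(est: ProportionMatrix, truth: ProportionMatrix) -> EvalReport:
    """Bundle both metrics into one report."""
    return EvalReport(
        mse_per_type=mse_per_celltype(est, truth),
        jsd_per_spot=jsd_per_spot(est, truth),
        spot_ids=list(truth.spot_ids),
    )


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

def _region_proportions(
    xy: np.ndarray, centers: np.ndarray, K: int, sharpness: float
) -> np.ndarray:
    """Smoothly varying truth: softmax of negative distance to region centers."""
    d = np.sqrt(((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    logits = -sharpness * d
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


def generate_synthetic_fixture(
    K: int = 3,
    genes_per_type: int = 200,
    n_background_genes: int = 400,
    n_cells: int = 300,
    n_spots: int = 400,
    grid: tuple[int, int] = (20, 20),
    fold_change: float = 8.0,
    nb_dispersion: float = 2.0,
    mean_umi: float = 2400.0,
    region_sharpness: float = 0.35,
    seed: int = 0,
) -> tuple[SCReference, SRTDataset, ProportionMatrix]:
    """Generate a matched (reference, spatial dataset, truth) triple.

    The reference has K cell types, each with a block of
    ``genes_per_type`` marker genes upregulated ``fold_change``-fold, with
    negative-binomial counts.  Spots sit on a ``grid`` with smoothly
    varying true compositions organized around K spatial regions; spot
    counts are assembled with the pseudo-spot sampler at per-spot UMI
    budgets around ``mean_umi``; the RGB image colors each region
    distinctly so histology correlates with composition.
    """
    if grid[0] * grid[1] != n_spots:
        raise ValueError("grid dimensions must multiply to n_spots")
    rng = np.random.default_rng(seed)
    M = K * genes_per_type + n_background_genes
    gene_ids = [f"gene_{k:05d}" for k in range(M)]
    cell_types = [f"type_{j}" for j in range(K)]

    # per-gene base rates (lognormal spread) and marker fold-changes
    base = rng.lognormal(mean=0.0, sigma=0.6, size=M)
    rates = np.tile(base, (K, 1))
    for j in range(K):
        lo, hi = j * genes_per_type, (j + 1) * genes_per_type
        rates[j, lo:hi] *= fold_change

    labels = [cell_types[j] for j in rng.integers(0, K, size=n_cells)]
    # guarantee every type is represented
    for j in range(K):
        labels[j] = cell_types[j]
    label_idx = np.array([cell_types.index(l) for l in labels])

    # negative binomial via gamma-Poisson mixture with shape nb_dispersion
    mean_counts = rates[label_idx]
    gamma = rng.gamma(shape=nb_dispersion, scale=1.0 / nb_dispersion,
                      size=mean_counts.shape)
    counts = rng.poisson(mean_counts * gamma).astype(float)
    # no empty cells
    empty = counts.sum(axis=1) == 0
    counts[empty, 0] = 1.0
    cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]
    reference = SCReference(
        counts=counts, cell_ids=cell_ids, gene_ids=gene_ids,
        labels=labels, cell_types=cell_types,
    )

    # spot grid and smoothly varying truth around K region centers
    gx, gy = grid
    xs, ys = np.meshgrid(np.arange(gx), np.arange(gy), indexing="ij")
    xy = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    centers = np.column_stack([
        rng.uniform(0, gx - 1, size=K), rng.uniform(0, gy - 1, size=K)
    ])
    truth_p = _region_proportions(xy, centers, K, region_sharpness)
    spot_ids = [f"spot_{i:04d}" for i in range(n_spots)]
    truth = ProportionMatrix(
        proportions=truth_p, spot_ids=spot_ids, cell_types=cell_types
    )

    umi = np.maximum(rng.normal(mean_umi, mean_umi / 6, size=n_spots), 200.0)
    pseudo = build_pseudo_srt(
        BenchmarkSpec(umi_totals=umi, proportions=truth,
                      seed=int(rng.integers(0, 2**31 - 1))),
        reference,
    )

    # histology raster: color each pixel by its nearest region's palette,
    # blended by the local truth mixture, plus pixel noise
    px_per_spot = 20
    Himg, Wimg = gy * px_per_spot, gx * px_per_spot
    palette = rng.uniform(60, 220, size=(K, 3))
    rows = np.arange(Himg)[:, None] / px_per_spot
    cols = np.arange(Wimg)[None, :] / px_per_spot
    pix_xy = np.column_stack([
        np.broadcast_to(cols, (Himg, Wimg)).ravel(),
        np.broadcast_to(rows, (Himg, Wimg)).ravel(),
    ])
    mix = _region_proportions(pix_xy, centers, K, region_sharpness)
    img = (mix @ palette).reshape(Himg, Wimg, 3)
    img += rng.normal(0, 8.0, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)
    pixel_xy = (xy + 0.5) * px_per_spot   # spot centers in (x=col, y=row)

    srt = SRTDataset(
        counts=pseudo.counts, spot_ids=spot_ids, gene_ids=gene_ids,
        xy=xy, pixel_xy=pixel_xy, image=image,
    )
    return reference, srt, truth
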