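"""Gene selection and joint standardization of spatial and reference matrices.

The smoothed spot matrix and the single-cell reference are reduced to a
common highly-variable gene panel, then each matrix is log1p-transformed
and z-scored per gene independently (population convention).  Independent
z-scoring removes platform-specific scale differences before the two
matrices are stacked for the embedding step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PreprocessedPair",
    "NoVariableGenesError",
    "GeneMismatchError",
    "select_hvg",
    "intersect_and_standardize",
]


class NoVariableGenesError(ValueError):
    """Expression matrix carries no variable genes to rank."""


class GeneMismatchError(ValueError):
    """Gene identifier universes do not overlap."""


@dataclass
class PreprocessedPair:
    """Standardized spot and cell matrices over a shared gene panel."""

    srt_z: np.ndarray  # (n_spots, p)
    sc_z: np.ndarray   # (n_cells, p)
    genes: list[str]

    def __post_init__(self) -> None:
        p = len(self.genes)
        if p < 1:
            raise ValueError("at least one shared gene is required")
        if self.srt_z.shape[1] != p or self.sc_z.shape[1] != p:
            raise ValueError("gene list does not match matrix widths")


def _dispersion(X: np.ndarray) -> np.ndarray:
    """Per-gene dispersion (variance / mean) of log1p values; 0/0 -> 0."""
    logged = np.log1p(np.asarray(X, dtype=float))
    mean = logged.mean(axis=0)
    var = logged.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return disp


def select_hvg(X_star: np.ndarray, gene_ids: list[str], h: int) -> list[str]:
    """Rank genes by log1p dispersion and return the top ``h``.

    Ties (including the all-constant case) break by input gene order, which
    keeps runs reproducible.
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    X_star = np.asarray(X_star, dtype=float)
    if len(gene_ids) != X_star.shape[1]:
        raise ValueError("gene_ids length does not match matrix width")
    if not np.any(X_star != 0):
        raise NoVariableGenesError("expression matrix is identically zero")
    disp = _dispersion(X_star)
    # stable sort on negated dispersion = descending with input-order ties
    order = np.argsort(-disp, kind="stable")
    top = order[: min(h, len(gene_ids))]
    return [gene_ids[i] for i in top]


def _zscore_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column z-score (population std); returns (z, keep_mask)."""
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    # relative threshold so numerically-constant columns count as constant
    keep = std > 1e-12 * np.maximum(1.0, np.abs(mean))
    z = np.zeros_like(X)
    z[:, keep] = (X[:, keep] - mean[keep]) / std[keep]
    return z, keep


def intersect_and_standardize(
    X_star: np.ndarray,
    srt_genes: list[str],
    G: np.ndarray,
    sc_genes: list[str],
    hvg: list[str],
) -> PreprocessedPair:
    """Restrict both matrices to shared HVGs, then log1p + z-score each.

    Genes with zero within-matrix variance in either matrix (constant after
    log1p) are dropped consistently from both so no standardized column is
    degenerate.
    """
    srt_index = {g: i for i, g in enumerate(srt_genes)}
    sc_index = {g: i for i, g in enumerate(sc_genes)}
    shared = [g for g in hvg if g in srt_index and g in sc_index]
    if not shared:
        raise GeneMismatchError(
            "no highly variable genes shared between matrices; "
            f"examples spatial-side: {list(srt_index)[:3]}, "
            f"reference-side: {list(sc_index)[:3]}"
        )
    xs = np.log1p(np.asarray(X_star, dtype=float)[:, [srt_index[g] for g in shared]])
    gs = np.log1p(np.asarray(G, dtype=float)[:, [sc_index[g] for g in shared]])
    xz, keep_x = _zscore_columns(xs)
    gz, keep_g = _zscore_columns(gs)
    keep = keep_x & keep_g
    if not np.any(keep):
        raise NoVariableGenesError(
            "every shared gene is constant in at least one matrix"
        )
    genes = [g for g, k in zip(shared, keep) if k]
    # re-standardize after the drop so retained columns are exactly z-scored
    xz, _ = _zscore_columns(xs[:, keep])
    gz, _ = _zscore_columns(gs[:, keep])
    return PreprocessedPair(srt_z=xz, sc_z=gz, genes=genes)
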