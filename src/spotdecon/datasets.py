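"""In-memory containers for spatial transcriptomics and single-cell reference data.

A spatial dataset couples a spot x gene count matrix with optional spot
coordinates, image-pixel coordinates and an H&E-style RGB raster.  A
reference couples a cell x gene count matrix with one cell-type label per
cell.  Both are light dataclasses over numpy/pandas; validation happens at
construction so downstream code can assume the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SRTDataset", "SCReference", "ProportionMatrix"]


def _as_2d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class SRTDataset:
    """Spot-level expression with optional spatial / histology context.

    Parameters
    ----------
    counts : (n_spots, n_genes) array
        Nonnegative UMI counts.
    spot_ids : sequence of str
        Unique spot identifiers (barcodes).
    gene_ids : sequence of str
        Gene identifiers; duplicates are dropped first-wins by the readers.
    xy : (n_spots, 2) array, optional
        Spatial coordinates (x, y) in arbitrary units.
    pixel_xy : (n_spots, 2) array, optional
        Full-resolution image coordinates (x=column, y=row) of spot centers.
    image : (H, W, 3) array, optional
        RGB histology raster.
    """

    counts: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    xy: np.ndarray | None = None
    pixel_xy: np.ndarray | None = None
    image: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _as_2d_float(self.counts, "counts")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, m = self.counts.shape
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot_ids for {n} matrix rows")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {m} matrix columns")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids must be unique")
        if self.xy is not None:
            self.xy = _as_2d_float(self.xy, "xy")
            if self.xy.shape != (n, 2):
                raise ValueError(f"xy must have shape ({n}, 2)")
        if self.pixel_xy is not None:
            self.pixel_xy = _as_2d_float(self.pixel_xy, "pixel_xy")
            if self.pixel_xy.shape != (n, 2):
                raise ValueError(f"pixel_xy must have shape ({n}, 2)")
        if self.image is not None:
            self.image = np.asarray(self.image)
            if self.image.ndim != 3 or self.image.shape[2] != 3:
                raise ValueError("image must be an (H, W, 3) RGB raster")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def has_spatial(self) -> bool:
        return self.xy is not None

    @property
    def has_histology(self) -> bool:
        return self.image is not None and self.pixel_xy is not None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.spot_ids, columns=self.gene_ids)


@dataclass
class SCReference:
    """Annotated single-cell reference: counts plus one type label per cell."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: list[str]
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = _as_2d_float(self.counts, "counts")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("reference counts must be nonnegative and finite")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = [str(l) for l in self.labels]
        n, m = self.counts.shape
        if len(self.cell_ids) != n or len(self.labels) != n:
            raise ValueError("cell_ids and labels must match the number of rows")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {m} matrix columns")
        if not self.cell_types:
            # stable first-occurrence order
            self.cell_types = list(dict.fromkeys(self.labels))
        unknown = set(self.labels) - set(self.cell_types)
        if unknown:
            raise ValueError(f"labels not listed in cell_types: {sorted(unknown)}")
        missing = [t for t in self.cell_types if t not in set(self.labels)]
        if missing:
            raise ValueError(f"cell types with no cells: {missing}")
        if len(self.cell_types) < 2:
            raise ValueError("reference must contain at least 2 cell types")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def label_indices(self) -> np.ndarray:
        """Integer type index per cell, in ``cell_types`` order."""
        lut = {t: j for j, t in enumerate(self.cell_types)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def rescaled(self, total: float = 1000.0) -> "SCReference":
        """Copy with every cell's counts rescaled to sum to ``total``.

        Pseudo-spot construction assumes a common per-cell library size so
        that sampled cells contribute comparably to a spot's UMI budget.
        """
        sums = self.counts.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("cannot rescale cells with zero total counts")
        return SCReference(
            counts=self.counts / sums * total,
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            labels=list(self.labels),
            cell_types=list(self.cell_types),
        )


@dataclass
class ProportionMatrix:
    """Spot x cell-type proportions; every row is a probability vector."""

    proportions: np.ndarray
    spot_ids: list[str]
    cell_types: list[str]

    _ROW_TOL = 1e-6

    def __post_init__(self) -> None:
        self.proportions = _as_2d_float(self.proportions, "proportions")
        n, k = self.proportions.shape
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.cell_types = [str(t) for t in self.cell_types]
        if len(self.spot_ids) != n or len(self.cell_types) != k:
            raise ValueError("spot_ids / cell_types do not match matrix shape")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1 + self._ROW_TOL):
            raise ValueError("proportions must lie in [0, 1]")
        row_sums = self.proportions.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > self._ROW_TOL):
            worst = float(np.abs(row_sums - 1.0).max())
            raise ValueError(
                f"proportion rows must sum to 1 (worst deviation {worst:.2e})"
            )

    @property
    def n_spots(self) -> int:
        return self.proportions.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=pd.Index(self.spot_ids, name="spot_id"),
            columns=self.cell_types,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().round(6).to_csv(path, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "ProportionMatrix":
        df = pd.read_csv(path, index_col=0)
        P = df.to_numpy(dtype=float)
        sums = P.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-4):
            raise ValueError("rows of a proportion CSV must sum to ~1")
        P = P / sums[:, None]   # absorb decimal-rounding drift exactly
        return cls(
            proportions=P,
            spot_ids=[str(i) for i in df.index],
            cell_types=[str(c) for c in df.columns],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ProportionMatrix":
        return cls(
            proportions=df.to_numpy(dtype=float),
            spot_ids=[str(i) for i in df.index],
            cell_types=[str(c) for c in df.columns],
        )

    def aligned_to(self, other: "ProportionMatrix") -> "ProportionMatrix":
        """Reorder rows/columns to match ``other``; error on mismatched universes."""
        if set(self.spot_ids) != set(other.spot_ids):
            raise ValueError("spot universes differ")
        if set(self.cell_types) != set(other.cell_types):
            raise ValueError("cell-type universes differ")
        df = self.to_dataframe().loc[other.spot_ids, other.cell_types]
        return ProportionMatrix.from_dataframe(df)
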