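"""Readers and writers for the supported on-disk layouts.

Two spatial layouts are supported:

* ``visium`` — a directory with ``matrix.mtx`` (genes x spots, Matrix
  Market), ``barcodes.tsv``, ``features.tsv``, a
  ``tissue_positions.csv`` in the 10x dialect (barcode, in_tissue,
  array_row, array_col, pxl_row_in_fullres, pxl_col_in_fullres) and an
  optional ``image.png``/``.tif``/``.jpg``;
* ``csv`` — ``counts.csv`` (spots x genes) plus optional
  ``positions.csv`` with columns spot_id, x, y[, pixel_x, pixel_y] and an
  optional image file.

The reference is a counts table (cells x genes, CSV or Matrix Market with
identifier sidecars) plus a two-column labels CSV (cell_id, label).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .datasets import SCReference, SRTDataset

logger = logging.getLogger(__name__)

__all__ = ["read_srt", "read_reference", "write_srt", "write_reference"]

_IMAGE_NAMES = ("image.png", "image.tif", "image.tiff", "image.jpg", "image.jpeg")
_VISIUM_POSITION_COLS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


def _dedup_first_wins(ids: list[str], matrix: np.ndarray, axis: int):
    """Drop duplicate identifiers, keeping the first occurrence."""
    seen: set[str] = set()
    keep = []
    for i, g in enumerate(ids):
        if g not in seen:
            seen.add(g)
            keep.append(i)
    if len(keep) != len(ids):
        logger.warning("dropped %d duplicate identifiers", len(ids) - len(keep))
        matrix = np.take(matrix, keep, axis=axis)
        ids = [ids[i] for i in keep]
    return ids, matrix


def _raw_header(csv_path: Path) -> list[str]:
    """Column names from the raw header line (duplicates preserved)."""
    import csv as _csv

    with open(csv_path) as fh:
        header = next(_csv.reader(fh))
    return [str(g) for g in header[1:]]


def _find_image(path: Path) -> np.ndarray | None:
    for name in _IMAGE_NAMES:
        f = path / name
        if f.exists():
            img = np.asarray(Image.open(f).convert("RGB"))
            return img
    return None


def read_srt(path: str | Path, layout: str = "csv") -> SRTDataset:
    """Read a spatial dataset from ``path`` in the given layout."""
    path = Path(path)
    if layout == "visium":
        return _read_visium(path)
    if layout == "csv":
        return _read_csv_layout(path)
    raise ValueError(f"unknown layout {layout!r}; expected 'visium' or 'csv'")


def _read_visium(path: Path) -> SRTDataset:
    mtx = path / "matrix.mtx"
    barcodes_f = path / "barcodes.tsv"
    features_f = path / "features.tsv"
    for f in (mtx, barcodes_f, features_f):
        if not f.exists():
            raise FileNotFoundError(f"mandatory file missing: {f}")
    counts = np.asarray(mmread(mtx).todense(), dtype=float).T  # -> spots x genes
    if counts.size == 0:
        raise ValueError(f"empty expression matrix in {mtx}")
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(features_f, sep="\t", header=None)[0].astype(str).tolist()
    if len(barcodes) != counts.shape[0] or len(features) != counts.shape[1]:
        raise ValueError(
            f"matrix is {counts.shape[0]} spots x {counts.shape[1]} genes but "
            f"{len(barcodes)} barcodes / {len(features)} features were given"
        )
    features, counts = _dedup_first_wins(features, counts, axis=1)

    xy = pixel_xy = None
    pos_f = path / "tissue_positions.csv"
    if pos_f.exists():
        pos = pd.read_csv(pos_f, header=None, names=_VISIUM_POSITION_COLS)
        if pos["barcode"].astype(str).isin(["barcode"]).any():  # had a header row
            pos = pd.read_csv(pos_f)
            pos.columns = _VISIUM_POSITION_COLS[: len(pos.columns)]
        pos["barcode"] = pos["barcode"].astype(str)
        pos = pos.set_index("barcode")
        missing = [b for b in barcodes if b not in pos.index]
        extra = pos.index.difference(barcodes)
        if missing:
            warnings.warn(
                f"{len(missing)} of {len(barcodes)} barcodes in the matrix "
                f"have no position (first offenders: {missing[:3]}); they are "
                "retained but excluded from smoothing", stacklevel=2
            )
        if len(extra):
            warnings.warn(
                f"positions file lists {len(extra)} barcodes not in the "
                "matrix; taking the intersection", stacklevel=2
            )
        pos = pos.reindex(barcodes)   # unmatched barcodes become NaN rows
        xy = pos[["array_col", "array_row"]].to_numpy(dtype=float)
        pixel_xy = pos[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(float)

    return SRTDataset(
        counts=counts, spot_ids=barcodes, gene_ids=features,
        xy=xy, pixel_xy=pixel_xy, image=_find_image(path),
    )


def _read_csv_layout(path: Path) -> SRTDataset:
    counts_f = path / "counts.csv"
    if not counts_f.exists():
        raise FileNotFoundError(f"mandatory file missing: {counts_f}")
    df = pd.read_csv(counts_f, index_col=0)
    if df.empty:
        raise ValueError(f"empty expression matrix in {counts_f}")
    # pandas mangles duplicate column names; recover them from the raw header
    genes, counts = _dedup_first_wins(
        _raw_header(counts_f), df.to_numpy(dtype=float), axis=1
    )
    spot_ids = [str(i) for i in df.index]

    xy = pixel_xy = None
    pos_f = path / "positions.csv"
    if pos_f.exists():
        pos = pd.read_csv(pos_f)
        pos["spot_id"] = pos["spot_id"].astype(str)
        pos = pos.set_index("spot_id")
        missing = [s for s in spot_ids if s not in pos.index]
        if missing:
            warnings.warn(
                f"{len(missing)} of {len(spot_ids)} spots have no position "
                f"(first offenders: {missing[:3]}); they are retained but "
                "excluded from smoothing", stacklevel=2
            )
        if len(pos.index.difference(spot_ids)):
            warnings.warn(
                "positions file lists spots not in the matrix; "
                "taking the intersection", stacklevel=2
            )
        pos = pos.reindex(spot_ids)   # unmatched spots become NaN rows
        xy = pos[["x", "y"]].to_numpy(dtype=float)
        if {"pixel_x", "pixel_y"}.issubset(pos.columns):
            pixel_xy = pos[["pixel_x", "pixel_y"]].to_numpy(dtype=float)

    return SRTDataset(
        counts=counts, spot_ids=spot_ids, gene_ids=genes,
        xy=xy, pixel_xy=pixel_xy, image=_find_image(path),
    )


def write_srt(srt: SRTDataset, path: str | Path, layout: str = "csv") -> None:
    """Write a spatial dataset in the chosen layout (round-trips read_srt)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if layout == "csv":
        srt.to_dataframe().to_csv(path / "counts.csv")
        if srt.xy is not None:
            pos = pd.DataFrame({
                "spot_id": srt.spot_ids,
                "x": srt.xy[:, 0], "y": srt.xy[:, 1],
            })
            if srt.pixel_xy is not None:
                pos["pixel_x"] = srt.pixel_xy[:, 0]
                pos["pixel_y"] = srt.pixel_xy[:, 1]
            pos.to_csv(path / "positions.csv", index=False)
    elif layout == "visium":
        mmwrite(str(path / "matrix.mtx"), csr_matrix(srt.counts.T))
        pd.Series(srt.spot_ids).to_csv(path / "barcodes.tsv", index=False, header=False)
        pd.Series(srt.gene_ids).to_csv(path / "features.tsv", index=False, header=False)
        if srt.xy is not None and srt.pixel_xy is not None:
            pd.DataFrame({
                "barcode": srt.spot_ids,
                "in_tissue": 1,
                "array_row": srt.xy[:, 1],
                "array_col": srt.xy[:, 0],
                "pxl_row_in_fullres": srt.pixel_xy[:, 1],
                "pxl_col_in_fullres": srt.pixel_xy[:, 0],
            }).to_csv(path / "tissue_positions.csv", index=False, header=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if srt.image is not None:
        Image.fromarray(srt.image.astype(np.uint8)).save(path / "image.png")


def read_reference(counts_path: str | Path, labels_path: str | Path) -> SCReference:
    """Read reference counts (cells x genes CSV) and per-cell labels."""
    counts_path, labels_path = Path(counts_path), Path(labels_path)
    if not counts_path.exists():
        raise FileNotFoundError(f"mandatory file missing: {counts_path}")
    if not labels_path.exists():
        raise FileNotFoundError(f"mandatory file missing: {labels_path}")
    df = pd.read_csv(counts_path, index_col=0)
    if df.empty:
        raise ValueError(f"empty reference matrix in {counts_path}")
    genes, counts = _dedup_first_wins(
        _raw_header(counts_path), df.to_numpy(dtype=float), axis=1
    )
    cell_ids = [str(i) for i in df.index]
    lab = pd.read_csv(labels_path)
    lab.columns = [c.lower() for c in lab.columns]
    if "cell_id" not in lab.columns or "label" not in lab.columns:
        raise ValueError("labels file must have columns cell_id, label")
    lab["cell_id"] = lab["cell_id"].astype(str)
    lab = lab.set_index("cell_id")["label"]
    unlabeled = [c for c in cell_ids if c not in lab.index]
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} cells have no label "
            f"(first offenders: {unlabeled[:3]})"
        )
    return SCReference(
        counts=counts, cell_ids=cell_ids, gene_ids=genes,
        labels=[str(l) for l in lab.loc[cell_ids]],
    )


def write_reference(ref: SCReference, counts_path: str | Path,
                    labels_path: str | Path) -> None:
    pd.DataFrame(ref.counts, index=ref.cell_ids, columns=ref.gene_ids).to_csv(
        counts_path
    )
    pd.DataFrame({"cell_id": ref.cell_ids, "label": ref.labels}).to_csv(
        labels_path, index=False
    )
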