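"""Histology-aware spot adjacency and local smoothing of spot expression.

Spots that are physically close and look alike under H&E staining tend to
share cell-type composition, so the noisy per-spot expression can be
denoised by a weighted aggregate over neighbors.  The neighborhood weight
between spots u and v is a Gaussian kernel

    a(u, v) = exp(-d(u, v)^2 / (2 l^2))

on the Euclidean distance in (x, y, z*) space, where z* is a scaled scalar
summary of the RGB content of the image window around each spot and l is a
characteristic length scale.  l is not user-tuned: it is calibrated so that
the mean total off-diagonal row weight of the adjacency matrix A hits a
prespecified value (0.5 by default, i.e. neighbors jointly get half the
weight of the spot itself).  Smoothing is then the matrix product A @ X.

All variances and standard deviations here use the population (divide by N)
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "HistologyUnavailableError",
    "DegenerateHistologyError",
    "CalibrationError",
    "HistologyCoordinates",
    "AdjacencyMatrix",
    "compute_histology_coordinate",
    "combine_channels",
    "scale_histology",
    "pairwise_distance",
    "adjacency_from_distance",
    "calibrate_length_scale",
    "smooth_expression",
]


class HistologyUnavailableError(ValueError):
    """Image or pixel coordinates missing; caller should fall back to 2-D."""


class DegenerateHistologyError(ValueError):
    """All RGB channel variances are zero; histology carries no information."""


class CalibrationError(RuntimeError):
    """Length-scale calibration could not reach the target mean weight."""

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


@dataclass
class HistologyCoordinates:
    """Raw and scaled per-spot histology coordinates."""

    z: np.ndarray
    z_star: np.ndarray | None
    s: float
    channel_vars: tuple[float, float, float]


@dataclass
class AdjacencyMatrix:
    """Spot similarity weights with the calibrated length scale."""

    A: np.ndarray
    l: float
    mean_neighbor_weight: float

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not np.allclose(A, A.T):
            raise ValueError("A must be symmetric")
        if not np.allclose(np.diag(A), 1.0):
            raise ValueError("A must have unit diagonal")
        # mathematically entries lie in (0, 1]; exp underflow can produce
        # exact zeros for very distant pairs, which is accepted
        if np.any(A < 0) or np.any(A > 1 + 1e-12):
            raise ValueError("entries of A must lie in [0, 1]")
        self.A = A


def _pop_var(x: np.ndarray) -> float:
    return float(np.var(np.asarray(x, dtype=float)))  # numpy default ddof=0


def compute_histology_coordinate(
    image: np.ndarray | None,
    pixel_xy: np.ndarray | None,
    window: int = 50,
    pixel_order: str = "xy",
) -> HistologyCoordinates:
    """Summarize the image window around each spot as one scalar per spot.

    For spot v, (r_v, g_v, b_v) are the per-channel means over the
    ``window`` x ``window`` pixel square centered on the spot's pixel
    coordinates (clamped at image borders, partial windows averaged over
    the available pixels).  With V_r, V_g, V_b the population variances of
    those per-spot means across spots, the histology coordinate is the
    variance-weighted channel average

        z_v = (r_v V_r + g_v V_g + b_v V_b) / (V_r + V_g + V_b),

    so the channel that varies most across the tissue dominates.

    Parameters
    ----------
    pixel_order : {"xy", "rc"}
        Whether ``pixel_xy`` columns are (x=col, y=row) or (row, col).
    """
    if image is None or pixel_xy is None:
        raise HistologyUnavailableError(
            "histology unavailable: image and pixel coordinates are both required"
        )
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB raster")
    if window < 1:
        raise ValueError("window must be >= 1")
    px = np.asarray(pixel_xy, dtype=float)
    if pixel_order == "rc":
        rows, cols = px[:, 0], px[:, 1]
    elif pixel_order == "xy":
        cols, rows = px[:, 0], px[:, 1]
    else:
        raise ValueError("pixel_order must be 'xy' or 'rc'")
    H, W = img.shape[:2]
    bad = ~(np.isfinite(rows) & np.isfinite(cols)
            & (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W))
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} spot centers fall outside the image bounds"
        )

    half = window // 2
    n = px.shape[0]
    means = np.empty((n, 3))
    for v in range(n):
        r0 = max(int(round(rows[v])) - half, 0)
        r1 = min(int(round(rows[v])) + (window - half), H)
        c0 = max(int(round(cols[v])) - half, 0)
        c1 = min(int(round(cols[v])) + (window - half), W)
        means[v] = img[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0)

    return combine_channels(means)


def combine_channels(means: np.ndarray) -> HistologyCoordinates:
    """Variance-weighted average of per-spot RGB means into one coordinate.

    z_v = (r_v V_r + g_v V_g + b_v V_b) / (V_r + V_g + V_b), where V_c is
    the population variance of channel c's per-spot means across spots.
    """
    means = np.asarray(means, dtype=float)
    if means.ndim != 2 or means.shape[1] != 3:
        raise ValueError("means must be an (n_spots, 3) array")
    channel_vars = tuple(float(np.var(means[:, c])) for c in range(3))
    total = sum(channel_vars)
    if total == 0:
        raise DegenerateHistologyError(
            "all RGB channel variances are zero across spots"
        )
    weights = np.asarray(channel_vars) / total
    z = means @ weights
    return HistologyCoordinates(z=z, z_star=None, s=1.0, channel_vars=channel_vars)


def scale_histology(z: np.ndarray, xy: np.ndarray, s: float) -> np.ndarray:
    """Rescale histology coordinates to be commensurate with (x, y).

    z*_v = ((z_v - mean(z)) / std(z)) * max(std(x), std(y)) * s, so with
    s = 1 the histology axis has the same population variance as the wider
    spatial axis.  Constant z (std 0) degrades gracefully to all zeros.
    """
    z = np.asarray(z, dtype=float)
    xy = np.asarray(xy, dtype=float)
    if z.shape[0] < 2:
        raise ValueError("at least 2 spots are required to scale histology")
    if s < 0:
        raise ValueError("scale parameter s must be nonnegative")
    sigma_z = np.std(z)
    # relative threshold: a numerically-constant z is treated as constant
    if s == 0 or sigma_z <= 1e-12 * max(1.0, abs(float(z.mean()))):
        return np.zeros_like(z)
    sigma_x = np.std(xy[:, 0])
    sigma_y = np.std(xy[:, 1])
    return (z - z.mean()) / sigma_z * max(sigma_x, sigma_y) * s


def pairwise_distance(xy: np.ndarray, z_star: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distances over (x, y, z*) or (x, y) if no histology."""
    xy = np.asarray(xy, dtype=float)
    if z_star is not None:
        coords = np.column_stack([xy, np.asarray(z_star, dtype=float)])
    else:
        coords = xy
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return squareform(pdist(coords))


def adjacency_from_distance(D: np.ndarray, l: float) -> AdjacencyMatrix:
    """Gaussian-kernel adjacency a(u,v) = exp(-d(u,v)^2 / (2 l^2))."""
    if l <= 0:
        raise ValueError("length scale l must be positive")
    D = np.asarray(D, dtype=float)
    A = np.exp(-(D ** 2) / (2.0 * l ** 2))
    np.fill_diagonal(A, 1.0)
    n = A.shape[0]
    mean_w = float((A.sum() - n) / n)
    return AdjacencyMatrix(A=A, l=float(l), mean_neighbor_weight=mean_w)


def _mean_offdiag_weight(D: np.ndarray, l: float) -> float:
    A = np.exp(-(D ** 2) / (2.0 * l ** 2))
    n = D.shape[0]
    return float((A.sum() - np.trace(A)) / n)


def calibrate_length_scale(
    D: np.ndarray,
    target_mean_weight: float = 0.5,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> float:
    """Find l such that the mean off-diagonal row sum of A hits the target.

    The mean neighbor weight is monotone increasing in l, so bisection on
    log(l) is exact.  The initial bracket spans [1e-3, 1e3] times the
    median nearest-neighbor distance.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to calibrate")
    if not (0 < target_mean_weight < n - 1):
        raise ValueError(
            f"target mean weight must be in (0, {n - 1}) for {n} spots"
        )
    offdiag = D + np.diag(np.full(n, np.inf))
    med_nn = float(np.median(offdiag.min(axis=1)))
    if med_nn == 0:
        # coincident spots: fall back to median positive distance
        pos = D[D > 0]
        if pos.size == 0:
            raise CalibrationError("all spots coincide; adjacency is all-ones", float(n - 1))
        med_nn = float(np.median(pos))

    lo, hi = np.log(1e-3 * med_nn), np.log(1e3 * med_nn)
    f_lo = _mean_offdiag_weight(D, np.exp(lo))
    f_hi = _mean_offdiag_weight(D, np.exp(hi))
    if not (f_lo <= target_mean_weight <= f_hi):
        achieved = f_hi if target_mean_weight > f_hi else f_lo
        raise CalibrationError(
            f"target {target_mean_weight} not bracketed: achievable range "
            f"[{f_lo:.4g}, {f_hi:.4g}] within the search bracket",
            achieved,
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _mean_offdiag_weight(D, np.exp(mid))
        if abs(f_mid - target_mean_weight) <= tol:
            return float(np.exp(mid))
        if f_mid < target_mean_weight:
            lo = mid
        else:
            hi = mid
    achieved = _mean_offdiag_weight(D, np.exp(0.5 * (lo + hi)))
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations "
        f"(achieved mean weight {achieved:.4g})",
        achieved,
    )


def smooth_expression(A: AdjacencyMatrix | np.ndarray, X: np.ndarray) -> np.ndarray:
    """Locally smooth expression: X* = A @ X (self-weight 1 on the diagonal)."""
    mat = A.A if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    if mat.shape[1] != X.shape[0]:
        raise ValueError(
            f"adjacency ({mat.shape[0]}x{mat.shape[1]}) and expression "
            f"({X.shape[0]}x{X.shape[1]}) shapes do not align"
        )
    return mat @ X


def build_adjacency(
    xy: np.ndarray,
    image: np.ndarray | None = None,
    pixel_xy: np.ndarray | None = None,
    s: float = 1.0,
    target_mean_weight: float = 0.5,
    window: int = 50,
    pixel_order: str = "xy",
    tol: float = 1e-3,
) -> AdjacencyMatrix:
    """Convenience: histology coordinate -> scaling -> calibration -> A.

    Falls back to pure 2-D distances when histology is unavailable or
    degenerate, or when ``s`` is 0.
    """
    xy = np.asarray(xy, dtype=float)
    placed = np.all(np.isfinite(xy), axis=1)
    if not np.all(placed):
        # spots without coordinates stay in the dataset but receive an
        # identity row: their expression is not smoothed
        logger.warning(
            "%d spots lack coordinates and are excluded from smoothing",
            int(np.sum(~placed)),
        )
    xy_p = xy[placed]
    px_p = pixel_xy[placed] if pixel_xy is not None else None
    z_star = None
    if s > 0 and image is not None and px_p is not None:
        try:
            hist = compute_histology_coordinate(
                image, px_p, window=window, pixel_order=pixel_order
            )
            z_star = scale_histology(hist.z, xy_p, s)
        except (HistologyUnavailableError, DegenerateHistologyError) as exc:
            logger.warning("histology fallback to 2-D distances: %s", exc)
            z_star = None
    D = pairwise_distance(xy_p, z_star)
    l = calibrate_length_scale(D, target_mean_weight=target_mean_weight, tol=tol)
    sub = adjacency_from_distance(D, l)
    if np.all(placed):
        return sub
    n = xy.shape[0]
    A = np.eye(n)
    idx = np.flatnonzero(placed)
    A[np.ix_(idx, idx)] = sub.A
    return AdjacencyMatrix(A=A, l=sub.l, mean_neighbor_weight=sub.mean_neighbor_weight)
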