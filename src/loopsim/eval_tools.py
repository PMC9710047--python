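"""Contact-matrix comparison: DoG transform, discretization, stripe scoring.

Matrices are handled in their banded form: a ``[band_rows, nbins]`` image
whose row ``d`` holds the pixels at diagonal distance ``d``. Column ``i`` of
that image is exactly the vector of pixels starting on the matrix diagonal
at bin ``i`` and extending along matrix row ``i``; the anti-diagonal through
column ``j`` gives matrix column ``j``. Stripes generated by loop extrusion
always start at the diagonal, so the last non-zero pixel of such a vector
marks the stripe end; two matrices are compared by whether their stripe
ends agree, row by row and column by column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "TransformConfig",
    "dog_transform",
    "discretize",
    "stripe_end",
    "row_vectors",
    "column_vector",
    "score_matrices",
    "pixel_accuracy",
    "diagonal_correlation",
]


@dataclass(frozen=True)
class TransformConfig:
    """DoG + discretization settings.

    ``sigma1``/``sigma2`` are the less/more blurry Gaussian widths in pixels;
    the discretization threshold is in matrix-value units (reference data is
    typically thresholded at 1.5, simulated data at 0.75).
    """

    sigma1: float = 1.0
    sigma2: float = 1.6
    threshold: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.sigma1 < self.sigma2):
            raise ValueError("need 0 < sigma1 < sigma2")


def dog_transform(
    band: np.ndarray, sigma1: float = 1.0, sigma2: float = 1.6
) -> np.ndarray:
    """Difference-of-Gaussians band-pass of the band image.

    Blur at ``sigma1`` minus blur at ``sigma2`` (reflect padding at the band
    edges); highlights stripes and dots, and maps any constant matrix to 0.
    """
    if not (0 < sigma1 < sigma2):
        raise ValueError("need 0 < sigma1 < sigma2")
    band = np.asarray(band, dtype=float)
    lo = ndimage.gaussian_filter(band, sigma1, mode="reflect")
    hi = ndimage.gaussian_filter(band, sigma2, mode="reflect")
    return lo - hi


def discretize(band: np.ndarray, threshold: float) -> np.ndarray:
    """Step function: values >= threshold map to 1, all others to 0."""
    if not np.isfinite(threshold):
        if threshold == -np.inf:
            return np.ones_like(band, dtype=np.uint8)
        if threshold == np.inf:
            return np.zeros_like(band, dtype=np.uint8)
        raise ValueError("threshold must not be NaN")
    return (np.asarray(band) >= threshold).astype(np.uint8)


def stripe_end(vector: np.ndarray) -> int | None:
    """Index of the last non-zero pixel in a diagonal-anchored vector, or None."""
    nz = np.flatnonzero(np.asarray(vector))
    return int(nz[-1]) if nz.size else None


def row_vectors(band: np.ndarray) -> np.ndarray:
    """All matrix-row vectors at once: column ``i`` starts at diagonal bin i."""
    return np.asarray(band)


def column_vector(band: np.ndarray, j: int) -> np.ndarray:
    """Matrix column ``j`` as a diagonal-anchored vector (bounded by the band)."""
    band = np.asarray(band)
    band_rows = band.shape[0]
    length = min(band_rows, j + 1)
    d = np.arange(length)
    return band[d, j - d]


def _last_nonzero_per_column(mat: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Vectorized stripe end per column; -1 where the column is all zero."""
    nz = (mat != 0) & valid
    rows = np.arange(mat.shape[0])[:, None]
    return np.where(nz, rows, -1).max(axis=0)


def _stripe_ends(band: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(row-wise, column-wise) stripe-end indices per bin; -1 = no stripe."""
    band = np.asarray(band)
    band_rows, nbins = band.shape
    d = np.arange(band_rows)[:, None]
    i = np.arange(nbins)[None, :]
    row_valid = i + d < nbins  # row i extends right: needs bin i+d
    col_valid = i - d >= 0  # column j extends up: needs bin j-d
    row_ends = _last_nonzero_per_column(band, row_valid)
    # column j pixels live at [d, j-d]: shift each band row right by d
    shifted = np.zeros_like(band)
    for dd in range(band_rows):
        shifted[dd, dd:] = band[dd, : nbins - dd]
    col_ends = _last_nonzero_per_column(shifted, col_valid)
    return row_ends, col_ends


def score_matrices(
    reference: np.ndarray, target: np.ndarray, mode: str = "dissimilarity"
) -> tuple[np.ndarray, np.ndarray]:
    """Stripe-end agreement between two binary band matrices.

    For every bin, the stripe ends of the corresponding matrix row (and
    column) are compared; both-empty counts as agreement. Returns per-bin
    (row_scores, col_scores): 1 = mismatch in ``"dissimilarity"`` mode,
    1 = match in ``"similarity"`` mode.
    """
    reference = np.asarray(reference)
    target = np.asarray(target)
    if reference.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {target.shape}"
        )
    if mode not in ("similarity", "dissimilarity"):
        raise ValueError(f"unknown mode {mode!r}")
    ref_rows, ref_cols = _stripe_ends(reference)
    tgt_rows, tgt_cols = _stripe_ends(target)
    row_match = ref_rows == tgt_rows
    col_match = ref_cols == tgt_cols
    if mode == "similarity":
        return row_match.astype(np.uint8), col_match.astype(np.uint8)
    return (~row_match).astype(np.uint8), (~col_match).astype(np.uint8)


def pixel_accuracy(
    reference: np.ndarray,
    target: np.ndarray,
    barrier_bins: np.ndarray,
    window_bins: int,
) -> float:
    """Fraction of identically classified pixels near barriers.

    The window is the union (deduplicated) of subdiagonal stretches of
    ``window_bins`` bins centered on each barrier bin; all valid band pixels
    whose diagonal position falls inside are compared.
    """
    reference = np.asarray(reference)
    target = np.asarray(target)
    if reference.shape != target.shape:
        raise ValueError("shape mismatch")
    barrier_bins = np.asarray(barrier_bins, dtype=int)
    if barrier_bins.size == 0:
        raise ValueError("barrier list must be non-empty")
    band_rows, nbins = reference.shape
    half = window_bins // 2
    cols = np.zeros(nbins, dtype=bool)
    for b in barrier_bins:
        cols[max(0, b - half) : min(nbins, b + half + 1)] = True
    d = np.arange(band_rows)[:, None]
    i = np.arange(nbins)[None, :]
    valid = (i + d < nbins) & cols[None, :]
    total = int(valid.sum())
    agree = int(((reference == target) & valid).sum())
    return agree / total


def diagonal_correlation(
    reference: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Pearson correlation per off-diagonal distance (NaN where degenerate)."""
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if reference.shape != target.shape:
        raise ValueError("shape mismatch")
    band_rows, nbins = reference.shape
    out = np.full(band_rows, np.nan)
    for d in range(band_rows):
        n = nbins - d
        if n < 2:
            continue
        x = reference[d, :n]
        y = target[d, :n]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        out[d] = stats.pearsonr(x, y).statistic
    return out
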