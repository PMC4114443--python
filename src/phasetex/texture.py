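"""Gray-level co-occurrence texture statistics of projection-image ROIs.

The analysis protocol: sample 20 random 50x50-pixel regions of interest
inside an analysis mask of a 256-gray projective image, quantize each ROI
to K gray levels (K = 16 by default; linear binning of the 8-bit range),
accumulate a normalized co-occurrence matrix C over a set of pixel offsets,
and compute nine scalar texture statistics:

    T1 angular second moment   sum C_ij^2
    T2 inertia (contrast)      sum (i-j)^2 C_ij
    T3 inverse difference mom. sum C_ij / (1 + (i-j)^2)
    T4 entropy                 -sum C_ij log2 C_ij
    T5 correlation             (sum i j C_ij - mu_x mu_y) / (sigma_x sigma_y)
    T6 sum average             sum k c_{x+y}(k)
    T7 difference average      sum k c_{x-y}(k)
    T8 sum entropy             -sum c_{x+y}(k) log2 c_{x+y}(k)
    T9 difference entropy      -sum c_{x-y}(k) log2 c_{x-y}(k)

with c_{x+y}(k) = sum_{i+j=k} C_ij and c_{x-y}(k) = sum_{|i-j|=k} C_ij.
Logarithms are base 2 (entropies in bits) and 0*log 0 := 0.  A constant
ROI makes sigma_x sigma_y = 0; correlation is then reported as 0 with a
logged warning so random ROI sampling cannot abort a run.

Offsets are explicit ``(drow, dcol)`` displacements; the default is
distance 1 pooled over the four standard directions with a symmetric
matrix, the rotation-robust Haralick practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, PlacementError
from .imaging import ProjectionImage

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9")
FEATURE_LABELS = {
    "T1": "angular second moment", "T2": "inertia", "T3": "inverse difference moment",
    "T4": "entropy", "T5": "correlation", "T6": "sum average",
    "T7": "difference average", "T8": "sum entropy", "T9": "difference entropy",
}


def standard_offsets(distance: int = 1) -> list[tuple[int, int]]:
    """The four standard co-occurrence directions at a given distance."""
    d = int(distance)
    if d < 1:
        raise DomainError("offset distance must be >= 1")
    return [(0, d), (-d, d), (-d, 0), (-d, -d)]


@dataclass(frozen=True)
class ROI:
    """A square region of interest cut from a source image (0-based corner).

    The span is half-open: rows [row, row+size), cols [col, col+size).
    """

    pixels: np.ndarray
    image_id: str
    row: int
    col: int

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class GLCMatrix:
    """A K x K normalized gray-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (self.levels, self.levels):
            raise DomainError("GLCM shape must be (levels, levels)")
        if np.any(m < 0) or not np.isclose(m.sum(), 1.0):
            raise DomainError("GLCM must be nonnegative and normalized to sum 1")


def _window_counts(mask: np.ndarray, size: int) -> np.ndarray:
    """Number of True pixels in every size x size window (integral image, exact)."""
    m = mask.astype(np.int64)
    S = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
    S[1:, 1:] = m.cumsum(0).cumsum(1)
    return (S[size:, size:] - S[:-size, size:] - S[size:, :-size] + S[:-size, :-size])


def sample_rois(image: ProjectionImage | np.ndarray, mask: np.ndarray,
                n: int = 20, size: int = 50, seed: int | None = None,
                image_id: str = "image") -> list[ROI]:
    """Draw ``n`` ROIs uniformly at random among mask-contained placements.

    Top-left corners are sampled without replacement (overlap between ROIs is
    allowed, duplicate corners are not); every ROI lies fully inside both the
    image bounds and the mask.  The draw is reproducible from ``seed``.
    """
    data = image.data if isinstance(image, ProjectionImage) else np.asarray(image)
    if isinstance(image, ProjectionImage):
        image_id = image.meta.get("stage", image_id)
    if data.ndim != 2:
        raise DomainError("ROI sampling needs a 2-D image")
    if mask.shape != data.shape:
        raise DomainError("mask must match the image shape")
    if size < 2 or size > min(data.shape):
        raise DomainError(f"ROI size {size} incompatible with image shape {data.shape}")
    counts = _window_counts(mask.astype(bool), size)
    corners = np.argwhere(counts == size * size)
    if len(corners) < n:
        raise PlacementError(
            f"mask admits only {len(corners)} ROI placements of size {size}; "
            f"{n} requested (short by {n - len(corners)})")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(corners), size=n, replace=False)
    return [ROI(pixels=data[r:r + size, c:c + size].copy(),
                image_id=image_id, row=int(r), col=int(c))
            for r, c in corners[picks]]


def quantize_levels(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of the full 8-bit range [0, 255] into ``levels`` bins."""
    if levels < 2:
        raise DomainError("need at least 2 gray levels")
    q = (np.asarray(pixels).astype(np.int64) * levels) // 256
    if np.any(q < 0) or np.any(q >= levels):
        raise DomainError("pixel values must lie in the 8-bit range [0, 255]")
    return q


def compute_glcm(roi: ROI | np.ndarray, levels: int = 16,
                 offsets: Sequence[tuple[int, int]] | None = None,
                 symmetric: bool = True, prequantized: bool = False) -> GLCMatrix:
    """Normalized co-occurrence matrix of a ROI, pooled over offsets.

    Counts co-occurring quantized gray-level pairs ``(q[r, c], q[r+dr, c+dc])``
    for each offset, adds the transpose if ``symmetric``, pools offsets and
    normalizes to sum 1.  ``prequantized=True`` treats the input as already
    holding levels in [0, levels).
    """
    pixels = roi.pixels if isinstance(roi, ROI) else np.asarray(roi)
    if pixels.ndim != 2 or pixels.size == 0:
        raise DomainError("ROI must be a nonempty 2-D array")
    if offsets is None:
        offsets = standard_offsets(1)
    offsets = tuple((int(dr), int(dc)) for dr, dc in offsets)
    if not offsets:
        raise DomainError("offset list must be nonempty")
    if prequantized:
        q = np.asarray(pixels, dtype=np.int64)
        if np.any(q < 0) or np.any(q >= levels):
            raise DomainError("prequantized ROI has levels outside [0, levels)")
    else:
        q = quantize_levels(pixels, levels)

    counts = np.zeros((levels, levels), dtype=np.int64)
    H, W = q.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        if r0 >= r1 or c0 >= c1:
            continue  # offset larger than the ROI: contributes no pairs
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        counts += np.bincount((a * levels + b).ravel(),
                              minlength=levels * levels).reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DomainError("no co-occurring pairs; ROI smaller than every offset")
    return GLCMatrix(counts / total, levels, offsets, symmetric)


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_features(glcm: GLCMatrix) -> np.ndarray:
    """The nine texture statistics T1..T9 of a normalized GLCM (see module doc)."""
    C = glcm.matrix
    K = glcm.levels
    i = np.arange(K)[:, None]
    j = np.arange(K)[None, :]
    diff2 = (i - j) ** 2

    t1 = float((C**2).sum())
    t2 = float((diff2 * C).sum())
    t3 = float((C / (1.0 + diff2)).sum())
    t4 = _entropy_bits(C.ravel())

    cx = C.sum(axis=1)
    cy = C.sum(axis=0)
    k_ax = np.arange(K, dtype=float)
    mu_x = float((k_ax * cx).sum())
    mu_y = float((k_ax * cy).sum())
    sig_x = float(np.sqrt(((k_ax - mu_x) ** 2 * cx).sum()))
    sig_y = float(np.sqrt(((k_ax - mu_y) ** 2 * cy).sum()))
    denom = sig_x * sig_y
    if denom == 0.0:
        logger.warning("degenerate ROI (zero marginal variance); correlation set to 0")
        t5 = 0.0
    else:
        t5 = float(((i * j * C).sum() - mu_x * mu_y) / denom)

    c_sum = np.bincount((i + j).ravel(), weights=C.ravel(), minlength=2 * K - 1)
    c_diff = np.bincount(np.abs(i - j).ravel(), weights=C.ravel(), minlength=K)
    ks = np.arange(c_sum.size, dtype=float)
    kd = np.arange(c_diff.size, dtype=float)
    t6 = float((ks * c_sum).sum())
    t7 = float((kd * c_diff).sum())
    t8 = _entropy_bits(c_sum)
    t9 = _entropy_bits(c_diff)

    return np.array([t1, t2, t3, t4, t5, t6, t7, t8, t9])


def feature_matrix(rois: Sequence[ROI], levels: int = 16,
                   offsets: Sequence[tuple[int, int]] | None = None,
                   symmetric: bool = True) -> np.ndarray:
    """Per-ROI feature rows stacked into the n x 9 texture data matrix T."""
    if not rois:
        raise DomainError("feature_matrix needs at least one ROI")
    rows = []
    for idx, roi in enumerate(rois):
        try:
            rows.append(haralick_features(
                compute_glcm(roi, levels=levels, offsets=offsets, symmetric=symmetric)))
        except Exception as exc:
            raise DomainError(f"feature extraction failed for ROI index {idx} "
                              f"(corner {roi.row},{roi.col}): {exc}") from exc
    return np.vstack(rows)
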