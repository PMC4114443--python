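"""Correlation-matrix PCA of ROI texture features and the (F1+F2) discriminant.

For one specimen image the pipeline holds a 20 x 9 texture data matrix T
(rows = ROIs, columns = the nine GLCM statistics).  The analysis chain is:

1. standardize each column (mean 0, unit sample standard deviation, n-1);
2. form the 9 x 9 Pearson correlation matrix R across ROI rows;
3. eigendecompose R; sort eigenvalues descending; fix each eigenvector's
   sign (see below);
4. contribution rates CR_i = lambda_i / sum(lambda) and their cumulative
   sums CCR_i; keep the smallest m with CCR_m > 80%;
5. per-ROI component scores F_i = l_i . t (t a feature row);
6. the region discriminant: mean over ROIs of (F1 + F2), labelled normal
   when it exceeds a threshold (8.5 in the original study) and cancer
   otherwise (the boundary goes to the disease class, favoring sensitivity).

Sign convention.  An eigenvector's sign is mathematically arbitrary but
flips F_i and hence the meaning of any fixed threshold.  The default here
anchors the sign on the loadings of the two marginal-appearance features in
priority order: angular second moment first (T1, the texture-uniformity
statistic — uniform texture is the hallmark of normal tissue), sum average
second (T6, the overall gray level).  Whichever of the two has a solid
loading (|l| > 0.2) on a component fixes its sign to be nonnegative, so
higher scores mean more normal-like/brighter — the polarity a "normal iff
score > threshold" rule requires.  The plain nonnegative-loading-sum
convention is available as an option; with GLCM features it tends to orient
the first component along texture contrast and thereby invert the
discriminant.  Either way the absolute threshold is tied to the scale of
the data it was derived on and is a configuration parameter, not a constant
of nature.

Score scale.  Eigenvectors always come from the correlation matrix of the
standardized features.  Scores can be taken on the standardized matrix Z or
on the raw matrix T.  Per-specimen standardized scores are identically
mean-zero (Z's columns are centered), so a mean-score discriminant carries
information only in raw mode — the pipeline's default.  Both paths exist.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateFeatureError, DomainError


class RegionLabel(str, enum.Enum):
    NORMAL = "normal"
    CANCER = "cancer"


@dataclass
class PCAResult:
    """Eigenstructure of a correlation matrix, sorted by descending eigenvalue."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns l_i, unit norm, sign-fixed
    cr: np.ndarray | None = None
    ccr: np.ndarray | None = None
    n_components: int | None = None
    scores: np.ndarray | None = None


@dataclass
class DiscriminantResult:
    """The per-region (F1+F2) summary and the thresholded call."""

    score_mean: float
    score_sd: float
    label: RegionLabel
    threshold: float


def standardize(T: np.ndarray) -> np.ndarray:
    """Center each column and scale to unit sample standard deviation (n-1)."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 2:
        raise DomainError("feature matrix must be 2-D")
    sd = T.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateFeatureError(
            f"feature column(s) {bad.tolist()} have zero variance and cannot be standardized")
    return (T - T.mean(axis=0)) / sd


def correlation_matrix(T: np.ndarray) -> np.ndarray:
    """Pearson correlation of feature columns across ROI rows (Eq-level: R_ij)."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] < 3:
        raise DomainError("correlation matrix needs a 2-D matrix with >= 3 rows")
    Z = standardize(T)
    R = (Z.T @ Z) / (Z.shape[0] - 1)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R


#: Minimum |loading| for an anchor feature to pin a component's sign.
_ANCHOR_MIN_LOADING = 0.2


def _fix_sign(v: np.ndarray, convention: str,
              anchors: tuple[int, ...]) -> np.ndarray:
    tol = 1e-12
    if convention == "anchor":
        keys = [v[a] if abs(v[a]) > _ANCHOR_MIN_LOADING else 0.0 for a in anchors]
        keys += [v.sum(), v[np.argmax(np.abs(v))]]
    elif convention == "loading_sum":
        keys = [v.sum(), v[np.argmax(np.abs(v))]]
    else:
        raise DomainError(f"unknown sign convention {convention!r}")
    for key in keys:
        if abs(key) > tol:
            return v if key > 0 else -v
    return v


def eigendecompose(R: np.ndarray, sign_convention: str = "anchor",
                   anchors: tuple[int, ...] = (0, 5)) -> PCAResult:
    """Eigenpairs of a symmetric correlation matrix, descending, sign-fixed."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise DomainError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise DomainError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    anchors = tuple(a for a in anchors if a < R.shape[0]) or (0,)
    for i in range(vecs.shape[1]):
        vecs[:, i] = _fix_sign(vecs[:, i], sign_convention, anchors)
    return PCAResult(eigenvalues=vals, eigenvectors=vecs)


def contribution_rates(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CR_i = lambda_i / sum(lambda); CCR_i = cumulative sum of CR."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-10):
        raise DomainError("eigenvalues must be nonnegative")
    lam = np.clip(lam, 0.0, None)
    if np.any(np.diff(lam) > 1e-12):
        raise DomainError("eigenvalues must be sorted in descending order")
    total = lam.sum()
    if total == 0:
        raise DomainError("all eigenvalues are zero")
    cr = lam / total
    return cr, np.cumsum(cr)


def select_components(ccr: np.ndarray, threshold: float = 0.80) -> int:
    """Smallest m whose cumulative contribution rate exceeds the threshold."""
    if not 0 < threshold < 1:
        raise DomainError("CCR threshold must lie in (0, 1)")
    ccr = np.asarray(ccr, dtype=float)
    above = np.flatnonzero(ccr > threshold)
    if above.size == 0:
        return int(ccr.size)
    return int(above[0]) + 1


def principal_scores(Z: np.ndarray, eigenvectors: np.ndarray, m: int) -> np.ndarray:
    """Per-row component scores F_i = l_i . row, for the leading m components."""
    Z = np.asarray(Z, dtype=float)
    eigenvectors = np.asarray(eigenvectors, dtype=float)
    if not 1 <= m <= eigenvectors.shape[1]:
        raise DomainError(f"m must be in [1, {eigenvectors.shape[1]}], got {m}")
    if Z.shape[1] != eigenvectors.shape[0]:
        raise DomainError("feature dimension does not match eigenvector length")
    return Z @ eigenvectors[:, :m]


def classify_region(scores: np.ndarray, threshold: float = 8.5) -> DiscriminantResult:
    """Mean-of-(F1+F2) discriminant: normal iff the mean strictly exceeds the threshold."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise DomainError("discriminant needs at least 2 principal components")
    s = scores[:, 0] + scores[:, 1]
    mean = float(s.mean())
    sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
    label = RegionLabel.NORMAL if mean > threshold else RegionLabel.CANCER
    return DiscriminantResult(mean, sd, label, float(threshold))


def pooled_component_sums(feature_matrices: dict, ccr_threshold: float = 0.80,
                          sign_convention: str = "anchor") -> dict:
    """Cross-specimen (F1+F2) comparison in one pooled component basis.

    Per-specimen PCA yields a different eigenbasis for every specimen, so
    per-specimen scores are mutually incomparable — comparing their means
    across stages is only meaningful in a common basis.  This pools all
    specimens' feature rows, standardizes with the pooled statistics, takes
    the eigenbasis of the pooled correlation matrix and returns, per
    specimen key, the mean and standard deviation of the per-ROI (F1+F2)
    in that shared basis, plus the pooled eigenstructure.
    """
    keys = list(feature_matrices)
    if not keys:
        raise DomainError("pooled comparison needs at least one feature matrix")
    pooled = np.vstack([np.asarray(feature_matrices[k], dtype=float) for k in keys])
    Z = standardize(pooled)
    R = correlation_matrix(pooled)
    pca = eigendecompose(R, sign_convention=sign_convention)
    cr, ccr = contribution_rates(pca.eigenvalues)
    m = max(select_components(ccr, ccr_threshold), 2)
    scores = principal_scores(Z, pca.eigenvectors, m)
    sums = scores[:, 0] + scores[:, 1]
    out = {"eigenvalues": pca.eigenvalues.tolist(), "ccr": ccr.tolist(),
           "n_components": m, "per_specimen": {}}
    start = 0
    for k in keys:
        n = np.asarray(feature_matrices[k]).shape[0]
        chunk = sums[start:start + n]
        out["per_specimen"][str(k)] = {
            "sum_mean": float(chunk.mean()),
            "sum_sd": float(chunk.std(ddof=1)) if n > 1 else 0.0,
            "n_rois": int(n)}
        start += n
    return out


def pca_report(T: np.ndarray, ccr_threshold: float = 0.80,
               score_threshold: float = 8.5, score_mode: str = "raw",
               sign_convention: str = "anchor") -> dict:
    """Run the full per-specimen chain and return a Table-style summary dict."""
    if score_mode not in ("raw", "standardized"):
        raise DomainError(f"unknown score_mode {score_mode!r}")
    T = np.asarray(T, dtype=float)
    Z = standardize(T)
    R = correlation_matrix(T)
    pca = eigendecompose(R, sign_convention=sign_convention)
    cr, ccr = contribution_rates(pca.eigenvalues)
    m = select_components(ccr, ccr_threshold)
    basis = Z if score_mode == "standardized" else T
    n_score = max(m, 2)  # the discriminant always uses F1 and F2
    scores = principal_scores(basis, pca.eigenvectors, n_score)
    disc = classify_region(scores, score_threshold)
    f1, f2 = scores[:, 0], scores[:, 1]
    return {
        "eigenvalues": pca.eigenvalues.tolist(),
        "cr": cr.tolist(),
        "ccr": ccr.tolist(),
        "n_components": m,
        "ccr_selected": float(ccr[m - 1]),
        "score_mode": score_mode,
        "sign_convention": sign_convention,
        "F1_mean": float(f1.mean()), "F1_sd": float(f1.std(ddof=1)),
        "F2_mean": float(f2.mean()), "F2_sd": float(f2.std(ddof=1)),
        "sum_mean": disc.score_mean, "sum_sd": disc.score_sd,
        "threshold": disc.threshold,
        "label": disc.label.value,
    }
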