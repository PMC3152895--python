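"""Grey-level co-occurrence matrix at d=1, theta=0 and its 11 features.

The matrix counts horizontally adjacent ordered grey-level pairs
(Im(x, y), Im(x, y+1)), is symmetrized by adding its transpose, and is
normalized to a joint probability.  The 11 classical statistics
(angular second moment through difference entropy) are computed on it;
entropies use the natural logarithm and 0*log(0) is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from histotex.preprocessing import NG, NormalizedROI

COM_FEATURE_NAMES = (
    "Angular Second Moment",
    "Contrast",
    "Correlation",
    "Entropy",
    "Sum of Squares",
    "Inverse Difference Moment",
    "Sum Average",
    "Sum Variance",
    "Sum Entropy",
    "Difference Variance",
    "Difference Entropy",
)


@dataclass
class COMatrix:
    """Symmetric joint probability matrix of horizontal grey-level pairs."""

    p: np.ndarray  # (ng, ng); index k holds grey level k+1
    ng: int = NG
    d: int = 1
    theta: int = 0


def _roi_pixels(roi) -> np.ndarray:
    if isinstance(roi, NormalizedROI):
        return np.asarray(roi.pixels), roi.ng
    return np.asarray(roi), NG


def compute_com(roi, ng: int | None = None) -> COMatrix:
    """Build the symmetrized co-occurrence matrix of a normalized ROI."""
    pixels, roi_ng = _roi_pixels(roi)
    if ng is None:
        ng = roi_ng
    pixels = np.atleast_2d(pixels).astype(np.int64)
    if pixels.shape[1] < 2:
        raise ValueError("ROI needs at least 2 columns for horizontal pairs")
    if pixels.min() < 1 or pixels.max() > ng:
        raise ValueError(f"grey values must lie in [1, {ng}]")
    left = pixels[:, :-1] - 1
    right = pixels[:, 1:] - 1
    flat = left.ravel() * ng + right.ravel()
    counts = np.bincount(flat, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts = counts + counts.T
    return COMatrix(p=counts / counts.sum(), ng=ng)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def com_features(m: COMatrix) -> dict[str, float]:
    """The 11 co-occurrence statistics, keyed by their conventional names.

    Grey levels are the actual values 1..ng; marginals p_{x+y} and
    p_{x-y} are indexed by the sum (2..2 ng) and absolute difference
    (0..ng-1) of the pair.  Correlation of a single-level matrix
    (sigma_x = 0) is defined as 0.
    """
    p = m.p
    ng = m.ng
    levels = np.arange(1, ng + 1, dtype=np.float64)
    i = levels[:, None]
    j = levels[None, :]

    px = p.sum(axis=1)
    mu_x = float(levels @ px)
    sigma_x2 = float(((levels - mu_x) ** 2) @ px)
    # symmetric matrix: mu_y = mu_x, sigma_y = sigma_x

    # marginal of i+j (index k-2 holds sum k) and |i-j| (index n)
    idx_sum = (np.arange(ng)[:, None] + np.arange(ng)[None, :]).ravel()
    p_sum = np.bincount(idx_sum, weights=p.ravel(), minlength=2 * ng - 1)
    sums = np.arange(2, 2 * ng + 1, dtype=np.float64)
    idx_diff = np.abs(np.arange(ng)[:, None] - np.arange(ng)[None, :]).ravel()
    p_diff = np.bincount(idx_diff, weights=p.ravel(), minlength=ng)
    diffs = np.arange(ng, dtype=np.float64)

    asm = float((p**2).sum())
    contrast = float((diffs**2) @ p_diff)
    if sigma_x2 > 0:
        correlation = float(((i * j * p).sum() - mu_x * mu_x) / sigma_x2)
    else:
        correlation = 0.0
    entropy = _entropy(p)
    sum_of_squares = float((((i - mu_x) ** 2) * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    sum_average = float(sums @ p_sum)
    sum_variance = float(((sums - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)
    mu_d = float(diffs @ p_diff)
    difference_variance = float(((diffs - mu_d) ** 2) @ p_diff)
    difference_entropy = _entropy(p_diff)

    values = (
        asm,
        contrast,
        correlation,
        entropy,
        sum_of_squares,
        idm,
        sum_average,
        sum_variance,
        sum_entropy,
        difference_variance,
        difference_entropy,
    )
    return dict(zip(COM_FEATURE_NAMES, values))
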