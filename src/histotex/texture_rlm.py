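"""Run-length matrices in four directions and their five statistics.

A run is a maximal sequence of consecutive equal-valued pixels along a
scan direction (horizontal, vertical or either diagonal).  The matrix
r(i, l) counts runs of grey level i and length l; diagonal directions
scan every diagonal line of the ROI, so corner pixels contribute runs of
length 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from histotex.preprocessing import NG, NormalizedROI

#: directions in degrees, with their table-label spellings
RLM_DIRECTIONS = (0, 45, 90, 135)
RLM_DIRECTION_LABELS = {0: "Horizontal", 45: "45°", 90: "Vertical", 135: "135°"}

RLM_FEATURE_NAMES = (
    "Short Run Emphasis",
    "Long Run Emphasis",
    "Greylevel Non-uniformity",
    "Run Length Non-uniformity",
    "Fraction",
)


@dataclass
class RLMatrix:
    """Run counts indexed by grey level (1..ng) and run length (1..l_max)."""

    r: np.ndarray  # (ng, l_max) integer counts
    theta: int
    n_runs: int
    n_pixels: int
    ng: int = NG


def _direction_lines(pixels: np.ndarray, theta: int) -> list[np.ndarray]:
    rows, cols = pixels.shape
    if theta == 0:
        return list(pixels)
    if theta == 90:
        return list(pixels.T)
    if theta == 45:
        flipped = np.fliplr(pixels)
        return [flipped.diagonal(k) for k in range(-(rows - 1), cols)]
    if theta == 135:
        return [pixels.diagonal(k) for k in range(-(rows - 1), cols)]
    raise ValueError(f"direction must be one of {RLM_DIRECTIONS}, got {theta}")


def compute_rlm(roi, theta: int) -> RLMatrix:
    """Count every maximal run along direction ``theta`` (degrees)."""
    if isinstance(roi, NormalizedROI):
        pixels, ng = np.asarray(roi.pixels), roi.ng
    else:
        pixels, ng = np.asarray(roi), NG
    pixels = np.atleast_2d(pixels).astype(np.int64)
    if pixels.min() < 1 or pixels.max() > ng:
        raise ValueError(f"grey values must lie in [1, {ng}]")
    lines = _direction_lines(pixels, theta)

    # concatenate all scan lines with a -1 sentinel so one RLE pass suffices
    sentinel = np.array([-1], dtype=np.int64)
    parts: list[np.ndarray] = []
    for line in lines:
        parts.append(np.asarray(line, dtype=np.int64))
        parts.append(sentinel)
    arr = np.concatenate(parts[:-1]) if parts else np.empty(0, dtype=np.int64)

    change = np.flatnonzero(np.diff(arr) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [arr.size]))
    values = arr[starts]
    lengths = ends - starts
    keep = values > 0
    values, lengths = values[keep], lengths[keep]

    l_max = max(len(line) for line in lines)
    r = np.zeros((ng, l_max), dtype=np.int64)
    np.add.at(r, (values - 1, lengths - 1), 1)
    return RLMatrix(r=r, theta=theta, n_runs=int(len(values)), n_pixels=int(pixels.size), ng=ng)


def rlm_features(m: RLMatrix) -> dict[str, float]:
    """SRE, LRE, grey-level / run-length non-uniformity and run fraction."""
    if m.n_runs < 1:
        raise ValueError("run-length matrix holds no runs")
    r = m.r.astype(np.float64)
    lengths = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    n = float(m.n_runs)
    by_length = r.sum(axis=0)
    by_level = r.sum(axis=1)
    values = (
        float((by_length / lengths**2).sum() / n),
        float((by_length * lengths**2).sum() / n),
        float((by_level**2).sum() / n),
        float((by_length**2).sum() / n),
        n / float(m.n_pixels),
    )
    return dict(zip(RLM_FEATURE_NAMES, values))


def rlm_features_all_directions(roi) -> dict[str, float]:
    """The 20 direction-prefixed run-length features of one ROI."""
    out: dict[str, float] = {}
    for theta in RLM_DIRECTIONS:
        label = RLM_DIRECTION_LABELS[theta]
        feats = rlm_features(compute_rlm(roi, theta))
        for name, value in feats.items():
            out[f"{label} {name}"] = value
    return out
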