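"""Separable orthonormal Haar decomposition and per-scale energies.

At each level the image is filtered along rows and columns with the
orthonormal Haar pair (sum and difference over 2-pixel blocks, divided
by sqrt 2), producing an approximation LL and three detail subbands LH,
HL, HH.  The per-scale energy E_n is the mean squared detail coefficient
over the three subbands at level n.  Odd dimensions are truncated (last
row/column dropped) before filtering, which avoids injecting artificial
edge energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from histotex.preprocessing import NormalizedROI

_SQRT2 = np.sqrt(2.0)

#: deepest scale ever used, matching the feature tables E_1..E_5
MAX_SCALE = 5

#: smallest ROI side accepted for decomposition
MIN_SIDE = 8


@dataclass
class WaveletEnergies:
    """Map of scale n -> mean squared detail energy E_n."""

    E: dict[int, float]
    n_max: int
    wavelet: str = "haar"

    def feature_dict(self) -> dict[str, float]:
        return {f"E_{n}": self.E[n] for n in sorted(self.E)}


def _haar_step(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One separable Haar level: returns (LL, LH, HL, HH)."""
    rows, cols = a.shape
    a = a[: rows - rows % 2, : cols - cols % 2]
    lo_r = (a[:, 0::2] + a[:, 1::2]) / _SQRT2
    hi_r = (a[:, 0::2] - a[:, 1::2]) / _SQRT2
    ll = (lo_r[0::2] + lo_r[1::2]) / _SQRT2
    lh = (lo_r[0::2] - lo_r[1::2]) / _SQRT2
    hl = (hi_r[0::2] + hi_r[1::2]) / _SQRT2
    hh = (hi_r[0::2] - hi_r[1::2]) / _SQRT2
    return ll, lh, hl, hh


def haar_pyramid(pixels, n_levels: int):
    """Full decomposition: (approximation, [(LH, HL, HH) per level])."""
    a = np.asarray(pixels, dtype=np.float64)
    details = []
    for _ in range(n_levels):
        a, lh, hl, hh = _haar_step(a)
        details.append((lh, hl, hh))
    return a, details


def max_levels(rows: int, cols: int) -> int:
    """Deepest scale permitted for an ROI: floor(log2(min side)) - 1, <= 5."""
    return min(MAX_SCALE, int(np.floor(np.log2(min(rows, cols)))) - 1)


def wavelet_energies(roi, n_max: int | None = None) -> WaveletEnergies:
    """Per-scale detail energies E_1..E_{n_max} of a normalized ROI.

    E_n sums the squared coefficients of the three detail subbands at
    level n and divides by the number of coefficients summed, so scales
    are comparable.
    """
    pixels = roi.pixels if isinstance(roi, NormalizedROI) else roi
    a = np.asarray(pixels, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D ROI, got shape {a.shape}")
    rows, cols = a.shape
    if rows < MIN_SIDE or cols < MIN_SIDE:
        raise ValueError(f"ROI {rows}x{cols} smaller than {MIN_SIDE}x{MIN_SIDE}")
    limit = max_levels(rows, cols)
    if n_max is None:
        n_max = limit
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n_max = min(n_max, limit)

    _, details = haar_pyramid(a, n_max)
    energies = {}
    for n, (lh, hl, hh) in enumerate(details, start=1):
        count = lh.size + hl.size + hh.size
        energies[n] = float(((lh**2).sum() + (hl**2).sum() + (hh**2).sum()) / count)
    return WaveletEnergies(E=energies, n_max=n_max)
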