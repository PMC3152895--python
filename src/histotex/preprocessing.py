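"""Grey-level normalization of ROIs before texture computation.

Each single-channel ROI is clipped to mu +/- 3 sigma of its own grey
values and the clipped range mapped linearly onto integers 1..128
(7 bits).  This removes the dependency on the ROI's brightness and
contrast: any positive affine intensity change yields the same output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from histotex._util import round_half_up

#: number of grey levels after quantization ("7 bits")
NG = 128


@dataclass
class NormalizedROI:
    """Quantized single-channel ROI with values in 1..NG."""

    pixels: np.ndarray  # integer array in [1, NG]
    channel: str = ""
    roi_id: str = ""
    ng: int = NG


def normalize_roi(pixels, channel: str = "", roi_id: str = "") -> NormalizedROI:
    """Clip an ROI to mu +/- 3 sigma and quantize to integers 1..128.

    sigma is the population standard deviation of the ROI's own pixels.
    A constant ROI (sigma = 0) maps every pixel to the mid level 64.
    Rounding is half-up; results are clamped to [1, 128].
    """
    values = np.asarray(pixels, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty ROI")
    if values.size < 2:
        raise ValueError("ROI must have at least 2 pixels")
    mu = values.mean()
    sigma = values.std()
    if sigma == 0:
        out = np.full(values.shape, NG // 2, dtype=np.int64)
        return NormalizedROI(pixels=out, channel=channel, roi_id=roi_id)
    lo = mu - 3.0 * sigma
    hi = mu + 3.0 * sigma
    clipped = np.clip(values, lo, hi)
    scaled = 1.0 + (clipped - lo) * ((NG - 1) / (hi - lo))
    out = np.clip(round_half_up(scaled), 1, NG).astype(np.int64)
    return NormalizedROI(pixels=out, channel=channel, roi_id=roi_id)
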