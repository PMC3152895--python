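"""Conversions from RGB into the three analysis spaces.

Every channel is eventually treated as an independent grey-scale layer:
grey (luminance), R/G/B (copied as-is) and H/S/I.  H is an angle in
degrees [0, 360); S and I live in [0, 1]; all other channels in [0, 255].
``channel_to_byte`` maps any channel linearly onto [0, 255] so the
downstream normalization sees commensurate 8-bit-like inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from histotex._util import round_half_up

#: ITU-R BT.601 luminance weights, the most common grey projection.
DEFAULT_GREY_WEIGHTS = (0.299, 0.587, 0.114)

#: value ranges per channel tag
CHANNEL_RANGES = {
    "grey": (0.0, 255.0),
    "R": (0.0, 255.0),
    "G": (0.0, 255.0),
    "B": (0.0, 255.0),
    "H": (0.0, 360.0),
    "S": (0.0, 1.0),
    "I": (0.0, 1.0),
}


@dataclass
class ChannelImage:
    """A single scalar-valued layer extracted from an RGB image."""

    pixels: np.ndarray  # (rows, columns)
    channel: str  # one of CHANNEL_RANGES keys

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_RANGES:
            raise ValueError(f"unknown channel tag {self.channel!r}")

    @property
    def value_range(self) -> tuple[float, float]:
        return CHANNEL_RANGES[self.channel]


def _pixels(image) -> np.ndarray:
    px = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected rows x columns x 3 array, got shape {px.shape}")
    return px


def rgb_to_grey(image, weights=DEFAULT_GREY_WEIGHTS) -> ChannelImage:
    """Project RGB onto luminance: Y = wR*R + wG*G + wB*B, rounded to int."""
    px = _pixels(image).astype(np.float64)
    w = np.asarray(weights, dtype=np.float64)
    grey = px @ w
    grey = np.clip(round_half_up(grey), 0, 255).astype(np.int64)
    return ChannelImage(pixels=grey, channel="grey")


def split_rgb(image) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Return the R, G and B layers, values copied unmodified."""
    px = _pixels(image)
    return tuple(
        ChannelImage(pixels=px[:, :, k].astype(np.int64), channel=tag)
        for k, tag in enumerate("RGB")
    )


def rgb_to_hsi(image) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Convert to hue (degrees), saturation and intensity.

    With r, g, b the channels scaled to [0, 1]:

        I = (r + g + b) / 3
        S = 1 - 3 min(r, g, b) / (r + g + b)     (0 for black pixels)
        H = theta if b <= g else 360 - theta, with
        theta = arccos( ((r-g) + (r-b)) / 2 / sqrt((r-g)^2 + (r-b)(g-b)) )

    Achromatic pixels (S = 0) get H = 0 by convention.
    """
    px = _pixels(image).astype(np.float64) / 255.0
    r, g, b = px[:, :, 0], px[:, :, 1], px[:, :, 2]

    total = r + g + b
    intensity = total / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(den > 0, num / den, 1.0)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    hue = np.where(b <= g, theta, 360.0 - theta)
    hue = np.where(saturation == 0, 0.0, hue)
    hue = np.where(hue >= 360.0, hue - 360.0, hue)

    return (
        ChannelImage(pixels=hue, channel="H"),
        ChannelImage(pixels=saturation, channel="S"),
        ChannelImage(pixels=intensity, channel="I"),
    )


def channel_to_byte(channel: ChannelImage) -> np.ndarray:
    """Map a channel linearly onto integer [0, 255].

    grey/R/G/B pass through; H is scaled from [0, 360) and S, I from
    [0, 1].  This makes all seven layers commensurate before the per-ROI
    grey-level normalization.
    """
    lo, hi = channel.value_range
    scaled = (np.asarray(channel.pixels, dtype=np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(round_half_up(scaled), 0, 255).astype(np.int64)
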