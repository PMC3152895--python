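"""Raster image I/O, resolution degradation and ROI partitioning.

Images are 24-bit RGB rasters (BMP or PNG).  Each image is optionally
degraded to half or quarter resolution by block averaging and then split
into four equal non-overlapping regions of interest on a 2x2 grid after
trimming a configurable border margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from histotex._util import round_half_up

#: factor -> resolution tag
RESOLUTION_TAGS = {1: "full", 2: "half", 4: "quarter"}

#: minimum ROI side length accepted by the texture engines
MIN_ROI_SIDE = 16


class ImageFormatError(ValueError):
    """Raised when a file does not decode to a 3-channel 8-bit raster."""


@dataclass
class RGBImage:
    """A 3-channel 8-bit image plus acquisition metadata."""

    pixels: np.ndarray  # (rows, columns, 3) uint8
    source_id: str = ""
    label: str | None = None  # "C" or "F"
    resolution: str = "full"  # "full" | "half" | "quarter"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ImageFormatError(
                f"expected rows x columns x 3 pixel array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ImageFormatError("channel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def columns(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ROI:
    """One of the four sub-regions of a parent image."""

    pixels: np.ndarray  # (r, c) or (r, c, 3)
    parent_id: str = ""
    position: int = 0  # quadrant index, row-major in {0, 1, 2, 3}
    label: str | None = None

    @property
    def roi_id(self) -> str:
        return f"{self.parent_id}/roi{self.position}"


def load_image(path: str | Path, label: str | None = None) -> RGBImage:
    """Read a BMP or PNG file into an :class:`RGBImage`.

    The raster must be 3-channel with 8 bits per channel; anything else
    raises :class:`ImageFormatError` naming the offending property.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            pixels = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise ImageFormatError(f"cannot decode {path}: {exc}") from exc
    if mode != "RGB":
        raise ImageFormatError(
            f"{path}: expected 3-channel 8-bit RGB raster, got mode {mode!r}"
        )
    return RGBImage(pixels=pixels, source_id=path.stem, label=label)


def save_image(image: RGBImage, path: str | Path) -> None:
    """Write an :class:`RGBImage` as BMP or PNG (chosen by extension)."""
    Image.fromarray(image.pixels, mode="RGB").save(Path(path))


def reduce_resolution(image: RGBImage, factor: int) -> RGBImage:
    """Degrade resolution by block-mean averaging of factor x factor tiles.

    Each output pixel is the rounded mean of its source block, per channel,
    which emulates optical resolution loss without aliasing.  ``factor``
    must be one of 1, 2, 4 and must divide both image dimensions.
    """
    if factor not in RESOLUTION_TAGS:
        raise ValueError(f"factor must be one of {sorted(RESOLUTION_TAGS)}, got {factor}")
    rows, cols = image.rows, image.columns
    if rows % factor or cols % factor:
        raise ValueError(
            f"image dimensions {rows}x{cols} not divisible by factor {factor}"
        )
    if factor == 1:
        return RGBImage(
            pixels=image.pixels.copy(),
            source_id=image.source_id,
            label=image.label,
            resolution="full",
        )
    blocks = image.pixels.astype(np.float64).reshape(
        rows // factor, factor, cols // factor, factor, 3
    )
    means = blocks.mean(axis=(1, 3))
    return RGBImage(
        pixels=round_half_up(means).astype(np.uint8),
        source_id=image.source_id,
        label=image.label,
        resolution=RESOLUTION_TAGS[factor],
    )


def extract_rois(image: RGBImage, margin: float = 0.05) -> list[ROI]:
    """Split an image into 4 equal non-overlapping ROIs on a 2x2 grid.

    A ``margin`` fraction (of each dimension) is first trimmed from every
    border to avoid boundary artifacts; odd leftover rows/columns are
    dropped from the far edge so that the four ROIs are exactly equal.
    """
    if not 0 <= margin <= 0.2:
        raise ValueError(f"margin must be in [0, 0.2], got {margin}")
    rows, cols = image.rows, image.columns
    m_r = int(rows * margin)
    m_c = int(cols * margin)
    half_r = (rows - 2 * m_r) // 2
    half_c = (cols - 2 * m_c) // 2
    if half_r < MIN_ROI_SIDE or half_c < MIN_ROI_SIDE:
        raise ValueError(
            f"image {rows}x{cols} with margin {margin} too small for four "
            f">= {MIN_ROI_SIDE}x{MIN_ROI_SIDE} ROIs"
        )
    rois = []
    for position in range(4):
        qr, qc = divmod(position, 2)
        r0 = m_r + qr * half_r
        c0 = m_c + qc * half_c
        rois.append(
            ROI(
                pixels=image.pixels[r0 : r0 + half_r, c0 : c0 + half_c].copy(),
                parent_id=image.source_id,
                position=position,
                label=image.label,
            )
        )
    return rois
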