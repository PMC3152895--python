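"""Synthetic trichrome-like liver micrographs for end-to-end testing.

Both classes share the same generative process — correlated pinkish
cytoplasm noise plus dark nuclei — and the fibrosis class additionally
receives green-dominant curvilinear collagen strands rendered as
random-walk curves of configurable count, width and waviness.  Every
image is reproducible from its own seed; dataset seeds derive from the
master seed as ``master_seed + image_index``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, ellipse

from histotex.image_io import RGBImage, save_image


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mimic the study's image format."""

    rows: int = 512
    columns: int = 680
    n_control: int = 5
    n_fibrosis: int = 7
    # hepatocyte cytoplasm: pinkish stationary correlated noise
    background_rgb: tuple[float, float, float] = (150.0, 120.0, 135.0)
    # per-channel noise sd: red and blue stain uptake varies more than green
    background_noise_sd: tuple[float, float, float] = (24.0, 12.0, 24.0)
    background_blur: float = 1.5  # correlation length, pixels
    # nuclei: small dark blue-violet ellipses
    n_nuclei: int = 160
    nucleus_radius: tuple[float, float] = (2.0, 5.0)
    nucleus_rgb: tuple[float, float, float] = (70.0, 60.0, 110.0)
    # collagen: green-dominant wavy strands, fibrosis class only
    collagen_strands: int = 20
    strand_width: float = 4.0
    strand_waviness: float = 0.25  # sd of per-step heading change, radians
    # green-dominant, with red/blue pulled down so the strands nearly
    # vanish in the luminance projection but stand out in G
    collagen_rgb: tuple[float, float, float] = (105.0, 170.0, 90.0)
    collagen_alpha: float = 0.8
    master_seed: int = 0

    def __post_init__(self) -> None:
        for palette in (self.background_rgb, self.nucleus_rgb, self.collagen_rgb):
            if not all(0 <= v <= 255 for v in palette):
                raise ValueError(f"palette values must lie in [0, 255]: {palette}")
        if self.collagen_strands < 0:
            raise ValueError("collagen strand count must be >= 0")


def _strand_mask(rng: np.random.Generator, rows: int, cols: int, config: SyntheticConfig) -> np.ndarray:
    """Binary canvas of random-walk strands, softened at the edges."""
    mask = np.zeros((rows, cols), dtype=np.float64)
    radius = max(config.strand_width / 2.0, 1.0)
    for _ in range(config.collagen_strands):
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        heading = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.integers(250, 600))
        step = 2.0
        for _ in range(n_steps):
            heading += rng.normal(0.0, config.strand_waviness)
            r += step * np.sin(heading)
            c += step * np.cos(heading)
            if not (0 <= r < rows and 0 <= c < cols):
                break
            rr, cc = disk((r, c), radius, shape=(rows, cols))
            mask[rr, cc] = 1.0
    return np.clip(gaussian_filter(mask, sigma=1.0), 0.0, 1.0)


def generate_image(label: str, config: SyntheticConfig, seed: int) -> RGBImage:
    """Render one labeled synthetic micrograph, bit-reproducible per seed."""
    if label not in ("C", "F"):
        raise ValueError(f"label must be 'C' or 'F', got {label!r}")
    rng = np.random.default_rng(seed)
    rows, cols = config.rows, config.columns

    img = np.empty((rows, cols, 3), dtype=np.float64)
    noise = rng.normal(0.0, 1.0, size=(rows, cols, 3))
    for k in range(3):
        img[:, :, k] = config.background_rgb[k] + gaussian_filter(
            noise[:, :, k] * config.background_noise_sd[k], sigma=config.background_blur
        )

    for _ in range(config.n_nuclei):
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        r_rad = rng.uniform(*config.nucleus_radius)
        c_rad = rng.uniform(*config.nucleus_radius)
        angle = rng.uniform(0, np.pi)
        rr, cc = ellipse(r, c, r_rad, c_rad, shape=(rows, cols), rotation=angle)
        jitter = rng.normal(0.0, 5.0, size=3)
        img[rr, cc] = np.clip(np.asarray(config.nucleus_rgb) + jitter, 0, 255)

    if label == "F" and config.collagen_strands > 0:
        mask = _strand_mask(rng, rows, cols, config)
        alpha = config.collagen_alpha * mask[:, :, None]
        # collagen carries the same correlated noise as the cytoplasm so the
        # strands differ from background mainly in the green channel's mean,
        # not in local smoothness (which would leak signal into R and B)
        collagen = np.empty_like(img)
        strand_noise = rng.normal(0.0, 1.0, size=(rows, cols, 3))
        for k in range(3):
            collagen[:, :, k] = config.collagen_rgb[k] + gaussian_filter(
                strand_noise[:, :, k] * config.background_noise_sd[k], sigma=config.background_blur
            )
        img = img * (1.0 - alpha) + collagen * alpha

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RGBImage(pixels=pixels, label=label)


def generate_dataset(config: SyntheticConfig) -> list[RGBImage]:
    """The full labeled cohort: n_control C images then n_fibrosis F images."""
    images = []
    index = 0
    for label, count in (("C", config.n_control), ("F", config.n_fibrosis)):
        for k in range(count):
            image = generate_image(label, config, seed=config.master_seed + index)
            image.source_id = f"{label}{k:02d}"
            images.append(image)
            index += 1
    return images


def write_dataset(config: SyntheticConfig, out_dir: str | Path, fmt: str = "png") -> Path:
    """Write the dataset as images plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "seed"])
        for index, image in enumerate(generate_dataset(config)):
            filename = f"{image.source_id}.{fmt}"
            save_image(image, out_dir / filename)
            writer.writerow([filename, image.label, config.master_seed + index])
    return manifest
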