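"""Full experiment grid: schemes x resolutions x texture methods.

For every resolution the images are degraded, split into ROIs and
converted into the channels each scheme needs; every channel ROI is
normalized and run through the three texture engines; parameters are
pooled per scheme, the top three Fisher features selected per cell and
the unsupervised classification error recorded per group — the analogue
of the study's error-bar grid and feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from histotex.classification import classify_unsupervised
from histotex.color_spaces import channel_to_byte, rgb_to_grey, rgb_to_hsi, split_rgb
from histotex.feature_selection import (
    SCHEME_PREFIXES,
    SCHEMES,
    FeatureTable,
    pool_scheme,
    select_top,
)
from histotex.image_io import RGBImage, extract_rois, reduce_resolution
from histotex.preprocessing import normalize_roi
from histotex.synthetic_data import SyntheticConfig, generate_dataset
from histotex.texture_com import com_features, compute_com
from histotex.texture_rlm import rlm_features_all_directions
from histotex.texture_wt import max_levels, wavelet_energies

RESOLUTIONS = ("full", "half", "quarter")
RESOLUTION_FACTORS = {"full": 1, "half": 2, "quarter": 4}
METHODS = ("COM", "RLM", "WT")


@dataclass
class ExperimentResult:
    """Error table plus the per-cell selected features."""

    errors: pd.DataFrame  # columns: scheme, resolution, method, group, percent_error
    features: pd.DataFrame  # columns: scheme, resolution, method, rank, feature, fisher
    seed: int = 0
    classifier: str = "kmeans"


def _channel_images(roi_pixels: np.ndarray, channels: set[str]) -> dict[str, np.ndarray]:
    """Byte-quantized single-channel layers of one RGB ROI."""
    out: dict[str, np.ndarray] = {}
    if "grey" in channels:
        out["grey"] = channel_to_byte(rgb_to_grey(roi_pixels))
    if channels & {"R", "G", "B"}:
        for ch in split_rgb(roi_pixels):
            if ch.channel in channels:
                out[ch.channel] = channel_to_byte(ch)
    if channels & {"H", "S", "I"}:
        for ch in rgb_to_hsi(roi_pixels):
            if ch.channel in channels:
                out[ch.channel] = channel_to_byte(ch)
    return out


def _method_features(norm, method: str, wt_levels: int) -> dict[str, float]:
    if method == "COM":
        return com_features(compute_com(norm))
    if method == "RLM":
        return rlm_features_all_directions(norm)
    if method == "WT":
        return wavelet_energies(norm, n_max=wt_levels).feature_dict()
    raise ValueError(f"unknown method {method!r}")


def compute_feature_tables(
    images: list[RGBImage],
    resolution: str,
    schemes=SCHEMES,
    methods=METHODS,
    margin: float = 0.05,
) -> dict[tuple[str, str], FeatureTable]:
    """Pooled FeatureTable per (scheme, method) cell at one resolution."""
    factor = RESOLUTION_FACTORS[resolution]
    rois = []
    for image in images:
        rois.extend(extract_rois(reduce_resolution(image, factor), margin=margin))
    roi_ids = [roi.roi_id for roi in rois]
    labels = pd.Series([roi.label for roi in rois], index=roi_ids)

    channels: set[str] = set()
    for scheme in schemes:
        channels |= set(SCHEME_PREFIXES[scheme])

    wt_levels = max_levels(*rois[0].pixels.shape[:2])
    # rows of per-channel, per-method feature dicts
    records: dict[tuple[str, str], list[dict[str, float]]] = {
        (channel, method): [] for channel in channels for method in methods
    }
    for roi in rois:
        layers = _channel_images(roi.pixels, channels)
        for channel, pixels in layers.items():
            norm = normalize_roi(pixels, channel=channel, roi_id=roi.roi_id)
            for method in methods:
                records[(channel, method)].append(_method_features(norm, method, wt_levels))

    tables: dict[tuple[str, str], FeatureTable] = {}
    for scheme in schemes:
        for method in methods:
            per_channel = {
                channel: FeatureTable(
                    data=pd.DataFrame(records[(channel, method)], index=roi_ids),
                    labels=labels,
                    scheme=scheme,
                    resolution=resolution,
                    method=method,
                )
                for channel in SCHEME_PREFIXES[scheme]
            }
            tables[(scheme, method)] = pool_scheme(per_channel, scheme)
    return tables


def run_experiment(
    images: list[RGBImage] | None = None,
    config: SyntheticConfig | None = None,
    seed: int = 0,
    resolutions=RESOLUTIONS,
    schemes=SCHEMES,
    methods=METHODS,
    margin: float = 0.05,
    classifier: str = "kmeans",
    k: int = 3,
) -> ExperimentResult:
    """Run the grid and return the error table and selected features.

    Provide either ``images`` (labeled RGBImages, both classes present)
    or ``config`` to generate a synthetic cohort.
    """
    if images is None:
        if config is None:
            config = SyntheticConfig(master_seed=seed)
        images = generate_dataset(config)
    label_counts = pd.Series([im.label for im in images]).value_counts()
    if set(label_counts.index) != {"C", "F"} or label_counts.min() < 2:
        raise ValueError("need at least 2 labeled images per class (C and F)")

    error_rows = []
    feature_rows = []
    for resolution in resolutions:
        tables = compute_feature_tables(
            images, resolution, schemes=schemes, methods=methods, margin=margin
        )
        for scheme in schemes:
            for method in methods:
                table = tables[(scheme, method)]
                ranking = select_top(table, k=k)
                for rank, (name, fvalue) in enumerate(ranking.entries, start=1):
                    feature_rows.append(
                        {
                            "scheme": scheme,
                            "resolution": resolution,
                            "method": method,
                            "rank": rank,
                            "feature": name,
                            "fisher": fvalue,
                        }
                    )
                result = classify_unsupervised(
                    table.data[ranking.names],
                    table.labels.to_numpy(),
                    seed=seed,
                    classifier=classifier,
                )
                for group, err in result.percent_errors.items():
                    error_rows.append(
                        {
                            "scheme": scheme,
                            "resolution": resolution,
                            "method": method,
                            "group": group,
                            "percent_error": err,
                        }
                    )
    return ExperimentResult(
        errors=pd.DataFrame(error_rows),
        features=pd.DataFrame(feature_rows),
        seed=seed,
        classifier=classifier,
    )


def plot_error_table(errors: pd.DataFrame, out_path) -> None:
    """Bar chart of percentage error per resolution (one panel each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    resolutions = [r for r in RESOLUTIONS if r in set(errors["resolution"])]
    fig, axes = plt.subplots(1, len(resolutions), figsize=(5 * len(resolutions), 4), squeeze=False)
    for ax, resolution in zip(axes[0], resolutions):
        sub = errors[errors["resolution"] == resolution]
        pivot = sub.pivot_table(
            index="method", columns=["scheme", "group"], values="percent_error"
        )
        pivot.plot.bar(ax=ax, legend=False)
        ax.set_title(f"{resolution} resolution")
        ax.set_ylabel("percentage error")
        ax.set_ylim(0, 100)
    axes[0][-1].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
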