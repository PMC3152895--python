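"""Scheme pooling, Fisher-coefficient ranking and top-k feature selection.

Texture parameters computed per channel are pooled into one descriptor
set per scheme (greylevel: the single grey layer, unprefixed; RGB: the
R/G/B layers with R_/G_/B_ column prefixes; HSI likewise with
H_/S_/I_).  Parameters are ranked by the two-class Fisher coefficient
F = (m1 - m2)^2 / (v1 + v2) and the top three become the features used
for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMES = ("greylevel", "RGB", "HSI")

#: channel tag -> column prefix, per scheme
SCHEME_PREFIXES = {
    "greylevel": {"grey": ""},
    "RGB": {"R": "R_", "G": "G_", "B": "B_"},
    "HSI": {"H": "H_", "S": "S_", "I": "I_"},
}

#: default number of selected features ("three coordinates")
DEFAULT_K = 3


@dataclass
class FeatureTable:
    """Samples x named texture parameters, with one class label per row."""

    data: pd.DataFrame  # index: sample ids; columns: parameter names
    labels: pd.Series  # aligned to data.index, values in {"C", "F"}
    scheme: str = ""
    resolution: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, index=self.data.index)
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.labels.isna().any():
            raise ValueError("every sample needs a class label")


@dataclass
class FisherRanking:
    """Parameter names with Fisher coefficients, ordered non-increasing."""

    entries: list[tuple[str, float]] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["feature", "fisher"])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df


def pool_scheme(channel_tables: dict[str, FeatureTable], scheme: str) -> FeatureTable:
    """Concatenate per-channel tables into one scheme table.

    Column names get the channel prefix of the scheme; all tables must
    share sample ordering and labels.
    """
    if scheme not in SCHEME_PREFIXES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    prefixes = SCHEME_PREFIXES[scheme]
    missing = set(prefixes) - set(channel_tables)
    if missing:
        raise ValueError(f"scheme {scheme!r} needs channels {sorted(missing)}")

    reference = channel_tables[next(iter(prefixes))]
    pieces = []
    for channel, prefix in prefixes.items():
        table = channel_tables[channel]
        if not table.data.index.equals(reference.data.index):
            raise ValueError(f"channel {channel!r} has a mismatched sample set")
        if not table.labels.equals(reference.labels):
            raise ValueError(f"channel {channel!r} has mismatched labels")
        pieces.append(table.data.add_prefix(prefix))
    pooled = pd.concat(pieces, axis=1)
    return FeatureTable(
        data=pooled,
        labels=reference.labels.copy(),
        scheme=scheme,
        resolution=reference.resolution,
        method=reference.method,
    )


def fisher_coefficient(values, labels) -> float:
    """Two-class Fisher coefficient (m1 - m2)^2 / (v1 + v2).

    Variances are unbiased sample variances.  If both within-class
    variances are zero the value is +inf when the means differ and 0.0
    when every value is identical.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(classes)}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    between = (a.mean() - b.mean()) ** 2
    within = a.var(ddof=1) + b.var(ddof=1)
    if within == 0:
        return float("inf") if between > 0 else 0.0
    return float(between / within)


def rank_features(table: FeatureTable) -> FisherRanking:
    """Rank all columns by Fisher coefficient, ties broken by column order."""
    scores = [
        (name, fisher_coefficient(table.data[name].to_numpy(), table.labels.to_numpy()))
        for name in table.data.columns
    ]
    # stable sort keeps column order among ties
    ordered = sorted(scores, key=lambda item: -item[1])
    return FisherRanking(entries=ordered)


def select_top(table: FeatureTable, k: int = DEFAULT_K) -> FisherRanking:
    """The k most discriminating parameters of a pooled table."""
    if table.data.shape[1] < k:
        raise ValueError(f"table has {table.data.shape[1]} columns, needs >= {k}")
    group_sizes = table.labels.value_counts()
    if k > group_sizes.min():
        raise ValueError(
            f"k={k} exceeds the smaller group size {group_sizes.min()}"
        )
    ranking = rank_features(table)
    return FisherRanking(entries=ranking.entries[:k])
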