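import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histotex.feature_selection import (
    FeatureTable,
    fisher_coefficient,
    pool_scheme,
    rank_features,
    select_top,
)


def _table(data: dict, labels, **tags) -> FeatureTable:
    df = pd.DataFrame(data)
    return FeatureTable(data=df, labels=pd.Series(labels, index=df.index), **tags)


@pytest.fixture
def labels8():
    return ["C"] * 4 + ["F"] * 4


class TestPoolScheme:
    def test_rgb_pooling_column_count(self, labels8):
        rng = np.random.default_rng(0)
        channels = {
            ch: _table({f"f{k}": rng.normal(size=8) for k in range(11)}, labels8)
            for ch in ("R", "G", "B")
        }
        pooled = pool_scheme(channels, "RGB")
        assert pooled.data.shape[1] == 33
        assert all(
            name.startswith(("R_", "G_", "B_")) for name in pooled.data.columns
        )

    def test_greylevel_passthrough_names(self, labels8):
        table = _table({"Sum of Squares": np.arange(8.0)}, labels8)
        pooled = pool_scheme({"grey": table}, "greylevel")
        assert list(pooled.data.columns) == ["Sum of Squares"]

    def test_duplicated_channel_doubles_columns(self, labels8):
        table = _table({"x": np.arange(8.0)}, labels8)
        pooled = pool_scheme({"H": table, "S": table, "I": table}, "HSI")
        assert pooled.data.shape[1] == 3
        assert (pooled.data["H_x"] == pooled.data["S_x"]).all()

    def test_mismatched_samples_raise(self, labels8):
        a = _table({"x": np.arange(8.0)}, labels8)
        b = FeatureTable(
            data=pd.DataFrame({"x": np.arange(8.0)}, index=list("abcdefgh")),
            labels=pd.Series(labels8, index=list("abcdefgh")),
        )
        with pytest.raises(ValueError, match="sample set"):
            pool_scheme({"R": a, "G": a, "B": b}, "RGB")


class TestFisherCoefficient:
    def test_identical_distributions(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["C", "C", "C", "F", "F", "F"]
        assert fisher_coefficient(values, labels) == 0.0

    def test_zero_within_class_variance(self):
        assert fisher_coefficient([0, 0, 1, 1], ["C", "C", "F", "F"]) == float("inf")

    def test_hand_computed_value(self):
        # class C {1,2,3}, class F {7,8,9}: (2-8)^2 / (1+1) = 18
        f = fisher_coefficient([1, 2, 3, 7, 8, 9], ["C"] * 3 + ["F"] * 3)
        assert f == pytest.approx(18.0)

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            fisher_coefficient([1, 2, 3], ["C", "F", "F"])

    @given(
        st.lists(st.integers(min_value=-50, max_value=50).map(float), min_size=3, max_size=8),
        st.lists(st.integers(min_value=-50, max_value=50).map(float), min_size=3, max_size=8),
        st.floats(min_value=0.5, max_value=3.0),
        st.floats(min_value=-10, max_value=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, a_vals, b_vals, scale, shift):
        values = np.array(a_vals + b_vals)
        labels = np.array(["C"] * len(a_vals) + ["F"] * len(b_vals))
        f1 = fisher_coefficient(values, labels)
        f2 = fisher_coefficient(scale * values + shift, labels)
        if np.isinf(f1):
            assert np.isinf(f2)
        else:
            assert f2 == pytest.approx(f1, rel=1e-6, abs=1e-9)


class TestSelectTop:
    def test_exactly_three_features(self, labels8):
        rng = np.random.default_rng(1)
        table = _table({f"f{k}": rng.normal(size=8) for k in range(10)}, labels8)
        ranking = select_top(table, k=3)
        assert len(ranking.names) == 3
        fvals = [f for _, f in ranking.entries]
        assert fvals == sorted(fvals, reverse=True)

    def test_label_column_ranks_first(self, labels8):
        rng = np.random.default_rng(2)
        table = _table(
            {
                "noise1": rng.normal(size=8),
                "label_copy": [0.0] * 4 + [1.0] * 4,
                "noise2": rng.normal(size=8),
                "noise3": rng.normal(size=8),
            },
            labels8,
        )
        assert select_top(table, k=3).names[0] == "label_copy"

    def test_signal_confined_to_g_channel(self, labels8):
        rng = np.random.default_rng(3)
        channels = {}
        for ch in ("R", "G", "B"):
            data = {f"f{k}": rng.normal(size=8) for k in range(5)}
            if ch == "G":
                data = {
                    f"f{k}": np.array([0.0] * 4 + [50.0] * 4) + rng.normal(size=8)
                    for k in range(5)
                }
            channels[ch] = _table(data, labels8)
        ranking = select_top(pool_scheme(channels, "RGB"), k=3)
        assert all(name.startswith("G_") for name in ranking.names)

    def test_tie_broken_by_column_order(self, labels8):
        x = np.array([0.0, 1, 2, 3, 10, 11, 12, 13])
        table = _table({"second": x, "first": x}, labels8)
        ranking = rank_features(table)
        assert [name for name, _ in ranking.entries] == ["second", "first"]

    def test_k_exceeding_group_size_raises(self):
        table = _table(
            {f"f{k}": np.arange(5.0) for k in range(4)}, ["C", "C", "F", "F", "F"]
        )
        with pytest.raises(ValueError, match="group size"):
            select_top(table, k=3)

    def test_sample_permutation_invariance(self, labels8):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({f"f{k}": rng.normal(size=8) for k in range(6)})
        table = _table({c: df[c].to_numpy() for c in df}, labels8)
        perm = rng.permutation(8)
        shuffled = FeatureTable(
            data=df.iloc[perm].reset_index(drop=True),
            labels=pd.Series(np.array(labels8)[perm]),
        )
        assert select_top(table).names == select_top(shuffled).names
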