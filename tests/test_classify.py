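import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stalkpull.calibration import PAPER2023_INFERENCE, InferenceModel
from stalkpull.classify import (
    LEVELS,
    PAPER2023_SCHEME,
    ClassScheme,
    ClusterSummary,
    accuracy_table,
    classify_fmax,
    classify_population,
    cluster_fmax,
    grade_proportions,
    scheme_from_clusters,
)
from stalkpull.features import PlantFeatures


def optimal_contiguous_partition(values, k):
    """Brute-force oracle: contiguous k-partition of sorted values
    minimizing total within-cluster sum of squares."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    best, best_cost = None, np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        cost = sum(sse(x[a:b]) for a, b in zip(bounds, bounds[1:]))
        if cost < best_cost - 1e-12:
            best_cost, best = cost, bounds
    return [x[a:b] for a, b in zip(best, best[1:])], best_cost


class TestClusterFmax:
    def test_well_separated_quadruplets(self):
        values = [0.9, 1.0, 1.1, 4.8, 5.0, 5.2, 9.9, 10.0, 10.1, 19.5, 20.0, 20.5]
        labels, summary = cluster_fmax(values, k=4)
        np.testing.assert_allclose(summary.means, [1.0, 5.0, 10.0, 20.0])
        np.testing.assert_array_equal(summary.counts, [3, 3, 3, 3])
        # matches the brute-force optimal contiguous partition
        segs, _ = optimal_contiguous_partition(values, 4)
        np.testing.assert_allclose([s.mean() for s in segs], summary.means)

    def test_k_equals_n_is_singletons(self):
        values = [1.0, 3.0, 9.0, 27.0]
        _, summary = cluster_fmax(values, k=4)
        np.testing.assert_allclose(summary.means, values)
        np.testing.assert_allclose(summary.mins, summary.maxs)

    def test_two_separated_values(self):
        labels, summary = cluster_fmax([1.0, 50.0], k=2)
        np.testing.assert_array_equal(summary.counts, [1, 1])

    def test_degenerate_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cluster_fmax([5.0] * 10, k=4)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            cluster_fmax([1.0, 2.0], k=4)

    def test_summary_invariants(self, rng):
        values = rng.uniform(1, 40, 200)
        labels, summary = cluster_fmax(values, k=4)
        assert summary.counts.sum() == 200
        assert np.all(np.diff(summary.means) > 0)
        assert np.all(summary.mins <= summary.means)
        assert np.all(summary.means <= summary.maxs)
        # 1-D clusters are contiguous intervals
        assert np.all(summary.maxs[:-1] < summary.mins[1:])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_on_small_instances(self, data):
        n = data.draw(st.integers(6, 14))
        k = data.draw(st.integers(2, 4))
        values = data.draw(
            st.lists(st.floats(0, 50, allow_nan=False), min_size=n, max_size=n,
                     unique=True)
        )
        labels, summary = cluster_fmax(values, k=k)
        x = np.asarray(values)
        ward_cost = sum(
            float(np.sum((x[labels == i] - x[labels == i].mean()) ** 2))
            for i in range(k)
        )
        _, oracle_cost = optimal_contiguous_partition(values, k)
        assert ward_cost == pytest.approx(oracle_cost, rel=1e-9, abs=1e-9)


class TestSchemeFromClusters:
    def test_published_cluster_maxima(self):
        summary = ClusterSummary(
            means=np.array([9.25, 14.53, 20.61, 31.33]),
            mins=np.array([3.4, 11.9, 17.6, 26.0]),
            maxs=np.array([11.8, 17.5, 25.8, 55.8]),
            counts=np.array([378, 444, 266, 84]),
        )
        scheme = scheme_from_clusters(summary)
        assert scheme.boundaries == (11.8, 17.5, 25.8)

    def test_toy_cluster_maxima(self):
        values = [0.9, 1.0, 1.1, 4.8, 5.0, 5.2, 9.9, 10.0, 10.1, 19.5, 20.0, 20.5]
        _, summary = cluster_fmax(values, k=4)
        assert scheme_from_clusters(summary).boundaries == (1.1, 5.2, 10.1)

    def test_overlapping_ranges_rejected(self):
        summary = ClusterSummary(
            means=np.array([5.0, 10.0, 20.0, 30.0]),
            mins=np.array([1.0, 8.0, 18.0, 28.0]),
            maxs=np.array([9.0, 15.0, 25.0, 40.0]),
            counts=np.array([3, 3, 3, 3]),
        )
        with pytest.raises(ValueError, match="overlap"):
            scheme_from_clusters(summary)


class TestClassifyFmax:
    @pytest.mark.parametrize(
        "value, level",
        [
            (9.25, "poor"),       # weakest published cluster mean
            (17.5, "low"),        # boundary belongs to the lower level
            (11.8, "poor"),
            (20.61, "moderate"),
            (31.33, "high"),
            (25.8001, "high"),
        ],
    )
    def test_published_scheme_examples(self, value, level):
        assert classify_fmax(PAPER2023_SCHEME, value) == level

    @settings(derandomize=True, max_examples=200)
    @given(value=st.floats(0, 100, allow_nan=False))
    def test_partition_covers_nonnegative_axis(self, value):
        level = classify_fmax(PAPER2023_SCHEME, value)
        assert level in LEVELS
        b1, b2, b3 = PAPER2023_SCHEME.boundaries
        expected = (
            "poor" if value <= b1 else
            "low" if value <= b2 else
            "moderate" if value <= b3 else "high"
        )
        assert level == expected


class TestClassifyPopulation:
    def _features(self):
        return [
            PlantFeatures("P1", Fmax=9.0, F45=9.0),
            PlantFeatures("P2", Fmax=16.0, F45=16.0),
            PlantFeatures("P3", Fmax=30.0, F45=30.0, break_angle=80.0, survived_90=False),
            PlantFeatures("P4", Fmax=8.0, break_angle=30.0, survived_45=False,
                          survived_90=False),
        ]

    def test_identity_model_modes_agree_where_f45_equals_fmax(self):
        ident = InferenceModel(a=1.0, b=0.0, r2=1.0, n=2)
        feats = self._features()
        measured = classify_population(feats, PAPER2023_SCHEME, mode="measured")
        inferred = classify_population(feats, PAPER2023_SCHEME, ident, mode="inferred")
        for pid in ("P1", "P2", "P3"):
            assert measured[pid] == inferred[pid]

    def test_early_broken_plant_unclassifiable_in_inferred_mode(self):
        inferred = classify_population(
            self._features(), PAPER2023_SCHEME, PAPER2023_INFERENCE, mode="inferred"
        )
        assert inferred["P4"] is None
        measured = classify_population(self._features(), PAPER2023_SCHEME, mode="measured")
        assert measured["P4"] == "poor"

    def test_published_model_prediction_classified(self):
        feats = [PlantFeatures("P1", Fmax=20.0, F45=10.0)]
        inferred = classify_population(
            feats, PAPER2023_SCHEME, PAPER2023_INFERENCE, mode="inferred"
        )
        # 1.1354 * 10 - 0.3358 = 11.0182 -> poor
        assert inferred["P1"] == "poor"


class TestAccuracyTable:
    @staticmethod
    def _series(values, ids=None):
        ids = ids or [f"P{i}" for i in range(len(values))]
        return pd.Series(values, index=pd.Index(ids, name="plant_id"))

    def test_identical_labelings_are_100_percent(self):
        labels = self._series(["poor", "low", "moderate", "high"])
        table = accuracy_table(labels, labels)
        assert (table["accuracy_pct"] == 100.0).all()
        assert table["agreement"].sum() == 4

    def test_disjoint_labelings_are_0_percent(self):
        m = self._series(["poor", "poor", "low"])
        p = self._series(["low", "low", "poor"])
        table = accuracy_table(m, p)
        assert table.loc["poor", "accuracy_pct"] == 0.0
        assert table.loc["low", "accuracy_pct"] == 0.0

    def test_hand_counted_example(self):
        m = self._series(["poor", "poor", "low", "low"])
        p = self._series(["poor", "low", "low", "low"])
        table = accuracy_table(m, p)
        assert table.loc["poor", "accuracy_pct"] == pytest.approx(50.0)
        assert table.loc["low", "accuracy_pct"] == pytest.approx(100.0)
        assert table["agreement"].sum() <= 4

    def test_disjoint_plant_sets_rejected(self):
        m = self._series(["poor"], ids=["A"])
        p = self._series(["poor"], ids=["B"])
        with pytest.raises(ValueError):
            accuracy_table(m, p)


class TestGradeProportions:
    def _frame(self, levels, variety):
        ids = [f"P{i}" for i in range(len(levels))]
        s = pd.Series(levels, index=pd.Index(ids, name="plant_id"))
        g = pd.DataFrame({"variety": variety}, index=s.index)
        return s, g

    def test_single_level_group(self):
        s, g = self._frame(["high", "high"], ["A", "A"])
        table = grade_proportions(s, g)
        high = table[(table.variety == "A") & (table.level == "high")]
        assert high["percent"].iloc[0] == 100.0

    def test_balanced_two_level_group(self):
        s, g = self._frame(["poor", "high"], ["A", "A"])
        table = grade_proportions(s, g)
        assert set(table[table.percent == 50.0].level) == {"poor", "high"}

    def test_one_per_level_gives_25_each(self):
        s, g = self._frame(list(LEVELS), ["A"] * 4)
        table = grade_proportions(s, g)
        assert (table.percent == 25.0).all()

    def test_percentages_sum_to_100_per_group(self, rng):
        levels = rng.choice(LEVELS, size=60).tolist()
        variety = rng.choice(["A", "B", "C"], size=60).tolist()
        s, g = self._frame(levels, variety)
        table = grade_proportions(s, g)
        sums = table.groupby("variety")["percent"].sum()
        np.testing.assert_allclose(sums, 100.0)
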