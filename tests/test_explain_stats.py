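import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
import xgboost as xgb
from scipy import stats as sps
from sklearn.metrics import silhouette_score

from rfepp.explain_stats import (
    attribution_ranking,
    benjamini_hochberg,
    cluster_and_boxplot_tables,
    correlate_golden_to_all,
    embed,
    kendall_tau,
    volcano_stats,
)

from conftest import make_matrix


def bh_by_hand(ps):
    """Independent step-up oracle: p*(m/rank), cumulative min from the top."""
    m = len(ps)
    order = np.argsort(ps)
    scaled = [ps[i] * m / (rank + 1) for rank, i in enumerate(order)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = np.empty(m)
    for rank, i in enumerate(order):
        out[i] = min(scaled[rank], 1.0)
    return out


def kendall_by_hand(x, y):
    """Exhaustive concordant/discordant pair counting (tau-a, no ties)."""
    c = d = 0
    for (i, j) in itertools.combinations(range(len(x)), 2):
        s = (x[i] - x[j]) * (y[i] - y[j])
        c += s > 0
        d += s < 0
    return (c - d) / (c + d)


class TestKendall:
    @pytest.mark.parametrize(
        "x,y,expected",
        [([1, 2, 3], [2, 4, 6], 1.0),
         ([1, 2, 3], [3, 2, 1], -1.0),
         ([1, 2, 3], [1, 3, 2], 1 / 3)],
    )
    def test_worked_examples(self, x, y, expected):
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(expected)

    def test_matches_exhaustive_pair_counting_small_n(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            x = rng.permutation(n).astype(float)  # no ties
            y = rng.permutation(n).astype(float)
            tau, _ = kendall_tau(x, y)
            assert tau == pytest.approx(kendall_by_hand(x, y))

    def test_missing_pairs_dropped(self):
        tau, _ = kendall_tau([1, 2, 3, np.nan], [2, 4, 6, 1])
        assert tau == pytest.approx(1.0)

    def test_insufficient_pairs_yield_nan(self):
        tau, p = kendall_tau([1, np.nan], [2, 3])
        assert np.isnan(tau) and np.isnan(p)

    def test_null_rejection_rate_calibrated(self):
        """Independent uniforms, n=20: ~5% of p-values fall below 0.05."""
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            _, p = kendall_tau(rng.random(20), rng.random(20))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "ps,expected",
        [([0.5], [0.5]),
         ([0.04, 0.01], [0.04, 0.02]),
         ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03])],
    )
    def test_worked_examples(self, ps, expected):
        assert benjamini_hochberg(ps) == pytest.approx(expected)

    def test_matches_hand_step_up_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            ps = rng.random(int(rng.integers(1, 15))).tolist()
            assert benjamini_hochberg(ps) == pytest.approx(bh_by_hand(ps))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(4)
        ps = rng.random(50)
        assert (benjamini_hochberg(ps) >= ps - 1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_step_up_properties(self, ps):
        adjusted = benjamini_hochberg(ps)
        assert ((adjusted >= np.asarray(ps) - 1e-12) & (adjusted <= 1.0)).all()
        # monotone: a smaller raw p never gets a larger adjusted p
        order = np.argsort(ps)
        assert (np.diff(adjusted[order]) >= -1e-12).all()


class TestCorrelateGoldenToAll:
    def test_duplicated_feature_detected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        vals = np.column_stack([base, base, rng.normal(size=30)])
        m = make_matrix(vals.tolist(), feature_ids=["g", "copy", "other"],
                        classes=["A", "B"] * 15)
        table = correlate_golden_to_all(m, ["g"])
        row = table[table.feature == "copy"].iloc[0]
        assert row.kendall_tau == pytest.approx(1.0)
        assert "g" not in set(table.feature)  # never self-correlated

    def test_null_false_positive_rate_is_alpha_controlled(self):
        """50 samples, 100 independent noise pairs: few survive BH at 0.05."""
        retained = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = rng.standard_normal((50, 101))
            m = make_matrix(vals.tolist(), classes=["A", "B"] * 25)
            table = correlate_golden_to_all(m, [m.feature_ids[0]], alpha=0.05)
            retained.append(len(table))
        assert np.mean(retained) <= 10


class TestVolcano:
    def test_disjoint_groups_exact_p(self):
        m = make_matrix([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]],
                        classes=["A"] * 3 + ["B"] * 3)
        tables = volcano_stats(m)
        assert set(tables) == {"A"}  # two classes -> single contrast
        row = tables["A"].iloc[0]
        assert row.p_value == pytest.approx(0.1)  # exact 2/20 enumeration
        assert row.effect == pytest.approx(-9.0)

    def test_identical_distributions_near_one(self):
        m = make_matrix([[1.0], [2.0], [1.0], [2.0]], classes=["A", "A", "B", "B"])
        row = volcano_stats(m)["A"].iloc[0]
        assert row.effect == 0.0
        assert row.p_value > 0.6

    def test_missing_imputed_with_feature_minimum(self):
        m = make_matrix([[5.0], [None], [1.0], [7.0]], classes=["A", "A", "B", "B"])
        tables = volcano_stats(m)
        # imputed value 1.0 for the A-group missing cell: mean A = 3.0
        assert tables["A"].iloc[0].effect == pytest.approx(3.0 - 4.0)

    def test_three_classes_give_three_contrasts(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(9, 2)).tolist(), classes=list("ABC") * 3)
        assert set(volcano_stats(m)) == {"A", "B", "C"}

    def test_matches_exact_permutation_enumeration(self):
        """Two-sided rank-sum p equals brute-force permutation enumeration."""
        a = [1.0, 4.0, 6.0]
        b = [2.0, 3.0, 9.0]
        observed = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        pooled = a + b
        stats = []
        for comb in itertools.combinations(range(6), 3):
            grp = [pooled[i] for i in comb]
            stats.append(sps.mannwhitneyu(grp, [pooled[i] for i in range(6)
                                                if i not in comb]).statistic)
        obs = sps.mannwhitneyu(a, b).statistic
        n = len(stats)
        extreme = sum(1 for s in stats
                      if abs(s - 4.5) >= abs(obs - 4.5) - 1e-9)  # 4.5 = null mean
        assert observed == pytest.approx(extreme / n)


class TestAttribution:
    @pytest.fixture
    def fitted(self, separable_matrix):
        y = (separable_matrix.classes == "B").astype(int)
        clf = xgb.XGBClassifier(n_estimators=10, max_depth=2, tree_method="hist",
                                n_jobs=1, random_state=0, verbosity=0)
        clf.fit(separable_matrix.data, y)
        return clf

    def test_additivity_reconstructs_margin(self, separable_matrix, fitted):
        table = attribution_ranking(fitted, separable_matrix,
                                    separable_matrix.feature_ids)
        margins = fitted.get_booster().predict(
            xgb.DMatrix(separable_matrix.data), output_margin=True)
        reconstructed = table.values.sum(axis=1) + table.base_values
        np.testing.assert_allclose(reconstructed, margins, atol=1e-5)

    def test_signal_feature_ranked_first(self, separable_matrix, fitted):
        table = attribution_ranking(fitted, separable_matrix,
                                    separable_matrix.feature_ids)
        assert table.ranking[0] == "sig"

    def test_unused_feature_attributes_zero(self, separable_matrix):
        y = (separable_matrix.classes == "B").astype(int)
        stump = xgb.XGBClassifier(n_estimators=1, max_depth=1, tree_method="hist",
                                  n_jobs=1, random_state=0, verbosity=0)
        stump.fit(separable_matrix.data, y)
        table = attribution_ranking(stump, separable_matrix,
                                    separable_matrix.feature_ids)
        used = set(stump.get_booster().get_score())  # DataFrame fit keeps names
        for f in separable_matrix.feature_ids:
            if f not in used:
                assert (table.values[f] == 0).all()

    def test_identical_samples_identical_rows(self, separable_matrix, fitted):
        two = make_matrix(
            np.vstack([separable_matrix.data.iloc[0]] * 2).tolist(),
            sample_ids=["x", "y"],
            feature_ids=separable_matrix.feature_ids,
            classes=["A", "A"],
        )
        table = attribution_ranking(fitted, two, separable_matrix.feature_ids)
        np.testing.assert_array_equal(table.values.loc["x"], table.values.loc["y"])

    def test_feature_mismatch_errors(self, separable_matrix, fitted):
        with pytest.raises(ValueError):
            attribution_ranking(fitted, separable_matrix, ["sig"])


class TestEmbed:
    def test_separated_blobs_have_high_silhouette(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.5, size=(15, 5))
        b = rng.normal(8, 0.5, size=(15, 5))
        m = make_matrix(np.vstack([a, b]).tolist(), classes=["A"] * 15 + ["B"] * 15)
        coords = embed(m, method="pca")
        assert silhouette_score(coords, m.classes) > 0.5

    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(5, 4)).tolist()
        vals.append(list(vals[0]))
        m = make_matrix(vals)
        coords = embed(m, method="pca")
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[5], atol=1e-9)

    def test_constant_matrix_errors(self):
        m = make_matrix([[1.0, 1.0]] * 4)
        with pytest.raises(ValueError):
            embed(m, method="pca")


class TestClusterTables:
    def test_identical_features_merge_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        vals = np.column_stack([base, base, -base, rng.normal(size=20)])
        m = make_matrix(vals.tolist(), feature_ids=["a", "a2", "anti", "n"],
                        classes=["X", "Y"] * 10)
        linkage, order, summary = cluster_and_boxplot_tables(
            m, ["a", "a2", "anti", "n"])
        first = sorted([int(linkage[0, 0]), int(linkage[0, 1])])
        assert first == [0, 1]  # a and a2
        assert linkage[-1, 2] == max(linkage[:, 2])  # anti merges last/highest

    def test_single_feature_trivial(self, two_class_matrix):
        linkage, order, summary = cluster_and_boxplot_tables(two_class_matrix, ["f1"])
        assert linkage.shape == (0, 4)
        assert order == ["f1"]
        assert set(summary["class"]) == {"A", "B"}

    def test_summary_quantiles(self):
        m = make_matrix([[1.0], [2.0], [3.0], [10.0]], classes=["A"] * 3 + ["B"])
        _, _, summary = cluster_and_boxplot_tables(m, ["f1"])
        a = summary[summary["class"] == "A"].iloc[0]
        assert (a["min"], a["median"], a["max"]) == (1.0, 2.0, 3.0)
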