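import numpy as np
import pytest

from rfepp.benchmark import MoonsSpec, generate_moons_highdim
from rfepp.rfe_core import (
    RfeConfig,
    _significant_drop,
    cv_fit_and_score,
    hyperparameter_search,
    monte_carlo_select,
    rank_and_eliminate,
    run_stage1,
    run_stage2,
)
from rfepp.splitting import stratified_group_kfold

from conftest import make_matrix


@pytest.fixture
def config():
    return RfeConfig()


def folds_for(matrix, k=5, seed=0):
    return stratified_group_kfold(matrix.sample_ids, matrix.classes, k, seed=seed)


class TestRankAndEliminate:
    def test_unique_minimum_removed(self):
        gains = {"a": 5, "b": 4, "c": 3, "d": 3, "e": 1}
        kept, removed, tied = rank_and_eliminate(gains, list("abcde"), 0.10)
        assert removed == ["e"]
        assert tied == []
        assert kept == list("abcd")

    def test_tie_recorded_not_removed(self):
        gains = {"a": 5, "b": 3, "c": 3, "d": 1, "e": 1}
        kept, removed, tied = rank_and_eliminate(gains, list("abcde"), 0.10)
        # d and e tie at the minimum; exactly one leaves (stable input-order
        # tie-break), the other is flagged for re-ranking
        assert removed == ["d"]
        assert tied == ["e"]
        assert set(kept) == {"a", "b", "c", "e"}

    def test_ceiling_forces_progress_on_small_sets(self):
        gains = {f: i for i, f in enumerate("abcde")}
        _, removed, _ = rank_and_eliminate(gains, list("abcde"), 0.10)
        assert len(removed) == 1  # ceil(0.5)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            rank_and_eliminate({"a": 1}, ["a"], 1.5)


class TestStoppingRule:
    def test_small_relative_drop_continues(self, config):
        assert not _significant_drop(0.90, 0.85, config)  # 0.05 < 0.1*0.85

    def test_large_relative_drop_stops(self, config):
        assert _significant_drop(0.90, 0.75, config)  # 0.15 > 0.075

    def test_absolute_mode(self):
        cfg = RfeConfig(absolute_drop=True)
        assert _significant_drop(0.90, 0.79, cfg)
        assert not _significant_drop(0.90, 0.81, cfg)


class TestCvFitAndScore:
    def test_perfect_separation_scores_one(self, separable_matrix, config):
        folds = folds_for(separable_matrix)
        res = cv_fit_and_score(separable_matrix, separable_matrix.sample_ids,
                               ["sig"], folds, config, seed=0)
        assert res.auc_mean == 1.0

    def test_unused_feature_has_zero_gain(self, separable_matrix, config):
        folds = folds_for(separable_matrix)
        res = cv_fit_and_score(separable_matrix, separable_matrix.sample_ids,
                               separable_matrix.feature_ids, folds, config, seed=0)
        assert res.gains["sig"] > 0
        assert min(res.gains.values()) >= 0

    def test_pure_noise_scores_near_half_on_average(self, config):
        rng = np.random.default_rng(0)
        means = []
        for seed in range(50):
            vals = np.random.default_rng(seed).standard_normal((10, 5))
            labels = list("AB" * 5)
            m = make_matrix(vals.tolist(), classes=labels)
            folds = folds_for(m, k=5, seed=seed)
            res = cv_fit_and_score(m, m.sample_ids, m.feature_ids, folds,
                                   config, seed=seed)
            means.append(res.auc_mean)
        assert abs(np.mean(means) - 0.5) < 0.1

    def test_augmentation_never_touches_validation(self, separable_matrix):
        cfg = RfeConfig(bootstrap_on=True, noisy_on=True)
        before = separable_matrix.data.copy()
        folds = folds_for(separable_matrix)
        cv_fit_and_score(separable_matrix, separable_matrix.sample_ids,
                         separable_matrix.feature_ids, folds, cfg, seed=0)
        assert separable_matrix.data.equals(before)


class TestStage1:
    def test_moons_mini_recovers_informative_features(self):
        """Both moon coordinates survive to the optimal set in >=4/5 seeds."""
        hits = 0
        for seed in range(5):
            m = generate_moons_highdim(
                MoonsSpec(n_samples=60, n_noise_features=40, seed=seed))
            cfg = RfeConfig(master_seed=seed)
            folds = stratified_group_kfold(m.sample_ids, m.classes, 5, seed=seed)
            opt, trace = run_stage1(m, m.sample_ids, m.feature_ids, folds, cfg,
                                    seed=seed * 100)
            hits += {"moon_1", "moon_2"} <= set(opt)
            for p in trace.passes:
                sizes = [r.n_features for r in p]
                assert sizes == sorted(sizes, reverse=True)
                assert len(set(sizes)) == len(sizes)  # strictly shrinking
        assert hits >= 4

    def test_needs_two_features(self, separable_matrix, config):
        with pytest.raises(ValueError):
            run_stage1(separable_matrix, separable_matrix.sample_ids, ["sig"],
                       folds_for(separable_matrix), config, seed=0)


class TestStage2:
    def test_under_cap_returns_unchanged(self, separable_matrix, config):
        opt = separable_matrix.feature_ids  # 4 features, cap 30
        out, trace = run_stage2(separable_matrix, separable_matrix.sample_ids,
                                opt, folds_for(separable_matrix), config, seed=0)
        assert out == opt and trace.passes == []

    def test_cap_enforced(self, separable_matrix):
        cfg = RfeConfig(stage2_cap=2)
        out, _ = run_stage2(separable_matrix, separable_matrix.sample_ids,
                            separable_matrix.feature_ids,
                            folds_for(separable_matrix), cfg, seed=0)
        assert len(out) == 2

    def test_cap_one_keeps_top_gain_feature(self, separable_matrix):
        cfg = RfeConfig(stage2_cap=1)
        out, _ = run_stage2(separable_matrix, separable_matrix.sample_ids,
                            separable_matrix.feature_ids,
                            folds_for(separable_matrix), cfg, seed=0)
        assert out == ["sig"]


class TestHyperparameterSearch:
    def test_single_draw_wins(self, separable_matrix, config):
        params, _ = hyperparameter_search(
            separable_matrix, separable_matrix.sample_ids, ["sig"],
            folds_for(separable_matrix), config, n_draws=1, seed=3)
        assert set(params) == {"max_depth", "learning_rate", "n_estimators",
                               "subsample", "colsample_bytree", "min_child_weight"}

    def test_deterministic_given_seed(self, separable_matrix, config):
        args = (separable_matrix, separable_matrix.sample_ids,
                separable_matrix.feature_ids, folds_for(separable_matrix), config)
        p1, _ = hyperparameter_search(*args, n_draws=5, seed=11)
        p2, _ = hyperparameter_search(*args, n_draws=5, seed=11)
        assert p1 == p2

    def test_capable_setting_beats_crippled_grid(self, config):
        # two-point grid on moons: a single stump cannot model the
        # nonlinear boundary, a real ensemble can
        m = generate_moons_highdim(MoonsSpec(n_samples=60, n_noise_features=0, seed=1))
        folds = stratified_group_kfold(m.sample_ids, m.classes, 5, seed=1)
        base = {"learning_rate": [0.3], "subsample": [1.0],
                "colsample_bytree": [1.0], "min_child_weight": [1]}
        grid = {"max_depth": [1, 4], "n_estimators": [1, 100], **base}
        params, res = hyperparameter_search(
            m, m.sample_ids, m.feature_ids, folds, config,
            n_draws=30, seed=0, grid=grid)
        crippled = cv_fit_and_score(
            m, m.sample_ids, m.feature_ids, folds, config, seed=0,
            params={"max_depth": 1, "n_estimators": 1, "learning_rate": 0.3,
                    "subsample": 1.0, "colsample_bytree": 1.0,
                    "min_child_weight": 1})
        assert (params["max_depth"], params["n_estimators"]) != (1, 1)
        assert res.auc_mean > crippled.auc_mean


@pytest.fixture(scope="module")
def result():
    m = generate_moons_highdim(MoonsSpec(n_samples=40, n_noise_features=15, seed=2))
    cfg = RfeConfig(n_simulations=2, n_grid_draws=4, master_seed=2)
    return monte_carlo_select(m, config=cfg), m


class TestMonteCarloSelect:
    def test_golden_is_union_of_selected(self, result):
        res, _ = result
        union = set().union(*(s.selected_features for s in res.simulations))
        assert set(res.golden_features) == union

    def test_final_test_isolated_from_all_fitting(self, result):
        res, _ = result
        assert set(res.split_plan.final_test).isdisjoint(res.fit_sample_ids)

    def test_split_plan_partitions_each_simulation(self, result):
        res, m = result
        final = set(res.split_plan.final_test)
        for sim in res.split_plan.simulations:
            train, itest = set(sim["train"]), set(sim["internal_test"])
            assert final | train | itest == set(m.sample_ids)
            assert not (final & train or final & itest or train & itest)
            fold_union = set().union(*(set(f) for f in sim["cv_folds"]))
            assert fold_union == train

    def test_single_simulation_golden_equals_selection(self):
        m = generate_moons_highdim(MoonsSpec(n_samples=30, n_noise_features=8, seed=5))
        cfg = RfeConfig(n_simulations=1, n_grid_draws=3, master_seed=5)
        res = monte_carlo_select(m, config=cfg)
        assert res.golden_features == sorted(res.simulations[0].selected_features)

    def test_class_with_single_group_rejected(self):
        vals = np.random.default_rng(0).normal(size=(4, 3)).tolist()
        m = make_matrix(vals, classes=["A", "A", "B", "B"])
        from rfepp.io_tables import ReplicateGroups
        groups = ReplicateGroups({"s1": "G", "s2": "G"})
        with pytest.raises(ValueError, match="replicate groups"):
            monte_carlo_select(m, groups=groups, config=RfeConfig(master_seed=1))
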