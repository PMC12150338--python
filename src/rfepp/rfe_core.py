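"""The RFE++ engine: Monte-Carlo two-stage recursive feature elimination.

The algorithm searches for the smallest feature set that still predicts
the phenotype, using gradient-boosted decision trees (native missing
value handling, no scale sensitivity) as the base learner:

* A final test set is put aside once, before anything is fitted.
* Each Monte-Carlo simulation shuffles the feature columns, re-splits
  the remainder into train / internal test, and runs

  - **stage 1** — repeated elimination passes.  One pass ("rfecv
    iteration") runs stratified k-fold cross-validation of a
    boosted-tree classifier, ranks features by total split gain, removes
    the worst 10% (exact gain ties to removed features are flagged and
    re-ranked rather than dropped) and repeats down to a single feature,
    charting CV ROC AUC against feature count; the pass returns its
    best-performing subset, and the next pass restarts from it with a
    smaller maximum feature count.  Passes repeat until one shows a
    significant loss — by default a *relative* drop of more than
    ``auc_drop_threshold`` x the current pass's CV AUC against the
    previous pass.  The feature list still considered before the loss is
    that simulation's optimal set.  The loss is guaranteed eventually:
    pass starting sets shrink strictly, and performance collapses once
    the signal carriers are forced out.
  - **stage 2** (optional) — the same elimination forced onward, stopping
    rule ignored, until at most ``stage2_cap`` features remain: a list
    small enough for wet-lab follow-up.

  A random-grid hyperparameter-searched classifier ("Grid2") is then
  fitted on the selected features and scored on the internal test set.
* The union of all simulations' selections — the *golden features* — is
  the candidate list.  A final hyperparameter-searched model on the
  golden features, trained with repeated cross-validation on everything
  except the final test set, is evaluated exactly once on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from . import evaluation
from .augmentation import bootstrap_augment, fit_noise_model
from .io_tables import ExpressionMatrix, ReplicateGroups
from .splitting import (
    SplitPlan,
    stratified_group_kfold,
    stratified_group_split,
)

logger = logging.getLogger(__name__)

#: gains closer than this are considered exactly tied
TIE_TOLERANCE = 1e-12

#: fixed booster settings for the elimination loop (the hyperparameter
#: search later tunes the reporting models; the loop itself uses one
#: lean, deterministic configuration)
STAGE_PARAMS: dict = {
    "n_estimators": 100,
    "max_depth": 6,
    "learning_rate": 0.3,
    "min_child_weight": 1,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
}

#: the random-grid search space (documented default; the draw count is
#: RfeConfig.n_grid_draws)
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [2, 3, 4, 6],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [50, 100, 200],
    "subsample": [0.7, 0.9, 1.0],
    "colsample_bytree": [0.5, 0.8, 1.0],
    "min_child_weight": [1, 3, 5],
}


@dataclass
class RfeConfig:
    """Tunable parameters of a selection run (defaults are the tool's)."""

    elimination_fraction: float = 0.10
    auc_drop_threshold: float = 0.1
    absolute_drop: bool = False
    stage2_cap: int = 30
    force_stage2: bool = True
    n_simulations: int = 3
    cv_folds: int = 5
    bootstrap_on: bool = False
    noisy_on: bool = False
    n_replicates: int = 2
    noise_scale: float = 1.0
    final_test_fraction: float = 0.3
    internal_test_fraction: float = 0.3
    considered_classes: list[str] | None = None
    n_grid_draws: int = 20
    final_cv_repeats: int = 2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.elimination_fraction < 1.0:
            raise ValueError("elimination_fraction must be in (0,1)")
        if self.stage2_cap < 1:
            raise ValueError("stage2_cap must be >= 1")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be >= 0")


@dataclass
class IterationRecord:
    """One elimination round: survivors, what left, and the CV score."""

    n_features: int
    surviving: list[str]
    removed: list[str]
    tied: list[str]
    cv_auc_mean: float
    cv_auc_sd: float
    cv_micro_mean: float


@dataclass
class EliminationTrace:
    """Elimination history: one list of records per pass ("rfecv iteration").

    Each pass charts CV AUC against the shrinking feature count; the
    per-pass curves are what the scalability plots show.
    """

    passes: list[list[IterationRecord]] = field(default_factory=list)

    @property
    def iterations(self) -> list[IterationRecord]:
        """All records across passes, in execution order."""
        return [rec for p in self.passes for rec in p]

    def pass_frame(self, j: int) -> pd.DataFrame:
        recs = self.passes[j]
        return pd.DataFrame(
            {
                "n_features": [r.n_features for r in recs],
                "cv_roc_auc_ovo_weighted_mean": [r.cv_auc_mean for r in recs],
                "cv_roc_auc_ovo_weighted_sd": [r.cv_auc_sd for r in recs],
                "cv_roc_auc_micro_mean": [r.cv_micro_mean for r in recs],
            }
        )


@dataclass
class CvResult:
    auc_mean: float
    auc_sd: float
    micro_mean: float
    gains: dict[str, float]
    oof_true: np.ndarray | None = None          # out-of-fold labels
    oof_proba: np.ndarray | None = None         # out-of-fold class probabilities
    fold_reports: list[evaluation.EvaluationReport] = field(default_factory=list)


@dataclass
class SimulationResult:
    index: int
    train: list[str]
    internal_test: list[str]
    optimal_features: list[str]
    stage2_features: list[str] | None
    selected_features: list[str]
    stage1_trace: EliminationTrace
    stage2_trace: EliminationTrace | None
    grid2_params: dict
    grid2_train_report: evaluation.EvaluationReport
    grid2_test_report: evaluation.EvaluationReport


@dataclass
class SelectionResult:
    simulations: list[SimulationResult]
    golden_features: list[str]
    final_params: dict
    final_model: xgb.XGBClassifier
    final_thresholds: dict[str, float]
    final_test_report: evaluation.EvaluationReport
    final_cv_report: CvResult
    split_plan: SplitPlan
    classes: list[str]
    #: every sample id that ever entered a model fit / noise model /
    #: threshold choice — the anti-leakage audit trail
    fit_sample_ids: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------


def make_classifier(params: dict | None = None, seed: int = 0) -> xgb.XGBClassifier:
    """A boosted-tree classifier with the pipeline's fixed plumbing.

    Histogram tree growth, single thread, log-loss objective; missing
    values pass straight through to the tree's default-direction
    handling — never imputed.
    """
    merged = dict(STAGE_PARAMS)
    if params:
        merged.update(params)
    return xgb.XGBClassifier(
        **merged,
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed) % (2**31),
        verbosity=0,
        eval_metric="logloss",
    )


def _encode(classes: Sequence[str], labels: pd.Series) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    return np.asarray([index[l] for l in labels], dtype=int)


def cv_fit_and_score(
    matrix: ExpressionMatrix,
    train_samples: Sequence[str],
    features: Sequence[str],
    folds: Sequence[Sequence[str]],
    config: RfeConfig,
    seed: int,
    params: dict | None = None,
    collect_oof: bool = False,
    audit: set[str] | None = None,
) -> CvResult:
    """Stratified cross-validation of one feature set.

    Fits one booster per fold on the fold-train side (augmented there,
    and only there, when the bootstrap flags are on), scores the
    validation side with the one-vs-one weighted and micro ROC AUC, and
    accumulates each feature's total split gain across the fold models.
    """
    features = list(features)
    if not features:
        raise ValueError("cv_fit_and_score needs a non-empty feature set")
    classes = sorted(set(matrix.classes.loc[list(train_samples)]))
    if len(classes) < 2:
        raise ValueError("cross-validation needs >= 2 classes in train")
    # one dense view per call; per-fold work is plain row slicing
    sub = matrix.data[features]
    X = np.ascontiguousarray(sub.to_numpy())
    row_of = {s: i for i, s in enumerate(sub.index)}
    y_all = _encode(classes, matrix.classes.loc[sub.index])
    aucs, micros = [], []
    gains: dict[str, float] = {f: 0.0 for f in features}
    oof_true: list[np.ndarray] = []
    oof_proba: list[np.ndarray] = []
    train_set = set(train_samples)
    for fold_idx, valid_ids in enumerate(folds):
        valid_ids = list(valid_ids)
        fit_ids = sorted(train_set - set(valid_ids))
        fit_rows = [row_of[s] for s in fit_ids]
        X_fit = X[fit_rows]
        y_fit = y_all[fit_rows]
        if config.bootstrap_on:
            fold_train = ExpressionMatrix(
                pd.DataFrame(X_fit, index=fit_ids, columns=features),
                matrix.classes.loc[fit_ids],
            )
            model = fit_noise_model(fold_train)
            scale = config.noise_scale if config.noisy_on else 0.0
            fold_train = bootstrap_augment(
                fold_train, model, config.n_replicates, scale,
                seed=seed * 1000 + fold_idx,
            )
            X_fit = fold_train.data.to_numpy()
            y_fit = _encode(classes, fold_train.classes)
        if audit is not None:
            audit.update(fit_ids)
        clf = make_classifier(params, seed=seed * 100 + fold_idx)
        if len(set(y_fit)) < 2:
            raise ValueError(f"fold {fold_idx} lost a class; check stratification")
        clf.fit(X_fit, y_fit)
        valid_rows = [row_of[s] for s in valid_ids]
        proba = clf.predict_proba(X[valid_rows])
        y_valid = matrix.classes.loc[valid_ids].to_numpy()
        aucs.append(evaluation.ovo_weighted_auc(y_valid, proba, classes))
        micros.append(evaluation.micro_auc(y_valid, proba, classes))
        if collect_oof:
            oof_true.append(y_valid)
            oof_proba.append(proba)
        # positional names (f0, f1, ...) map back to the feature list
        booster_gain = clf.get_booster().get_score(importance_type="total_gain")
        for name, g in booster_gain.items():
            gains[features[int(name[1:])]] = gains.get(features[int(name[1:])], 0.0) + float(g)
    return CvResult(
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        micro_mean=float(np.mean(micros)),
        gains=gains,
        oof_true=np.concatenate(oof_true) if collect_oof else None,
        oof_proba=np.vstack(oof_proba) if collect_oof else None,
    )


def rank_and_eliminate(
    gains: dict[str, float],
    surviving: Sequence[str],
    fraction: float,
    max_remove: int | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Drop the lowest-gain ``ceil(fraction * n)`` features.

    Returns (kept, removed, tied): *tied* are kept features whose gain
    exactly equals the best gain among the removed — they stay in play
    and are re-ranked next round instead of being silently lost to an
    arbitrary tie-break.  Gain ties break by the caller's current column
    order (stable sort): deterministic, and the per-simulation column
    shuffle therefore varies which tied feature leaves first, instead of
    a fixed alphabetical bias deciding every simulation the same way.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"elimination fraction must be in (0,1), got {fraction}")
    surviving = list(surviving)
    if not surviving:
        raise ValueError("no surviving features to rank")
    r = ceil(fraction * len(surviving))
    if max_remove is not None:
        r = min(r, max_remove)
    r = max(r, 1)
    ranked = sorted(surviving, key=lambda f: gains.get(f, 0.0))
    removed = ranked[:r]
    kept = ranked[r:]
    max_removed = max(gains.get(f, 0.0) for f in removed)
    tied = [f for f in kept if abs(gains.get(f, 0.0) - max_removed) <= TIE_TOLERANCE]
    # preserve the caller's feature order for the kept set
    kept_set = set(kept)
    kept_ordered = [f for f in surviving if f in kept_set]
    return kept_ordered, removed, tied


def _significant_drop(prev: float, current: float, config: RfeConfig) -> bool:
    if config.absolute_drop:
        return current < prev - config.auc_drop_threshold
    return current < prev - config.auc_drop_threshold * current


def eliminate_path(
    matrix: ExpressionMatrix,
    train_samples: Sequence[str],
    features: Sequence[str],
    folds: Sequence[Sequence[str]],
    config: RfeConfig,
    seed: int,
    stop_size: int = 1,
    audit: set[str] | None = None,
) -> list[IterationRecord]:
    """One full elimination pass: score, drop the worst 10%, repeat.

    Runs from the given feature set down to ``stop_size`` features,
    scoring every intermediate set; the returned records are the AUC vs
    feature-count curve of this pass.
    """
    surviving = list(features)
    if not surviving:
        raise ValueError("elimination pass needs at least 1 feature")
    path: list[IterationRecord] = []
    step = 0
    while True:
        res = cv_fit_and_score(
            matrix, train_samples, surviving, folds, config,
            seed=seed + step, audit=audit,
        )
        if len(surviving) <= stop_size:
            path.append(IterationRecord(
                len(surviving), list(surviving), [], [],
                res.auc_mean, res.auc_sd, res.micro_mean,
            ))
            return path
        n_over = len(surviving) - stop_size
        kept, removed, tied = rank_and_eliminate(
            res.gains, surviving, config.elimination_fraction, max_remove=n_over,
        )
        path.append(IterationRecord(
            len(surviving), list(surviving), removed, tied,
            res.auc_mean, res.auc_sd, res.micro_mean,
        ))
        surviving = kept
        step += 1


def _best_record(path: Sequence[IterationRecord]) -> IterationRecord:
    """The pass's best-performing subset: highest CV AUC, parsimony on ties."""
    return min(path, key=lambda r: (-r.cv_auc_mean, r.n_features))


def run_stage1(
    matrix: ExpressionMatrix,
    train_samples: Sequence[str],
    features: Sequence[str],
    folds: Sequence[Sequence[str]],
    config: RfeConfig,
    seed: int,
    audit: set[str] | None = None,
) -> tuple[list[str], EliminationTrace]:
    """Repeat elimination passes until one loses significantly.

    Each pass eliminates from its starting set down to one feature and
    returns the best-performing subset along the way; the next pass
    restarts from that subset.  When a pass's best CV AUC drops
    significantly below the previous pass's, the feature list still
    considered before the loss (the losing pass's starting set) is the
    optimal set.  Termination is guaranteed: starting sets shrink
    strictly, so either the loss fires or a single feature remains.
    """
    current = list(features)
    if len(current) < 2:
        raise ValueError("stage 1 needs at least 2 features")
    trace = EliminationTrace()
    prev_best: float | None = None
    j = 0
    while True:
        path = eliminate_path(
            matrix, train_samples, current, folds, config,
            seed=seed + 10000 * j, audit=audit,
        )
        trace.passes.append(path)
        best = _best_record(path)
        if prev_best is not None and _significant_drop(prev_best, best.cv_auc_mean, config):
            return current, trace
        if len(best.surviving) >= len(current) or len(best.surviving) == 1:
            # no shrink possible (peak at the start) or nothing left to try
            return list(best.surviving), trace
        prev_best = best.cv_auc_mean
        current = list(best.surviving)
        j += 1


def run_stage2(
    matrix: ExpressionMatrix,
    train_samples: Sequence[str],
    optimal_features: Sequence[str],
    folds: Sequence[Sequence[str]],
    config: RfeConfig,
    seed: int,
    audit: set[str] | None = None,
) -> tuple[list[str], EliminationTrace]:
    """Force elimination onward (no stopping rule) to ``stage2_cap`` features."""
    surviving = list(optimal_features)
    trace = EliminationTrace()
    if len(surviving) <= config.stage2_cap:
        return surviving, trace
    path = eliminate_path(
        matrix, train_samples, surviving, folds, config,
        seed=seed + 777_000, stop_size=config.stage2_cap, audit=audit,
    )
    trace.passes.append(path)
    return list(path[-1].surviving), trace


def hyperparameter_search(
    matrix: ExpressionMatrix,
    train_samples: Sequence[str],
    features: Sequence[str],
    folds: Sequence[Sequence[str]],
    config: RfeConfig,
    n_draws: int,
    seed: int,
    grid: dict[str, list] | None = None,
    audit: set[str] | None = None,
) -> tuple[dict, CvResult]:
    """Random-grid search: best mean CV one-vs-one weighted ROC AUC wins.

    Draws ``n_draws`` parameter combinations uniformly from the grid
    (deterministic given ``seed``; ties keep the earliest draw) and
    returns the winning parameters together with that winner's CV result
    including out-of-fold predictions (used downstream for threshold
    tuning).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(seed)
    keys = sorted(grid)
    best_params: dict | None = None
    best_score = -np.inf
    for _ in range(n_draws):
        params = {k: grid[k][rng.integers(len(grid[k]))] for k in keys}
        res = cv_fit_and_score(
            matrix, train_samples, features, folds, config,
            seed=seed, params=params, audit=audit,
        )
        if res.auc_mean > best_score:
            best_score = res.auc_mean
            best_params = params
    assert best_params is not None
    winner = cv_fit_and_score(
        matrix, train_samples, features, folds, config,
        seed=seed, params=best_params, collect_oof=True, audit=audit,
    )
    return best_params, winner


def _thresholds_from_oof(res: CvResult, classes: list[str]) -> dict[str, float]:
    """Per-class one-vs-rest optimal thresholds from out-of-fold predictions."""
    curves = evaluation.roc_curve_and_auc(res.oof_true, res.oof_proba, "per_class", classes)
    out = {}
    for label, curve in curves.items():
        thr = evaluation.optimal_threshold(curve)
        out[label] = float(min(max(thr, 0.0), 1.0))
    return out


def monte_carlo_select(
    matrix: ExpressionMatrix,
    groups: ReplicateGroups | None = None,
    config: RfeConfig | None = None,
    final_test_ids: Sequence[str] | None = None,
) -> SelectionResult:
    """Run the full Monte-Carlo selection and final evaluation.

    ``final_test_ids`` may pin the held-out test set externally (the
    synthetic benchmark uses this to score every method on an identical
    split); by default it is drawn here, stratified and group-atomic.
    """
    config = config or RfeConfig()
    groups = groups or ReplicateGroups({})
    if matrix.classes is None:
        raise ValueError("selection requires class labels")
    work = matrix
    if config.considered_classes:
        keep = [s for s in work.sample_ids
                if work.classes.loc[s] in set(config.considered_classes)]
        work = work.subset(samples=keep)
    classes = sorted(set(work.classes))
    if len(classes) < 2:
        raise ValueError("selection requires at least 2 classes")
    by_class = {}
    for s in work.sample_ids:
        by_class.setdefault(work.classes.loc[s], set()).add(groups.group_of(s))
    thin = [c for c, g in by_class.items() if len(g) < 2]
    if thin:
        raise ValueError(f"classes with < 2 replicate groups: {sorted(thin)}")

    audit: set[str] = set()
    seed = config.master_seed

    if final_test_ids is None:
        rest, final_test = stratified_group_split(
            work.sample_ids, work.classes, config.final_test_fraction, groups, seed,
        )
    else:
        final_test = sorted(final_test_ids)
        rest = sorted(set(work.sample_ids) - set(final_test))
    plan = SplitPlan(final_test=list(final_test), seed=seed)

    simulations: list[SimulationResult] = []
    for i in range(config.n_simulations):
        sim_seed = seed + 1 + i
        rng = np.random.default_rng(sim_seed)
        shuffled = [work.feature_ids[j] for j in rng.permutation(work.n_features)]
        train, internal_test = stratified_group_split(
            rest, work.classes.loc[rest], config.internal_test_fraction, groups, sim_seed,
        )
        folds = stratified_group_kfold(
            train, work.classes.loc[train], config.cv_folds, groups, sim_seed,
        )
        plan.simulations.append(
            {"train": train, "internal_test": internal_test,
             "cv_folds": [list(f) for f in folds]}
        )
        optimal, trace1 = run_stage1(
            work, train, shuffled, folds, config, seed=sim_seed * 100, audit=audit,
        )
        stage2: list[str] | None = None
        trace2 = None
        if config.force_stage2 and len(optimal) > config.stage2_cap:
            stage2, trace2 = run_stage2(
                work, train, optimal, folds, config, seed=sim_seed * 100, audit=audit,
            )
        selected = stage2 if stage2 is not None else optimal
        grid2_params, grid2_cv = hyperparameter_search(
            work, train, selected, folds, config, config.n_grid_draws,
            seed=sim_seed * 100 + 7, audit=audit,
        )
        thresholds = _thresholds_from_oof(grid2_cv, classes)
        clf = make_classifier(grid2_params, seed=sim_seed)
        fit_matrix = work.subset(train, selected)
        if config.bootstrap_on:
            noise = fit_noise_model(fit_matrix)
            scale = config.noise_scale if config.noisy_on else 0.0
            fit_matrix = bootstrap_augment(
                fit_matrix, noise, config.n_replicates, scale, seed=sim_seed,
            )
        audit.update(train)
        clf.fit(fit_matrix.data, _encode(classes, fit_matrix.classes))
        train_eval = work.subset(train, selected)
        test_eval = work.subset(internal_test, selected)
        train_report = evaluation.evaluate_split(
            "grid2_train", train_eval.classes.to_numpy(),
            clf.predict_proba(train_eval.data), classes, thresholds,
        )
        test_report = evaluation.evaluate_split(
            "grid2_internal_test", test_eval.classes.to_numpy(),
            clf.predict_proba(test_eval.data), classes, thresholds,
        )
        simulations.append(SimulationResult(
            index=i, train=list(train), internal_test=list(internal_test),
            optimal_features=list(optimal), stage2_features=stage2,
            selected_features=list(selected), stage1_trace=trace1,
            stage2_trace=trace2, grid2_params=grid2_params,
            grid2_train_report=train_report, grid2_test_report=test_report,
        ))
        logger.info(
            "simulation %d: |optimal|=%d |selected|=%d grid2 internal-test "
            "micro AUC=%.3f", i, len(optimal), len(selected), test_report.micro_auc,
        )

    golden = sorted(set().union(*(s.selected_features for s in simulations)))

    # final model: repeated k-fold CV hyperparameter search on everything
    # except the final test set, then one evaluation on the final test set
    rest_classes = work.classes.loc[rest]
    rep_folds: list[list[str]] = []
    for rep in range(config.final_cv_repeats):
        rep_folds.extend(
            stratified_group_kfold(rest, rest_classes, config.cv_folds, groups,
                                   seed + 900 + rep)
        )
    final_params, final_cv = hyperparameter_search(
        work, rest, golden, rep_folds, config, config.n_grid_draws,
        seed=seed + 999, audit=audit,
    )
    final_thresholds = _thresholds_from_oof(final_cv, classes)
    final_clf = make_classifier(final_params, seed=seed + 999)
    fit_matrix = work.subset(rest, golden)
    if config.bootstrap_on:
        noise = fit_noise_model(fit_matrix)
        scale = config.noise_scale if config.noisy_on else 0.0
        fit_matrix = bootstrap_augment(
            fit_matrix, noise, config.n_replicates, scale, seed=seed + 999,
        )
    audit.update(rest)
    final_clf.fit(fit_matrix.data, _encode(classes, fit_matrix.classes))
    test_matrix = work.subset(final_test, golden)
    final_report = evaluation.evaluate_split(
        "final_test", test_matrix.classes.to_numpy(),
        final_clf.predict_proba(test_matrix.data), classes, final_thresholds,
    )
    logger.info(
        "final model on %d golden features: test micro AUC=%.3f",
        len(golden), final_report.micro_auc,
    )
    return SelectionResult(
        simulations=simulations,
        golden_features=golden,
        final_params=final_params,
        final_model=final_clf,
        final_thresholds=final_thresholds,
        final_test_report=final_report,
        final_cv_report=final_cv,
        split_plan=plan,
        classes=classes,
        fit_sample_ids=audit,
    )
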