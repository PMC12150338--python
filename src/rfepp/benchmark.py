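"""Synthetic high-dimensional benchmark: two-moons + Gaussian noise features.

The benchmark emulates the hard case of omics feature selection: a
nonlinearly separable phenotype signal carried by exactly two features,
buried under thousands of uninformative ones.  Two interleaving
half-circles (40 samples per class by default) provide the signal; every
additional column is i.i.d. standard normal noise.  Five methods compete
on an identical stratified 70/30 split per seed, scored by
micro-averaged test ROC AUC:

* ``rfepp`` — the full Monte-Carlo selection with its final-model score,
* ``rfecv_lr`` / ``rfecv_gbt`` — standard cross-validated recursive
  feature elimination around logistic regression / boosted trees,
* ``lr`` / ``gbt`` — the same learners fitted on all features at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.datasets import make_moons
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import evaluation
from .io_tables import ExpressionMatrix
from .rfe_core import RfeConfig, make_classifier, monte_carlo_select

logger = logging.getLogger(__name__)

METHODS = ("rfepp", "rfecv_lr", "rfecv_gbt", "lr", "gbt")


@dataclass(frozen=True)
class MoonsSpec:
    """Study conditions of the synthetic benchmark (defaults are the
    published setting: 80 samples, 2 informative + 5000 noise features)."""

    n_samples: int = 80
    moons_noise: float = 0.2
    n_noise_features: int = 5000
    test_fraction: float = 0.3
    seed: int = 0


def generate_moons_highdim(spec: MoonsSpec) -> ExpressionMatrix:
    """Generate the benchmark matrix: 2 moon coordinates + standard-normal noise.

    Columns 1–2 (``moon_1``, ``moon_2``) carry the class signal; the
    remaining columns are N(0, 1) draws.  Classes are balanced for even
    ``n_samples``, there are no missing cells, and the output is fully
    determined by ``spec.seed``.
    """
    if spec.n_samples < 4:
        raise ValueError("need at least 4 samples")
    xy, labels = make_moons(
        n_samples=spec.n_samples, noise=spec.moons_noise, random_state=spec.seed
    )
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.n_samples, spec.n_noise_features))
    width = len(str(max(spec.n_noise_features, 1)))
    columns = ["moon_1", "moon_2"] + [
        f"noise_{i + 1:0{width}d}" for i in range(spec.n_noise_features)
    ]
    data = pd.DataFrame(
        np.hstack([xy, noise]),
        index=pd.Index([f"sample_{i + 1:03d}" for i in range(spec.n_samples)],
                       name="files"),
        columns=columns,
    )
    classes = pd.Series([f"class_{l}" for l in labels], index=data.index, dtype=str)
    return ExpressionMatrix(data, classes)


def _split(matrix: ExpressionMatrix, spec: MoonsSpec, seed: int):
    train_ids, test_ids = train_test_split(
        matrix.sample_ids,
        test_size=spec.test_fraction,
        stratify=matrix.classes.to_numpy(),
        random_state=seed,
    )
    return sorted(train_ids), sorted(test_ids)


def _score(model, matrix: ExpressionMatrix, test_ids, classes, features=None) -> float:
    test = matrix.subset(test_ids, features)
    proba = model.predict_proba(test.data)
    return evaluation.micro_auc(test.classes.to_numpy(), proba, classes)


def run_benchmark(
    spec: MoonsSpec | None = None,
    methods: tuple[str, ...] = METHODS,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    rfecv_step: float | int = 1,
    rfe_config: RfeConfig | None = None,
) -> pd.DataFrame:
    """Run the model comparison; returns rows of (method, seed, micro_auc).

    Per seed, one dataset is generated and one stratified split is fixed;
    every requested method trains on the identical training portion and
    is scored on the identical test portion, which never influences any
    fit.  ``rfecv_step`` is the per-iteration removal for the standard
    RFECV comparators (1 = the textbook one-feature-at-a-time; a
    fraction removes that share of the remaining features per round).
    """
    spec = spec or MoonsSpec()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not methods:
        raise ValueError("no methods requested")
    rows = []
    for seed in seeds:
        matrix = generate_moons_highdim(replace(spec, seed=seed))
        classes = sorted(set(matrix.classes))
        train_ids, test_ids = _split(matrix, spec, seed)
        train = matrix.subset(train_ids)
        y_train = train.classes.map({c: i for i, c in enumerate(classes)}).to_numpy()
        for method in methods:
            auc, extras = _run_one(
                method, matrix, train, y_train, test_ids, classes, seed,
                rfecv_step, rfe_config,
            )
            logger.info("seed=%d method=%s micro AUC=%.3f", seed, method, auc)
            rows.append({"method": method, "seed": seed, "micro_auc": auc, **extras})
    return pd.DataFrame(rows)


def _run_one(method, matrix, train, y_train, test_ids, classes, seed,
             rfecv_step, rfe_config) -> tuple[float, dict]:
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    if method == "rfepp":
        config = rfe_config or RfeConfig()
        config = replace(config, master_seed=seed)
        result = monte_carlo_select(matrix, config=config, final_test_ids=test_ids)
        extras = {
            "n_selected": len(result.golden_features),
            "selected_features": ";".join(result.golden_features),
        }
        return result.final_test_report.micro_auc, extras
    if method == "lr":
        model = LogisticRegression(max_iter=2000).fit(train.data, y_train)
        return _score(model, matrix, test_ids, classes), {}
    if method == "gbt":
        model = make_classifier(seed=seed).fit(train.data, y_train)
        return _score(model, matrix, test_ids, classes), {}
    if method == "rfecv_lr":
        selector = RFECV(LogisticRegression(max_iter=2000), step=rfecv_step,
                         cv=cv, scoring="roc_auc", n_jobs=1)
    elif method == "rfecv_gbt":
        selector = RFECV(make_classifier(seed=seed), step=rfecv_step,
                         cv=cv, scoring="roc_auc", n_jobs=1)
    else:  # pragma: no cover - guarded in run_benchmark
        raise ValueError(method)
    selector.fit(train.data, y_train)
    chosen = [f for f, keep in zip(train.feature_ids, selector.support_) if keep]
    refit = selector.estimator_
    extras = {"n_selected": len(chosen), "selected_features": ";".join(chosen)}
    return _score(refit, matrix, test_ids, classes, features=chosen), extras


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd micro AUC per method, plus the relative-improvement statistic
    of the Monte-Carlo selector over the best comparator when present."""
    agg = table.groupby("method")["micro_auc"].agg(["mean", "std", "count"])
    if "rfepp" in agg.index and len(agg) > 1:
        best_other = agg.drop(index="rfepp")["mean"].max()
        agg.loc["rfepp", "relative_improvement"] = (
            agg.loc["rfepp", "mean"] / best_other - 1.0
        )
    return agg
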