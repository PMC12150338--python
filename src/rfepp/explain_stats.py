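"""Post-selection statistics: attributions, correlations, volcano tables,
embeddings and clustering summaries.

Everything here backs a figure the tool emits, but each function returns
plain tables so results are testable without parsing plots.  Missing
values are handled per operation: attribution and correlation work on
the observed data (trees and Kendall both tolerate gaps), while volcano
statistics and embeddings use per-feature observed-minimum imputation —
a conservative stand-in for "below detection limit" abundances.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_tables import ExpressionMatrix

logger = logging.getLogger(__name__)


# -- attribution --------------------------------------------------------


@dataclass
class AttributionTable:
    """Additive per-sample, per-feature attributions toward the prediction.

    ``values``: samples x features frame of tree-path (Shapley-style)
    contributions for the sample's predicted class; ``base_values``: the
    per-sample expected margin; ``ranking``: features sorted by mean
    absolute attribution, strongest first.
    """

    values: pd.DataFrame
    base_values: pd.Series
    ranking: list[str]

    def mean_abs(self) -> pd.Series:
        return self.values.abs().mean().sort_values(ascending=False)


def attribution_ranking(
    model: xgb.XGBClassifier, matrix: ExpressionMatrix, features: list[str]
) -> AttributionTable:
    """Tree-path additive attributions on the given samples.

    Uses the booster's exact tree-traversal Shapley computation; the
    attributions of a sample plus its base value reconstruct the model's
    margin output, so importance here is an additive decomposition of
    the actual predictions, not an ensemble-global statistic.  For
    multiclass models the contributions toward each sample's predicted
    class are reported.
    """
    booster = model.get_booster()
    if list(booster.feature_names) != list(features):
        raise ValueError("model was not fitted on exactly these features")
    data = matrix.data[features]
    dmat = xgb.DMatrix(data, missing=np.nan, feature_names=list(features))
    contribs = booster.predict(dmat, pred_contribs=True)
    if contribs.ndim == 3:  # multiclass: (samples, classes, features+1)
        pred_class = model.predict(data)
        rows = contribs[np.arange(len(data)), pred_class.astype(int), :]
    else:
        rows = contribs
    values = pd.DataFrame(rows[:, :-1], index=data.index, columns=features)
    base = pd.Series(rows[:, -1], index=data.index, name="base_value")
    ranking = list(values.abs().mean().sort_values(ascending=False).index)
    return AttributionTable(values=values, base_values=base, ranking=ranking)


# -- correlation --------------------------------------------------------


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction and two-sided p.

    Pairs with a missing value in either vector are dropped; fewer than
    two complete pairs yields ``(nan, nan)`` with a logged warning.  The
    p-value uses exact enumeration for small samples without ties and
    the normal approximation otherwise (scipy's default policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        logger.warning("kendall_tau: fewer than 2 complete pairs")
        return float("nan"), float("nan")
    res = sps.kendalltau(x[ok], y[ok], method="auto")
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_golden_to_all(
    matrix: ExpressionMatrix,
    golden_features: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kendall correlation of every golden feature against every other feature.

    All golden x other pairs form one multiple-testing family; rows with
    a BH-adjusted p below ``alpha`` are returned (columns: golden_feature,
    feature, kendall_tau, p_value, p_adjusted).  A feature is never
    correlated with itself.
    """
    if not golden_features:
        raise ValueError("no golden features to correlate")
    rows = []
    data = matrix.data
    for g in golden_features:
        gv = data[g].to_numpy()
        for other in matrix.feature_ids:
            if other == g:
                continue
            tau, p = kendall_tau(gv, data[other].to_numpy())
            rows.append((g, other, tau, p))
    table = pd.DataFrame(rows, columns=["golden_feature", "feature", "kendall_tau", "p_value"])
    complete = table["p_value"].notna()
    adjusted = np.full(len(table), np.nan)
    if complete.any():
        adjusted[complete.to_numpy()] = benjamini_hochberg(table.loc[complete, "p_value"])
    table["p_adjusted"] = adjusted
    kept = table[table["p_adjusted"] < alpha].reset_index(drop=True)
    return kept


# -- volcano ------------------------------------------------------------


def _impute_minimum(data: pd.DataFrame, global_minimum: bool = False) -> pd.DataFrame:
    """Fill missing cells with the observed minimum (per feature by default)."""
    if global_minimum:
        return data.fillna(np.nanmin(data.to_numpy()))
    return data.fillna(data.min())


def volcano_stats(
    matrix: ExpressionMatrix,
    features: list[str] | None = None,
    global_minimum: bool = False,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest volcano tables, one per class.

    Per feature: effect = mean(class) − mean(rest) after minimum-value
    imputation (values are assumed already log-scale), p from a
    two-sided Mann–Whitney U test, BH adjustment within the table.  The
    multiple-testing family is whatever feature list is passed, so a
    selected-features table is corrected over a smaller family than an
    all-features table.  In a two-class run the two one-vs-rest tables
    would mirror each other, so only one contrast (first class vs the
    other) is emitted.
    """
    if matrix.classes is None:
        raise ValueError("volcano statistics require class labels")
    classes = sorted(set(matrix.classes))
    if len(classes) < 2:
        raise ValueError("volcano statistics require >= 2 classes")
    features = list(features) if features is not None else matrix.feature_ids
    all_missing = [f for f in features if matrix.data[f].isna().all()]
    if all_missing:
        logger.warning("dropping %d feature(s) missing in all samples", len(all_missing))
        features = [f for f in features if f not in set(all_missing)]
    data = _impute_minimum(matrix.data[features], global_minimum)
    labels = matrix.classes
    out: dict[str, pd.DataFrame] = {}
    contrasts = classes[:1] if len(classes) == 2 else classes
    for label in contrasts:
        in_class = (labels == label).to_numpy()
        effects, ps = [], []
        for f in features:
            a = data[f].to_numpy()[in_class]
            b = data[f].to_numpy()[~in_class]
            effects.append(float(a.mean() - b.mean()))
            if np.all(a[0] == a) and np.all(b[0] == b) and a[0] == b[0]:
                ps.append(1.0)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ps.append(float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue))
        table = pd.DataFrame({
            "feature": features,
            "effect": effects,
            "p_value": ps,
            "p_adjusted": benjamini_hochberg(ps),
        })
        out[label] = table
    return out


# -- embeddings ---------------------------------------------------------


def embed(
    matrix: ExpressionMatrix,
    features: list[str] | None = None,
    method: str = "pca",
    seed: int = 0,
) -> pd.DataFrame:
    """2-D per-sample coordinates for class-separability inspection.

    ``method='pca'`` (deterministic up to sign) or ``'umap'`` (seeded;
    requires the optional umap-learn dependency).  Missing cells are
    minimum-imputed for the embedding only — the matrix itself is never
    modified.
    """
    if matrix.n_samples < 3:
        raise ValueError("embedding needs at least 3 samples")
    data = _impute_minimum(matrix.data[features] if features else matrix.data)
    if method == "pca":
        spread = data.to_numpy().std()
        if spread == 0:
            raise ValueError("constant matrix has no principal components")
        coords = PCA(n_components=2, random_state=seed).fit_transform(data)
        cols = ["PC1", "PC2"]
    elif method == "umap":
        import umap  # optional extra

        coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(data)
        cols = ["UMAP1", "UMAP2"]
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=data.index, columns=cols)


# -- clustering / distributions ----------------------------------------


def cluster_and_boxplot_tables(
    matrix: ExpressionMatrix, golden_features: list[str]
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Average-linkage clustering of the selected features + class summaries.

    Features are clustered on correlation distance (1 − Pearson r over
    minimum-imputed values), so co-regulated features merge early and
    anti-correlated ones last.  Returns (linkage matrix, leaf order,
    per-feature-per-class five-number summary table).
    """
    if not golden_features:
        raise ValueError("no selected features to cluster")
    data = _impute_minimum(matrix.data[golden_features])
    if len(golden_features) == 1:
        linkage = np.empty((0, 4))
        order = list(golden_features)
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(data.to_numpy().T)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
        order = [golden_features[i] for i in hierarchy.leaves_list(linkage)]
    rows = []
    if matrix.classes is not None:
        for f in golden_features:
            for label, chunk in data[f].groupby(matrix.classes):
                v = chunk.to_numpy()
                rows.append({
                    "feature": f, "class": label,
                    "min": v.min(), "q1": np.quantile(v, 0.25),
                    "median": np.quantile(v, 0.5),
                    "q3": np.quantile(v, 0.75), "max": v.max(),
                })
    summary = pd.DataFrame(rows)
    return linkage, order, summary
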