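"""End-to-end orchestration: read inputs, run the selection, write artifacts.

Every figure is emitted as a PDF together with a CSV twin of the same
stem carrying the underlying numbers, so downstream checks never have to
parse graphics.  A run manifest (config, inputs, checksums, emitted
files) and the split plan are written alongside for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__, evaluation, explain_stats
from .io_tables import (
    ExpressionMatrix,
    ReplicateGroups,
    log_transform,
    pivot_quant_report,
    read_class_annotations,
    read_expression_table,
    read_quant_report,
    read_replicate_annotations,
)
from .rfe_core import RfeConfig, SelectionResult, monte_carlo_select

logger = logging.getLogger(__name__)

LOG_FILE = "rfePlusPlusLog.txt"


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _save_fig(fig, path: Path, emitted: list[str]) -> None:
    fig.savefig(path)
    plt.close(fig)
    emitted.append(path.name)


def _csv_twin(frame: pd.DataFrame, pdf_path: Path, emitted: list[str]) -> None:
    csv_path = pdf_path.with_suffix(".csv")
    frame.to_csv(csv_path, index=False)
    emitted.append(csv_path.name)


def _roc_figure(title: str, y_true, proba, classes):
    curves = evaluation.roc_curve_and_auc(y_true, proba, "per_class", classes)
    micro = evaluation.roc_curve_and_auc(y_true, proba, "micro", classes)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(micro.fpr, micro.tpr, label=f"micro (AUC={micro.auc:.3f})", lw=2)
    for label, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, lw=1, alpha=0.7,
                label=f"{label} (AUC={curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(fontsize=7)
    rows = [{"averaging": "micro", "auc": micro.auc}]
    rows += [{"averaging": f"ovr:{c}", "auc": rc.auc} for c, rc in curves.items()]
    return fig, pd.DataFrame(rows)


def _confusion_figure(title: str, report: evaluation.ScoreReport):
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xticks(range(len(report.classes)), report.classes, rotation=45, ha="right")
    ax.set_yticks(range(len(report.classes)), report.classes)
    for i in range(report.confusion.shape[0]):
        for j in range(report.confusion.shape[1]):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    frame = pd.DataFrame(report.confusion, index=report.classes, columns=report.classes)
    frame.insert(0, "true_class", report.classes)
    return fig, frame


def run_pipeline(
    expression_table: str | Path | None = None,
    class_annotations: str | Path | None = None,
    replicate_annotations: str | Path | None = None,
    quant_report: str | Path | None = None,
    feature_level: str = "protein",
    output_dir: str | Path = "rfepp_output",
    config: RfeConfig | None = None,
    log2: bool = False,
    pseudocount: float = 1.0,
    write_embeddings: bool = True,
) -> SelectionResult:
    """Full pipeline: read → (pivot/log) → select → evaluate → report.

    Either ``expression_table`` (matrix with a trailing ``class`` column)
    or ``quant_report`` + ``class_annotations`` must be given.  All
    artifacts land in ``output_dir``; console scores are mirrored to
    ``rfePlusPlusLog.txt`` there.
    """
    config = config or RfeConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / LOG_FILE, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("rfepp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    started = time.time()
    emitted: list[str] = [LOG_FILE]
    inputs: dict[str, str] = {}
    try:
        # ---- read -----------------------------------------------------
        if quant_report is not None:
            report = read_quant_report(quant_report)
            matrix = pivot_quant_report(report, feature_level)
            inputs["quant_report"] = _checksum(Path(quant_report))
            if class_annotations is None:
                raise ValueError("a quant report input requires class annotations")
        elif expression_table is not None:
            matrix = read_expression_table(expression_table)
            inputs["expression_table"] = _checksum(Path(expression_table))
        else:
            raise ValueError("provide an expression table or a quant report")
        if class_annotations is not None:
            annotation = read_class_annotations(class_annotations)
            extra = sorted(set(annotation) - set(matrix.sample_ids))
            if extra:
                logger.warning("ignoring %d annotated files absent from the matrix",
                               len(extra))
            matrix = matrix.with_classes(annotation)
            inputs["class_annotations"] = _checksum(Path(class_annotations))
        groups = ReplicateGroups({})
        if replicate_annotations is not None:
            groups = read_replicate_annotations(replicate_annotations)
            inputs["replicate_annotations"] = _checksum(Path(replicate_annotations))
        if log2:
            matrix = log_transform(matrix, pseudocount)
            logger.info("applied log2(x + %g) transform", pseudocount)

        # ---- select ---------------------------------------------------
        result = monte_carlo_select(matrix, groups, config)

        # ---- per-simulation artifacts ---------------------------------
        for sim in result.simulations:
            pd.Series(sim.optimal_features, name="feature").to_csv(
                out / f"optimal_features_{sim.index}.csv", index=False)
            emitted.append(f"optimal_features_{sim.index}.csv")
            if sim.stage2_features is not None:
                stem = f"stage_2_forced_reduced_features_with_best_performance{sim.index}"
                pd.Series(sim.stage2_features, name="feature").to_csv(
                    out / f"{stem}.csv", index=False)
                emitted.append(f"{stem}.csv")
            # one scalability plot per elimination pass: CV AUC vs feature count
            all_passes = list(sim.stage1_trace.passes)
            if sim.stage2_trace is not None:
                all_passes.extend(sim.stage2_trace.passes)
            for j, records in enumerate(all_passes):
                stem = f"rfecv_iter_{j}_sim_{sim.index}_cv_roc_auc_ovo_weighted"
                n_feat = [rec.n_features for rec in records]
                mean = [rec.cv_auc_mean for rec in records]
                sd = [rec.cv_auc_sd for rec in records]
                fig, ax = plt.subplots(figsize=(4, 3))
                ax.errorbar(n_feat, mean, yerr=sd, fmt="o-", ms=3, lw=1)
                ax.set_xlabel("number of features")
                ax.set_ylabel("CV ROC AUC (ovo weighted)")
                ax.set_title(f"simulation {sim.index}, elimination pass {j}")
                ax.set_ylim(0, 1.05)
                ax.invert_xaxis()
                fig.tight_layout()
                _save_fig(fig, out / f"{stem}.pdf", emitted)
                _csv_twin(pd.DataFrame({
                    "n_features": n_feat,
                    "cv_roc_auc_ovo_weighted_mean": mean,
                    "cv_roc_auc_ovo_weighted_sd": sd,
                }), out / f"{stem}.pdf", emitted)
            for split, report in (("train", sim.grid2_train_report),
                                  ("test", sim.grid2_test_report)):
                stem = f"grid2_{split}_ROC_AUC_relevant_features_{sim.index}"
                frame = pd.DataFrame(
                    [{"averaging": "micro", "auc": report.micro_auc},
                     {"averaging": "ovo_weighted", "auc": report.ovo_weighted_auc}]
                    + [{"averaging": f"ovr:{c}", "auc": a}
                       for c, a in report.per_class_auc.items()])
                fig, ax = plt.subplots(figsize=(4, 3))
                ax.bar(frame["averaging"], frame["auc"])
                ax.set_ylim(0, 1.05)
                ax.set_ylabel("ROC AUC")
                ax.set_title(stem)
                ax.tick_params(axis="x", rotation=45)
                fig.tight_layout()
                _save_fig(fig, out / f"{stem}.pdf", emitted)
                _csv_twin(frame, out / f"{stem}.pdf", emitted)
                cstem = f"confusion_matrix_Grid2_{split}_{sim.index}"
                fig, frame = _confusion_figure(cstem, report.scores)
                _save_fig(fig, out / f"{cstem}.pdf", emitted)
                _csv_twin(frame, out / (cstem + ".pdf"), emitted)
            logger.info(
                "simulation %d: grid2 train micro AUC=%.3f, internal test "
                "micro AUC=%.3f, test accuracy=%.3f, test MAVG_F1=%.3f, "
                "test WAVG_F1=%.3f",
                sim.index, sim.grid2_train_report.micro_auc,
                sim.grid2_test_report.micro_auc, sim.grid2_test_report.scores.accuracy,
                sim.grid2_test_report.scores.macro_f1,
                sim.grid2_test_report.scores.weighted_f1,
            )

        # ---- global artifacts -----------------------------------------
        pd.Series(result.golden_features, name="feature").to_csv(
            out / "golden_features.csv", index=False)
        emitted.append("golden_features.csv")
        result.final_model.get_booster().save_model(out / "final_XGB_model.json")
        emitted.append("final_XGB_model.json")
        result.split_plan.to_json(out / "split_plan.json")
        emitted.append("split_plan.json")

        final_test = result.split_plan.final_test
        test_matrix = matrix.subset(final_test, result.golden_features)
        proba = result.final_model.predict_proba(test_matrix.data)
        stem = "roc_auc_final_XGBclassifier_golden_features_test_performance"
        fig, frame = _roc_figure(stem, test_matrix.classes.to_numpy(), proba,
                                 result.classes)
        _save_fig(fig, out / f"{stem}.pdf", emitted)
        _csv_twin(frame, out / f"{stem}.pdf", emitted)

        attribution = explain_stats.attribution_ranking(
            result.final_model, test_matrix, result.golden_features)
        stem = "xgb_final_features_shap_test_performance"
        mean_abs = attribution.mean_abs()
        fig, ax = plt.subplots(figsize=(5, max(2, 0.25 * len(mean_abs))))
        ax.barh(list(mean_abs.index)[::-1], list(mean_abs.to_numpy())[::-1])
        ax.set_xlabel("mean |attribution| (margin units)")
        ax.set_title("feature contributions on the final test set")
        fig.tight_layout()
        _save_fig(fig, out / f"{stem}.pdf", emitted)
        mean_abs_frame = mean_abs.rename("mean_abs_attribution").reset_index()
        mean_abs_frame.columns = ["feature", "mean_abs_attribution"]
        _csv_twin(mean_abs_frame, out / f"{stem}.pdf", emitted)

        corr = explain_stats.correlate_golden_to_all(matrix, result.golden_features)
        corr.to_csv(out / "significant_high_correlated_features_of_golden_features.csv",
                    index=False)
        emitted.append("significant_high_correlated_features_of_golden_features.csv")

        volcano = explain_stats.volcano_stats(matrix)
        volcano_selected = explain_stats.volcano_stats(matrix, result.golden_features)
        for label, table in volcano.items():
            stem = f"volcano_all_features_{label}"
            _volcano_figure(table, stem, out, emitted)
        for label, table in volcano_selected.items():
            stem = f"volcano_golden_features_{label}"
            _volcano_figure(table, stem, out, emitted)

        if write_embeddings:
            for scope, feats in (("all", None), ("golden", result.golden_features)):
                coords = explain_stats.embed(matrix, feats, "pca")
                stem = f"pca_{scope}_features"
                fig, ax = plt.subplots(figsize=(4, 3.5))
                for label in result.classes:
                    mask = (matrix.classes == label).to_numpy()
                    ax.scatter(coords.iloc[mask, 0], coords.iloc[mask, 1],
                               s=12, label=label)
                ax.set_xlabel("PC1")
                ax.set_ylabel("PC2")
                ax.legend(fontsize=7)
                ax.set_title(stem)
                fig.tight_layout()
                _save_fig(fig, out / f"{stem}.pdf", emitted)
                coords.reset_index().to_csv(out / f"{stem}.csv", index=False)
                emitted.append(f"{stem}.csv")

        linkage, order, box = explain_stats.cluster_and_boxplot_tables(
            matrix, result.golden_features)
        box.to_csv(out / "golden_features_class_boxplot_stats.csv", index=False)
        emitted.append("golden_features_class_boxplot_stats.csv")
        pd.Series(order, name="feature").to_csv(
            out / "golden_features_cluster_order.csv", index=False)
        emitted.append("golden_features_cluster_order.csv")

        dist = evaluation.score_distributions({
            "grid2_internal_test/micro": [s.grid2_test_report.micro_auc
                                          for s in result.simulations],
            "grid2_internal_test/ovo_weighted": [s.grid2_test_report.ovo_weighted_auc
                                                 for s in result.simulations],
            "stage1_cv/ovo_weighted": [
                rec.cv_auc_mean for s in result.simulations
                for rec in s.stage1_trace.iterations],
        })
        dist.reset_index(names="category").to_csv(
            out / "score_distributions.csv", index=False)
        emitted.append("score_distributions.csv")

        logger.info(
            "final model: %d golden features, test micro AUC=%.3f, "
            "test ovo-weighted AUC=%.3f, accuracy=%.3f",
            len(result.golden_features), result.final_test_report.micro_auc,
            result.final_test_report.ovo_weighted_auc,
            result.final_test_report.scores.accuracy,
        )

        manifest = {
            "tool": "rfepp",
            "version": __version__,
            "config": asdict(config),
            "inputs": inputs,
            "master_seed": config.master_seed,
            "started": started,
            "finished": time.time(),
            "emitted_files": sorted(set(emitted)),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        return result
    finally:
        root.removeHandler(handler)
        handler.close()


def _volcano_figure(table: pd.DataFrame, stem: str, out: Path, emitted: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(4, 3.5))
    with np.errstate(divide="ignore"):
        ax.scatter(table["effect"], -np.log10(table["p_adjusted"]), s=6)
    ax.set_xlabel("mean difference (class − rest)")
    ax.set_ylabel("-log10 adjusted p")
    ax.set_title(stem)
    fig.tight_layout()
    _save_fig(fig, out / f"{stem}.pdf", emitted)
    _csv_twin(table, out / f"{stem}.pdf", emitted)
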