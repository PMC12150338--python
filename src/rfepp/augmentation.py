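"""Class-conditional bootstrap augmentation, confined to training folds.

Small cohorts and imbalanced classes destabilise fold-level training.
The augmentation here adds, for every original training sample, a fixed
number of temporary synthetic replicates: copies perturbed per feature
by Gaussian noise whose standard deviation is the empirical standard
deviation of that feature *within the sample's phenotype class*, fitted
only on the current fold-train samples.  Synthetic rows carry marked
identifiers and exist only for the duration of one fold fit — they can
never enter a validation or test set, which is the whole anti-leakage
point of doing this inside the fold rather than up front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import ExpressionMatrix

#: marker separating an original sample id from its synthetic-replicate tag
SYNTHETIC_TAG = "::boot"


@dataclass
class NoiseModel:
    """Per-(class, feature) Gaussian noise parameters.

    ``means``/``stds`` are class x feature frames; cells with fewer than
    two observed values get std 0 (their replicates copy the original),
    cells never observed keep a missing mean — replicates stay missing
    there too.
    """

    means: pd.DataFrame
    stds: pd.DataFrame
    counts: pd.DataFrame


def fit_noise_model(fold_train: ExpressionMatrix) -> NoiseModel:
    """Estimate per-(class, feature) mean/sd from fold-train samples only.

    The caller must pass a matrix restricted to the fold-train side;
    statistics computed here are the only thing the augmentation uses,
    so evaluation samples never influence the synthetic replicates.
    """
    if fold_train.n_samples == 0:
        raise ValueError("cannot fit a noise model on an empty fold")
    if fold_train.classes is None:
        raise ValueError("noise model requires class labels")
    grouped = fold_train.data.groupby(fold_train.classes)
    means = grouped.mean()
    stds = grouped.std(ddof=0)  # ML estimate of the class-conditional Gaussian
    counts = grouped.count()
    stds = stds.where(counts >= 2, 0.0).fillna(0.0)
    return NoiseModel(means=means, stds=stds, counts=counts)


def bootstrap_augment(
    fold_train: ExpressionMatrix,
    model: NoiseModel,
    n_replicates: int = 2,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Append ``n_replicates`` noisy synthetic copies of every training sample.

    Each synthetic cell is ``original + N(0, (noise_scale * sd)^2)`` with
    the class-conditional sd from ``model``; missing cells stay missing
    and synthetic rows inherit their source label.  ``noise_scale=0``
    yields exact copies (pure resampling weight); ``n_replicates=0`` is
    the identity.
    """
    if n_replicates < 0:
        raise ValueError(f"n_replicates must be >= 0, got {n_replicates}")
    if n_replicates == 0:
        return fold_train
    rng = np.random.default_rng(seed)
    blocks = [fold_train.data]
    labels = [fold_train.classes]
    assert fold_train.classes is not None
    sd_rows = model.stds.reindex(
        index=fold_train.classes, columns=fold_train.data.columns
    ).to_numpy()
    base = fold_train.data.to_numpy()
    for r in range(n_replicates):
        noise = rng.standard_normal(base.shape) * sd_rows * noise_scale
        synth = base + noise  # NaN + noise stays NaN
        ids = [f"{s}{SYNTHETIC_TAG}{r}" for s in fold_train.sample_ids]
        blocks.append(
            pd.DataFrame(synth, index=pd.Index(ids, name=fold_train.data.index.name),
                         columns=fold_train.data.columns)
        )
        labels.append(pd.Series(fold_train.classes.to_numpy(), index=ids, dtype=str))
    data = pd.concat(blocks)
    classes = pd.concat(labels)
    return ExpressionMatrix(data, classes)


def is_synthetic(sample_id: str) -> bool:
    """True for ids created by :func:`bootstrap_augment` (never evaluable)."""
    return SYNTHETIC_TAG in sample_id
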