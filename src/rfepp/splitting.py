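"""Class-stratified, replicate-group-atomic data splitting.

Related measurements (technical replicates of a patient, say) must never
be divided between training and evaluation data, or the evaluation leaks
training information and the reported performance is optimistic.  Every
partition produced here therefore operates on replicate *groups*: a
group's class is the (required-identical) class of its member samples,
stratification counts groups per class, and a group lands wholly on one
side of every split and wholly inside one cross-validation fold.

Singleton groups (no replicate annotation) reduce everything to ordinary
stratified splitting.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import ExpressionMatrix, ReplicateGroups

logger = logging.getLogger(__name__)


class SplitError(ValueError):
    """A requested split cannot be formed without leakage or class loss."""


@dataclass
class SplitPlan:
    """The nested partition a selection run is built on.

    ``final_test`` is set aside once before any model sees the data;
    each simulation then re-splits the remainder into ``train`` and
    ``internal_test`` and carves ``cv_folds`` (validation sides) out of
    ``train``.
    """

    final_test: list[str]
    simulations: list[dict] = field(default_factory=list)  # {train, internal_test, cv_folds}
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=list))


def _grouped_by_class(
    sample_ids: Sequence[str],
    classes: pd.Series,
    groups: ReplicateGroups,
) -> dict[str, dict[str, list[str]]]:
    """class label -> {group id -> member sample ids}; mixed-class groups are errors."""
    members = groups.groups_for(sample_ids)
    by_class: dict[str, dict[str, list[str]]] = {}
    for gid, samples in members.items():
        labels = {str(classes.loc[s]) for s in samples}
        if len(labels) > 1:
            raise SplitError(
                f"replicate group {gid!r} mixes classes {sorted(labels)}; "
                "groups must be class-pure to stratify without leakage"
            )
        by_class.setdefault(labels.pop(), {})[gid] = list(samples)
    return by_class


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_group_split(
    sample_ids: Sequence[str],
    classes: pd.Series,
    fraction: float,
    groups: ReplicateGroups | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Split samples into (part_A, part_B) with part_B ≈ ``fraction`` of each class.

    Stratification is computed over replicate groups: per class,
    ``round(fraction * n_groups)`` groups go to part_B (half away from
    zero), clamped so both parts keep at least one group of every class.
    Deterministic given ``seed`` and invariant to the input sample order.
    """
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must be in (0,1), got {fraction}")
    groups = groups or ReplicateGroups({})
    by_class = _grouped_by_class(sample_ids, classes, groups)
    if len(by_class) < 2:
        raise SplitError("need at least 2 classes to stratify a split")
    rng = np.random.default_rng(seed)
    part_a: list[str] = []
    part_b: list[str] = []
    for label in sorted(by_class):
        gids = sorted(by_class[label])
        if len(gids) < 2:
            raise SplitError(
                f"class {label!r} has a single replicate group; cannot place it "
                "on both sides of a split without leakage"
            )
        n_b = _round_half_away(fraction * len(gids))
        n_b = min(max(n_b, 1), len(gids) - 1)  # >=1 group per class per side
        order = rng.permutation(len(gids))
        chosen = {gids[i] for i in order[:n_b]}
        for gid in gids:
            target = part_b if gid in chosen else part_a
            target.extend(by_class[label][gid])
    part_a.sort()
    part_b.sort()
    return part_a, part_b


def stratified_group_kfold(
    train_samples: Sequence[str],
    classes: pd.Series,
    k: int = 5,
    groups: ReplicateGroups | None = None,
    seed: int = 0,
) -> list[list[str]]:
    """Partition ``train_samples`` into k group-atomic, class-balanced folds.

    Returns the k validation-fold sample lists (disjoint, covering the
    input).  Per class, group counts across folds differ by at most one.
    If some class has fewer groups than ``k``, k is reduced to the
    smallest class group count with a logged warning; a class with a
    single group cannot be cross-validated at all and is an error.
    """
    groups = groups or ReplicateGroups({})
    by_class = _grouped_by_class(train_samples, classes, groups)
    min_groups = min(len(g) for g in by_class.values())
    if min_groups < 2:
        label = next(l for l, g in sorted(by_class.items()) if len(g) == min_groups)
        raise SplitError(
            f"class {label!r} has one replicate group in the training data; "
            "stratified cross-validation is impossible"
        )
    if k > min_groups:
        logger.warning(
            "reducing cross-validation folds from %d to %d (smallest class has "
            "%d replicate groups)", k, min_groups, min_groups,
        )
        k = min_groups
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for label in sorted(by_class):
        gids = sorted(by_class[label])
        order = rng.permutation(len(gids))
        for pos, idx in enumerate(order):
            folds[pos % k].extend(by_class[label][gids[idx]])
    for fold in folds:
        fold.sort()
    return folds


def check_partition(parts: Sequence[Sequence[str]], universe: Sequence[str]) -> None:
    """Assert the parts are disjoint and cover ``universe`` exactly."""
    seen: set[str] = set()
    for part in parts:
        part_set = set(part)
        overlap = seen & part_set
        if overlap:
            raise SplitError(f"partitions overlap on {sorted(overlap)[:5]}")
        seen |= part_set
    if seen != set(universe):
        raise SplitError("partitions do not cover the sample universe")
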