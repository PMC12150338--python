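"""Tabular input/output for expression matrices and annotations.

The central container is :class:`ExpressionMatrix`: a samples x features
abundance table with optional per-sample phenotype labels.  Missing
abundances are first-class citizens — they are stored as ``NaN`` and are
distinct from 0 throughout the pipeline (the boosted-tree learner handles
them natively, so no imputation happens at read time).

All files are plain UTF-8 CSV with a header row:

* expression table — first column ``files`` (sample identifiers), last
  column ``class`` (phenotype labels), every column in between a feature;
  empty cells (or ``NA``/``NaN``) mean *missing*, never zero.
* class annotations — columns ``files`` and ``class``.
* replicate annotations — columns ``files`` and ``SampleID``; every file
  mapped to the same SampleID (e.g. one patient's technical replicates)
  is kept atomic across all data splits.
* long-format quantification report — columns ``file``, ``protein``,
  ``peptide``, ``intensity``; a generic stand-in for search-engine
  exports, pivoted to peptide- or protein-level matrices.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: input tokens understood as a missing cell (output always writes "")
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan"})

SAMPLE_COL = "files"
CLASS_COL = "class"
GROUP_COL = "SampleID"


class TableFormatError(ValueError):
    """A tabular input violates its schema contract."""


@dataclass
class ExpressionMatrix:
    """Samples x features abundance matrix with optional class labels.

    Parameters
    ----------
    data
        ``DataFrame`` indexed by unique sample identifiers with unique
        feature-name columns; ``NaN`` encodes a missing measurement.
    classes
        Phenotype label per sample (index-aligned with ``data``), or
        ``None`` for an unlabelled matrix (e.g. fresh from a pivot).
    """

    data: pd.DataFrame
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableFormatError(f"duplicate sample identifier: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise TableFormatError(f"duplicate feature name: {dup!r}")
        self.data = self.data.astype(float)
        if self.classes is not None:
            self.classes = self.classes.reindex(self.data.index)
            if self.classes.isna().any():
                missing = list(self.data.index[self.classes.isna()])
                raise TableFormatError(f"samples without class label: {missing}")
            self.classes = self.classes.astype(str)

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        features: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a sub-matrix restricted to the given samples/features."""
        data = self.data
        if samples is not None:
            data = data.loc[list(samples)]
        if features is not None:
            data = data[list(features)]
        classes = None
        if self.classes is not None:
            classes = self.classes.loc[data.index]
        return ExpressionMatrix(data.copy(), classes)

    def with_classes(self, annotation: Mapping[str, str]) -> "ExpressionMatrix":
        """Attach class labels from a file→class mapping (must cover all samples)."""
        missing = [s for s in self.sample_ids if s not in annotation]
        if missing:
            raise TableFormatError(f"samples without class annotation: {missing}")
        classes = pd.Series({s: annotation[s] for s in self.sample_ids}, dtype=str)
        return ExpressionMatrix(self.data.copy(), classes.loc[self.data.index])


@dataclass
class ReplicateGroups:
    """File → replicate-group mapping; unmapped files are singleton groups."""

    mapping: dict[str, str] = field(default_factory=dict)

    def group_of(self, sample_id: str) -> str:
        return self.mapping.get(sample_id, sample_id)

    def groups_for(self, sample_ids: Iterable[str]) -> dict[str, list[str]]:
        """Partition ``sample_ids`` into replicate groups (group id → members)."""
        out: dict[str, list[str]] = {}
        for s in sample_ids:
            out.setdefault(self.group_of(s), []).append(s)
        return out


def _read_header(path: Path) -> list[str]:
    with open(path, newline="", encoding="utf-8-sig") as fh:
        return next(csv.reader(fh))


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a samples x features CSV (``files``, features..., ``class``).

    Empty / ``NA`` / ``NaN`` cells become missing values; the feature
    column order of the file is preserved.  Duplicate sample ids,
    duplicate feature names and non-numeric non-empty cells are hard
    errors naming the offending row/column.
    """
    path = Path(path)
    header = _read_header(path)
    if len(header) < 2 or header[0] != SAMPLE_COL or header[-1] != CLASS_COL:
        raise TableFormatError(
            f"{path}: expected first column {SAMPLE_COL!r} and last column "
            f"{CLASS_COL!r}, got {header[:1]} ... {header[-1:]}"
        )
    features = header[1:-1]
    seen: set[str] = set()
    for name in features:
        if name in seen:
            raise TableFormatError(f"{path}: duplicate feature column {name!r}")
        seen.add(name)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    raw.columns = header  # undo pandas dupe-mangling; dupes already rejected
    sample_ids = raw[SAMPLE_COL].tolist()
    dup = pd.Index(sample_ids)
    if dup.has_duplicates:
        raise TableFormatError(
            f"{path}: duplicate sample identifier {dup[dup.duplicated()][0]!r}"
        )

    values = np.full((len(raw), len(features)), np.nan)
    for j, name in enumerate(features):
        col = raw.iloc[:, 1 + j]
        for i, cell in enumerate(col):
            token = cell.strip()
            if token in MISSING_TOKENS:
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric value {cell!r} in row {sample_ids[i]!r},"
                    f" column {name!r}"
                ) from None

    data = pd.DataFrame(values, index=pd.Index(sample_ids, name=SAMPLE_COL), columns=features)
    classes = pd.Series(raw[CLASS_COL].tolist(), index=data.index, dtype=str)
    return ExpressionMatrix(data, classes)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix back to the ``files``/features/``class`` CSV schema.

    Missing cells are written as empty fields (never 0 or a string
    placeholder), so a write/read round trip is loss-free.
    """
    out = matrix.data.copy()
    out.index.name = SAMPLE_COL
    if matrix.classes is not None:
        out[CLASS_COL] = matrix.classes
    out.to_csv(path, na_rep="")


def _read_two_column_map(
    path: str | Path, key_col: str, value_col: str
) -> dict[str, str]:
    path = Path(path)
    header = _read_header(path)
    if header[:2] != [key_col, value_col]:
        raise TableFormatError(
            f"{path}: expected columns {key_col!r},{value_col!r}, got {header[:2]}"
        )
    table = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    mapping: dict[str, str] = {}
    for key, value in zip(table[key_col], table[value_col]):
        key = key.strip()
        value = value.strip()
        if key in mapping and mapping[key] != value:
            raise TableFormatError(
                f"{path}: file {key!r} mapped to both {mapping[key]!r} and {value!r}"
            )
        mapping[key] = value
    return mapping


def read_class_annotations(path: str | Path) -> dict[str, str]:
    """Read a ``files``,``class`` CSV into a file→class mapping.

    Exact duplicates are de-duplicated silently; the same file with two
    different classes is a hard error.
    """
    return _read_two_column_map(path, SAMPLE_COL, CLASS_COL)


def read_replicate_annotations(path: str | Path | None) -> ReplicateGroups:
    """Read a ``files``,``SampleID`` CSV into replicate groups.

    ``None`` (annotation not provided) yields the empty mapping, i.e.
    every sample is its own singleton group.
    """
    if path is None:
        return ReplicateGroups({})
    return ReplicateGroups(_read_two_column_map(path, SAMPLE_COL, GROUP_COL))


# -- long-format quantification reports --------------------------------

REPORT_COLUMNS = ("file", "protein", "peptide", "intensity")


def read_quant_report(path: str | Path) -> pd.DataFrame:
    """Read a generic long-format quantification report.

    Expected columns: ``file``, ``protein``, ``peptide``, ``intensity``
    (one row per observed file/peptide intensity).  Vendor exports are
    adapted to this schema by renaming columns upstream.
    """
    path = Path(path)
    table = pd.read_csv(path, encoding="utf-8-sig")
    missing = [c for c in REPORT_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"{path}: report lacks columns {missing}")
    table = table[list(REPORT_COLUMNS)].copy()
    if (table["intensity"].dropna() < 0).any():
        raise TableFormatError(f"{path}: negative intensities in report")
    return table


def pivot_quant_report(
    report: pd.DataFrame, feature_level: Literal["peptide", "protein"]
) -> ExpressionMatrix:
    """Pivot a long report to a file x feature matrix (no class labels yet).

    At peptide level each (file, peptide) intensity becomes one cell (the
    sum if a pair is reported more than once).  At protein level a
    protein's value per file is the sum of its observed peptide
    intensities in that file — the usual label-free rollup.  Feature/file
    combinations never observed stay missing, never 0.
    """
    if feature_level not in ("peptide", "protein"):
        raise TableFormatError(f"unknown feature level {feature_level!r}")
    key = "peptide" if feature_level == "peptide" else "protein"
    wide = (
        report.dropna(subset=["intensity"])
        .groupby(["file", key], sort=False)["intensity"]
        .sum()
        .unstack(key)
    )
    wide.index = wide.index.astype(str)
    wide.index.name = SAMPLE_COL
    wide.columns = wide.columns.astype(str)
    return ExpressionMatrix(wide)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Apply ``log2(v + pseudocount)`` to every observed cell.

    Missing cells stay missing.  Cells where ``v + pseudocount <= 0``
    (possible with a pseudocount below 1 on zero/negative abundances)
    are a hard error listing the offenders, because they have no finite
    log.
    """
    shifted = matrix.data + pseudocount
    bad = shifted <= 0
    if bad.any().any():
        named = [
            f"({matrix.sample_ids[i]}, {matrix.feature_ids[j]})"
            for i, j in zip(*np.nonzero(bad.to_numpy()))
        ]
        raise TableFormatError(
            "log transform undefined (value + pseudocount <= 0) for cells: "
            + ", ".join(named)
        )
    return ExpressionMatrix(np.log2(shifted), None if matrix.classes is None else matrix.classes.copy())
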