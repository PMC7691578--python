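"""Expression, label and clinical table handling.

Expression data are held as a features x samples matrix with explicit ID
lists. Tables move through three scales: raw sequencing ``counts``, library
size normalized ``rpm`` (reads per million), and ``log2`` (log2(RPM + 1)).
Preprocessing mirrors common miRNA-seq practice: per-class sparsity
filtering of features, intersection of features shared by every cohort,
RPM normalization and a log2 transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "LabelVector",
    "ClinicalRow",
    "read_expression_table",
    "write_expression_table",
    "read_label_table",
    "read_clinical_table",
    "to_survival",
    "rpm_log2_normalize",
    "filter_zero_fraction",
    "intersect_common_features",
]


class Scale(str, Enum):
    counts = "counts"
    rpm = "rpm"
    log2 = "log2"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Feature-by-sample real matrix with ID bookkeeping.

    Parameters
    ----------
    feature_ids : list of str
    sample_ids : list of str
    values : ndarray, shape (n_features, n_samples)
    scale_tag : Scale
        Unit of the values; ``counts`` implies nonnegative entries.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: Scale = Scale.counts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scale_tag = Scale(self.scale_tag)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if self.scale_tag is Scale.counts and np.any(self.values < 0):
            raise ValueError("counts-scale matrix has negative entries")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in feature_ids]
        return ExpressionMatrix(
            list(feature_ids), list(self.sample_ids), self.values[rows], self.scale_tag
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.feature_ids), list(sample_ids), self.values[:, cols], self.scale_tag
        )


@dataclass
class LabelVector:
    """Per-sample class labels (cancer type codes plus e.g. ``NORMAL``)."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("one label per sample required")
        _check_unique(self.sample_ids, "sample")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Labels as an array ordered like ``sample_ids``."""
        mapping = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return np.asarray([mapping[s] for s in sample_ids], dtype=object)


@dataclass
class ClinicalRow:
    sample_id: str
    vital_status: str  # "alive" | "dead"
    followup_days: float
    age: float | None = None
    gender: str | None = None

    def __post_init__(self) -> None:
        if self.vital_status not in ("alive", "dead"):
            raise ValueError(f"vital_status must be alive/dead, got {self.vital_status!r}")
        if self.followup_days < 0:
            raise ValueError(f"negative followup time for {self.sample_id!r}")


def read_expression_table(path, layout: str = "features_in_rows") -> ExpressionMatrix:
    """Read a TSV expression table into features x samples orientation.

    The first column holds row IDs, the header row holds column IDs. A
    non-numeric body cell raises with its row/column location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    body = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                body[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {raw!r} at row {df.index[i]!r}, column {col!r} in {path}"
                ) from None
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    if layout == "features_in_rows":
        return ExpressionMatrix(row_ids, col_ids, body)
    if layout == "samples_in_rows":
        return ExpressionMatrix(col_ids, row_ids, body.T)
    raise ValueError(f"unknown layout {layout!r}")


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_label_table(path) -> LabelVector:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "class"} <= set(df.columns):
        raise ValueError("label table requires columns sample_id, class")
    return LabelVector(list(df["sample_id"]), list(df["class"]))


def read_clinical_table(path) -> tuple[list[ClinicalRow], int]:
    """Read the clinical TSV; incomplete rows are dropped, not imputed.

    Returns the usable rows plus the count of excluded rows (missing vital
    status or followup time). A negative followup time is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "vital_status", "days_to_last_followup"}
    if not required <= set(df.columns):
        raise ValueError(f"clinical table requires columns {sorted(required)}")
    rows: list[ClinicalRow] = []
    excluded = 0
    for rec in df.to_dict("records"):
        status = str(rec["vital_status"]).strip().lower()
        days = str(rec["days_to_last_followup"]).strip()
        if status not in ("alive", "dead") or days in ("", "na", "nan", "NA"):
            excluded += 1
            continue
        t = float(days)
        if t < 0:
            raise ValueError(f"negative followup time for sample {rec['sample_id']!r}")
        age = rec.get("age", "")
        gender = rec.get("gender", "") or None
        rows.append(
            ClinicalRow(
                sample_id=str(rec["sample_id"]),
                vital_status=status,
                followup_days=t,
                age=float(age) if age not in ("", None) else None,
                gender=gender,
            )
        )
    if excluded:
        logger.info("read_clinical_table: excluded %d incomplete rows", excluded)
    return rows, excluded


def to_survival(rows: Sequence[ClinicalRow]) -> list[tuple[float, int]]:
    """(time, event) pairs: dead -> event 1, alive -> right-censored 0."""
    return [(r.followup_days, 1 if r.vital_status == "dead" else 0) for r in rows]


def rpm_log2_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample column to reads per million, then log2(RPM + 1)."""
    if counts.scale_tag is not Scale.counts:
        raise ValueError("rpm_log2_normalize expects a counts-scale matrix")
    totals = counts.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample columns with zero total counts: {[counts.sample_ids[i] for i in zero[:5]]}"
        )
    rpm = counts.values / totals * 1e6
    return ExpressionMatrix(
        list(counts.feature_ids), list(counts.sample_ids), np.log2(rpm + 1.0), Scale.log2
    )


def filter_zero_fraction(
    matrix: ExpressionMatrix, labels: LabelVector, threshold: float = 0.6
) -> ExpressionMatrix:
    """Drop features with more than ``threshold`` zeros in any class group.

    The fraction is computed per class; a feature is removed iff its zero
    fraction strictly exceeds the threshold in at least one group. Feature
    order is preserved. Zeros are meaningful on the counts/RPM scales only.
    """
    if matrix.scale_tag is Scale.log2:
        raise ValueError("zero-fraction filtering expects counts or RPM scale")
    y = labels.aligned_to(matrix.sample_ids)
    keep = np.ones(matrix.n_features, dtype=bool)
    for cls in np.unique(y):
        cols = y == cls
        if not cols.any():
            raise ValueError(f"empty class group {cls!r}")
        frac = (matrix.values[:, cols] == 0).mean(axis=1)
        keep &= frac <= threshold
    kept = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return matrix.subset_features(kept)


def intersect_common_features(matrices: Sequence[ExpressionMatrix]) -> list[str]:
    """Feature IDs present in every matrix, in the order of the first."""
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].feature_ids)
    for m in matrices[1:]:
        common &= set(m.feature_ids)
    if not common:
        raise ValueError("no features common to all matrices")
    return [f for f in matrices[0].feature_ids if f in common]
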