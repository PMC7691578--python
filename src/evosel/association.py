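"""Feature-target correlation ranking across cancer-type groups.

For each (feature, target) pair — typically a miRNA and a candidate mRNA
target — Pearson correlation is computed within every group (cancer type).
Because a miRNA represses its targets, strongly negative correlation marks
a likely regulatory association. Pairs are summarized by the cumulative
negative-correlation score (sum of the negative per-group r values) and
the association count (number of groups with r < 0), then ranked: more
groups first, more negative cumulative score next.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationRecord",
    "pearson_r",
    "top_negative_targets",
    "rank_associations",
    "build_association_records",
]


@dataclass
class AssociationRecord:
    feature_id: str
    target_id: str
    per_group_r: dict[str, float]
    significance_gate: float | None = None
    per_group_p: dict[str, float] = field(default_factory=dict)

    def _counted(self) -> list[float]:
        out = []
        for g, r in self.per_group_r.items():
            if r >= 0:
                continue
            if self.significance_gate is not None and self.per_group_p.get(g, 0.0) >= (
                self.significance_gate
            ):
                continue
            out.append(r)
        return out

    @property
    def cumulative_score(self) -> float:
        """Sum of the (counted) negative per-group correlations; <= 0."""
        return float(sum(self._counted()))

    @property
    def association_count(self) -> int:
        return len(self._counted())


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def top_negative_targets(corr: dict[str, float], k: int = 5) -> list[str]:
    """The k most negatively correlated targets, ascending by r.

    Fewer than k negative entries returns all of them; ties break by
    target ID for determinism.
    """
    if not corr:
        raise ValueError("empty correlation map")
    negative = sorted((r, t) for t, r in corr.items() if r < 0)
    return [t for _, t in negative[:k]]


def rank_associations(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Order records by association count (desc), cumulative score (asc),
    then (feature_id, target_id)."""
    return sorted(
        records,
        key=lambda r: (-r.association_count, r.cumulative_score, r.feature_id, r.target_id),
    )


def build_association_records(
    feature_expr: dict[str, pd.DataFrame],
    target_expr: dict[str, pd.DataFrame],
    pairs: list[tuple[str, str]],
    significance_gate: float | None = None,
) -> list[AssociationRecord]:
    """Correlate feature/target pairs within each group.

    ``feature_expr`` and ``target_expr`` map group name to a features x
    samples DataFrame; the two tables of a group must share sample columns.
    Groups missing a feature or target are skipped for that pair.
    """
    records = []
    for fid, tid in pairs:
        per_r: dict[str, float] = {}
        per_p: dict[str, float] = {}
        for group, fdf in feature_expr.items():
            tdf = target_expr.get(group)
            if tdf is None or fid not in fdf.index or tid not in tdf.index:
                continue
            shared = [s for s in fdf.columns if s in set(tdf.columns)]
            if len(shared) < 3:
                continue
            x = fdf.loc[fid, shared].to_numpy(dtype=float)
            y = tdf.loc[tid, shared].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            per_r[group] = float(res.statistic)
            per_p[group] = float(res.pvalue)
        records.append(
            AssociationRecord(
                feature_id=fid,
                target_id=tid,
                per_group_r=per_r,
                significance_gate=significance_gate,
                per_group_p=per_p,
            )
        )
    return records
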