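"""Contingency-table chi-square tests and count/percentage reporting.

Between-region comparisons of proportions (responsive vs not, excitatory
vs inhibitory, pause-active vs not, selective vs not) use the Pearson
chi-square statistic on the raw count table with expected counts from the
row/column margins, (rows-1)(cols-1) degrees of freedom, and no continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session_synth import ValidationError

__all__ = ["ContingencyTable", "pearson_chi_square", "proportion_report"]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValidationError("need at least a 2x2 count table")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValidationError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_proportions(
        cls, hits: list[int], totals: list[int], row_labels=(), col_labels=()
    ) -> "ContingencyTable":
        """Two-column table (hit, miss) from per-row hits and totals."""
        counts = np.column_stack([hits, np.asarray(totals) - np.asarray(hits)])
        return cls(counts, tuple(row_labels), tuple(col_labels))


def pearson_chi_square(table: ContingencyTable | np.ndarray) -> dict:
    """Pearson chi-square test of independence, no continuity correction.

    Returns ``{"statistic", "dof", "p"}``.  Raises on any zero row or
    column margin (expected counts undefined).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(
        table, dtype=float
    )
    if counts.ndim != 2:
        raise ValidationError("counts must be 2-D")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("zero row/column margin: test undefined")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return {"statistic": float(stat), "dof": int(dof), "p": float(p)}


def proportion_report(numerators, denominators, labels=None) -> list[dict]:
    """Counts with rounded integer percentages, results-section style."""
    nums = np.asarray(numerators)
    dens = np.asarray(denominators)
    if len(nums) != len(dens):
        raise ValidationError("numerators and denominators must align")
    if np.any(dens == 0):
        raise ValidationError("zero denominator")
    if np.any(nums > dens) or np.any(nums < 0):
        raise ValidationError("need 0 <= numerator <= denominator")
    labels = labels if labels is not None else [str(i) for i in range(len(nums))]
    return [
        {
            "label": lab,
            "count": int(n),
            "total": int(d),
            "percent": int(round(100.0 * n / d)),
        }
        for lab, n, d in zip(labels, nums, dens)
    ]
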