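"""Contingency-table association tests and immunohistochemistry scoring.

These are the statistics used to check whether a risk signature is confounded
by clinicopathological variables (T/N stage, grade, margin status, therapy),
and the intensity-times-proportion (I x P) scoring rule for tissue-microarray
immunostaining.

Conventions
-----------
* Fisher's exact test is two-sided by the probability-mass rule: the p-value
  sums hypergeometric probabilities of every 2x2 table with the observed
  margins whose probability does not exceed the observed table's.
* The Pearson chi-square test carries no Yates continuity correction.

Both conventions reproduce published high/low-risk association tables from
resected-PDAC cohorts to the printed decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "IHCScore",
    "fisher_exact_2x2",
    "chi_square_rxc",
    "ihc_score",
    "dichotomize_by_median",
]


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of nonnegative integer counts with optional axis labels."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("contingency table must be two-dimensional")
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be nonnegative integers")
        if arr.sum() <= 0:
            raise ValueError("contingency table is empty")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def shape(self):
        return self.counts.shape


def _as_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Parameters
    ----------
    table : 2x2 array-like or ContingencyTable

    Returns
    -------
    float
        Two-sided p-value under the probability-mass rule.
    """
    counts = _as_table(table)
    if counts.shape != (2, 2):
        raise ValueError(f"Fisher exact test requires a 2x2 table, got {counts.shape}")
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def chi_square_rxc(table) -> tuple[float, int, float]:
    """Pearson chi-square test (no continuity correction) on an r x c table.

    Returns ``(statistic, df, p_value)`` with ``df = (r-1)(c-1)``.
    All row and column totals must be positive.
    """
    counts = _as_table(table)
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValueError("chi-square test needs at least a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass(frozen=True)
class IHCScore:
    """Immunohistochemistry I x P score.

    intensity is graded 0 (no staining) to 4 (strong staining); proportion is
    the fraction of positive epithelial cells.  Staining is called positive
    only when more than 5% of cells express the marker; otherwise the score is
    forced to zero.
    """

    intensity: int
    proportion: float
    positive: bool = field(init=False)
    score: float = field(init=False)

    def __post_init__(self):
        if self.intensity not in (0, 1, 2, 3, 4):
            raise ValueError(f"intensity must be an integer 0-4, got {self.intensity}")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"proportion must lie in [0, 1], got {self.proportion}")
        positive = self.proportion > 0.05
        object.__setattr__(self, "positive", positive)
        object.__setattr__(
            self, "score", self.intensity * self.proportion if positive else 0.0
        )


def ihc_score(intensity: int, proportion: float) -> IHCScore:
    """Score one stained core as intensity times proportion of positive cells."""
    return IHCScore(intensity, proportion)


def dichotomize_by_median(scores, cutoff: float | None = None) -> list[str]:
    """Split scores into 'high' (> cutoff) and 'low' (<= cutoff) labels.

    With ``cutoff=None`` the sample median is used.  A score exactly at the
    cutoff is labelled low (boundary rule; published cutoffs such as 1.5 leave
    the boundary unassigned).
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("empty score list")
    if cutoff is None:
        cutoff = float(np.median(arr))
    return ["high" if s > cutoff else "low" for s in arr]
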