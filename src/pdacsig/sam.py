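"""Significance Analysis of Microarrays (SAM), two-class unpaired.

SAM scores each gene with a moderated t-like statistic

    d_i = (mean_2i - mean_1i) / (s_i + s0),

where s_i is the pooled two-sample standard error of the mean difference and
s0 (the "fudge factor") is a small positive offset chosen to stop genes with
tiny variance from dominating the ranking.  Significance is judged against
expected order statistics from label permutations: sorted observed d_(i) are
compared with the permutation average dbar_(i), and genes whose statistic
drifts more than a threshold delta from the expected line are called.  The
false discovery rate at a given delta is estimated as the median number of
called genes across permutations divided by the observed call count, and
delta is tuned to the smallest value meeting the target FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = ["SamResult", "sam_two_class", "compute_s0"]

logger = logging.getLogger(__name__)


@dataclass
class SamResult:
    """Outcome of a two-class SAM run.

    ``d``, ``s`` and ``q_values`` are aligned with ``genes`` (matrix row
    order).  ``dbar`` holds the permutation expected order statistics for the
    ascending-sorted observed d.  ``selected`` lists the genes called at
    ``delta``; ``fdr`` is the estimated median FDR at that delta.
    """

    genes: list
    d: np.ndarray
    s: np.ndarray
    s0: float
    dbar: np.ndarray
    delta: float
    q_values: np.ndarray
    selected: list
    n_perm: int
    seed: int
    target_fdr: float
    fdr: float
    cut_up: float = field(default=np.inf)
    cut_low: float = field(default=-np.inf)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "d": self.d,
                "s": self.s,
                "q_value": self.q_values,
                "selected": [int(g in sel) for g in self.genes],
            }
        )

    def write_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# s0={self.s0:.6g}\tdelta={self.delta:.6g}\t"
                f"n_perm={self.n_perm}\tseed={self.seed}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _group_stats(X: np.ndarray, mask2: np.ndarray):
    """Numerator r and pooled scatter s of the SAM statistic.

    mask2 flags class-2 membership; may be (n,) or (n_perm, n) for a batch of
    label assignments.  Returns arrays broadcast over the leading axis.
    """
    mask2 = np.atleast_2d(mask2).astype(float)  # (m, n)
    n = X.shape[1]
    n2 = mask2.sum(axis=1)  # (m,)
    n1 = n - n2
    sum_all = X.sum(axis=1)  # (g,)
    sumsq_all = (X * X).sum(axis=1)
    s2 = X @ mask2.T  # (g, m)
    ss2 = (X * X) @ mask2.T
    s1 = sum_all[:, None] - s2
    ss1 = sumsq_all[:, None] - ss2
    m1 = s1 / n1[None, :]
    m2 = s2 / n2[None, :]
    r = m2 - m1
    pooled = (ss1 - n1[None, :] * m1**2) + (ss2 - n2[None, :] * m2**2)
    pooled = np.maximum(pooled, 0.0) / (n - 2)
    s = np.sqrt((1.0 / n1 + 1.0 / n2)[None, :] * pooled)
    return r, s  # each (g, m)


def compute_s0(d_numerators: np.ndarray, scatters: np.ndarray) -> float:
    """Choose the fudge factor stabilizing d across the scatter range.

    Candidates are the percentiles of the per-gene scatter s on a 5% grid.
    For each candidate, genes are binned into scatter-quantile windows and
    the spread of d within each window is summarized by the scaled median
    absolute deviation; the candidate minimizing the coefficient of variation
    of these spreads across windows wins.  When every scatter is identical
    any candidate ties, and the 5th percentile (that common value) is
    returned by convention.
    """
    r = np.asarray(d_numerators, dtype=float)
    s = np.asarray(scatters, dtype=float)
    g = r.shape[0]
    if g < 20:
        raise ValueError("need at least 20 genes for stable scatter windows")
    if np.ptp(s) == 0.0:
        return float(np.percentile(s, 5))

    alphas = np.arange(0.0, 1.0001, 0.05)
    candidates = np.percentile(s, alphas * 100)
    order = np.argsort(s, kind="stable")
    n_win = max(2, min(100, g // 5))
    windows = np.array_split(order, n_win)

    best_cv, best_s0 = np.inf, candidates[1]
    for s0 in candidates:
        d = r / (s + s0)
        spreads = np.array(
            [np.median(np.abs(d[w] - np.median(d[w]))) / 0.64 for w in windows]
        )
        mean = spreads.mean()
        if mean == 0:
            continue
        cv = spreads.std(ddof=1) / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _permutation_masks(labels2: np.ndarray, n_perm: int, seed: int):
    """Boolean class-2 masks for permuted label assignments.

    Enumerates all distinct assignments when there are no more than n_perm of
    them, otherwise draws n_perm random shuffles of the label vector.
    """
    n = labels2.shape[0]
    n2 = int(labels2.sum())
    total = comb(n, n2)
    if total <= n_perm:
        masks = np.zeros((total, n), dtype=bool)
        for row, idx in enumerate(combinations(range(n), n2)):
            masks[row, list(idx)] = True
        return masks
    rng = np.random.default_rng(seed)
    masks = np.empty((n_perm, n), dtype=bool)
    for row in range(n_perm):
        masks[row] = rng.permutation(labels2)
    return masks


def sam_two_class(
    matrix: pd.DataFrame,
    labels,
    n_perm: int = 1000,
    target_fdr: float = 0.05,
    seed: int = 0,
    fdr_method: str = "mean",
) -> SamResult:
    """Run two-class unpaired SAM on a complete expression matrix.

    Parameters
    ----------
    matrix : DataFrame
        Genes x samples, no missing values (impute first).
    labels : sequence
        One label per sample with exactly two distinct values; d is positive
        for genes higher in the lexicographically larger class.
    n_perm : int
        Number of label permutations (all distinct assignments are
        enumerated when fewer than this).
    target_fdr : float
        The estimated-FDR level at which delta is tuned.
    seed : int
        Seed for the permutation RNG.
    fdr_method : str
        How the permutation false-call counts are summarized: "mean" (the
        original SAM convention; calibrated under the complete null) or
        "median" (reported by later SAM software; more liberal for very
        small call sets, since the median false count of a one-gene call is
        often exactly zero).
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing values; run knn_impute first")
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[1]:
        raise ValueError("one label per sample required")
    classes = np.unique(labels)
    if classes.shape[0] != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    mask2 = labels == classes[1]
    if mask2.sum() < 2 or (~mask2).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    if n_perm < 10:
        logger.warning("n_perm=%d is very small; FDR estimates will be unstable", n_perm)
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must lie in (0, 1)")

    r, s = _group_stats(X, mask2)
    r, s = r[:, 0], s[:, 0]
    s0 = compute_s0(r, s)
    d = r / (s + s0)
    g = d.shape[0]

    masks = _permutation_masks(mask2, n_perm, seed)
    rp, sp = _group_stats(X, masks)
    d_perm_unsorted = (rp / (sp + s0)).T  # (m, g)
    d_perm = np.sort(d_perm_unsorted, axis=1)
    dbar = d_perm.mean(axis=0)

    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    diffs = d_sorted - dbar
    i0 = int(np.searchsorted(dbar, 0.0))

    up_diffs = diffs[i0:]
    low_diffs = diffs[:i0][::-1]  # scan downward from the origin
    pos = np.unique(np.concatenate([up_diffs[up_diffs > 0], -low_diffs[low_diffs < 0]]))
    if pos.size > 2000:
        # compress the dense bulk but keep every extreme deviation exactly:
        # each large diff is its own attainable call-set boundary, and an
        # interpolated or thinned candidate there would skip real call sets
        bulk, tail = pos[:-500], pos[-500:]
        idx = np.unique(np.linspace(0, bulk.size - 1, 1500).round().astype(int))
        pos = np.concatenate([bulk[idx], tail])
    deltas = np.concatenate([[0.0], pos, [pos[-1] + 1.0] if pos.size else [1.0]])

    # thresholds for every candidate delta: first crossing away from the origin
    cut_ups = np.full(deltas.shape, np.inf)
    cut_lows = np.full(deltas.shape, -np.inf)
    for j, delta in enumerate(deltas):
        if up_diffs.size:
            hits = np.flatnonzero(up_diffs >= delta)
            if hits.size:
                cut_ups[j] = d_sorted[i0 + hits[0]]
        if low_diffs.size:
            hits = np.flatnonzero(low_diffs <= -delta)
            if hits.size:
                cut_lows[j] = d_sorted[i0 - 1 - hits[0]]

    n_called = (d[:, None] >= cut_ups[None, :]).sum(axis=0) + (
        d[:, None] <= cut_lows[None, :]
    ).sum(axis=0)

    # Per-permutation false calls at each candidate delta, counted over the
    # genes NOT called at that delta.  Permuted statistics of genuinely
    # differential genes do not represent the null and would otherwise
    # inflate the false-call count, biasing the FDR estimate upward under
    # strong signal; restricting the null pool to non-called genes (whose
    # count matches the null-gene count the false calls are drawn from)
    # removes that contamination.
    m = d_perm.shape[0]
    false_counts = np.empty((m, deltas.shape[0]))
    total_beyond = np.empty((m, deltas.shape[0]))
    for p in range(m):
        row = d_perm[p]
        total_beyond[p] = (g - np.searchsorted(row, cut_ups, side="left")) + (
            np.searchsorted(row, cut_lows, side="right")
        )
    d_perm_by_gene = d_perm_unsorted  # (m, g), gene-aligned columns
    for j in range(deltas.shape[0]):
        called_j = np.flatnonzero((d >= cut_ups[j]) | (d <= cut_lows[j]))
        if called_j.size == 0 or called_j.size > g // 2:
            false_counts[:, j] = total_beyond[:, j]
            continue
        called_beyond = (
            (d_perm_by_gene[:, called_j] >= cut_ups[j])
            | (d_perm_by_gene[:, called_j] <= cut_lows[j])
        ).sum(axis=1)
        false_counts[:, j] = total_beyond[:, j] - called_beyond
    if fdr_method not in ("mean", "median"):
        raise ValueError("fdr_method must be 'mean' or 'median'")
    summary = np.mean if fdr_method == "mean" else np.median
    typical_false = summary(false_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdrs = np.where(n_called > 0, typical_false / np.maximum(n_called, 1), 0.0)
    fdrs = np.minimum(fdrs, 1.0)

    ok = np.flatnonzero(fdrs <= target_fdr)
    j_star = int(ok[0]) if ok.size else int(np.argmin(fdrs))
    delta_star = float(deltas[j_star])
    cut_up, cut_low = float(cut_ups[j_star]), float(cut_lows[j_star])

    called = (d >= cut_up) | (d <= cut_low)
    genes = list(matrix.index)
    selected = [genes[i] for i in np.flatnonzero(called)]

    # q-value: smallest estimated FDR over thresholds at which the gene is called
    q = np.ones(g)
    for j in range(deltas.shape[0]):
        in_call = (d >= cut_ups[j]) | (d <= cut_lows[j])
        q[in_call] = np.minimum(q[in_call], fdrs[j])

    return SamResult(
        genes=genes,
        d=d,
        s=s,
        s0=s0,
        dbar=dbar,
        delta=delta_star,
        q_values=q,
        selected=selected,
        n_perm=int(masks.shape[0]),
        seed=seed,
        target_fdr=target_fdr,
        fdr=float(fdrs[j_star]),
        cut_up=cut_up,
        cut_low=cut_low,
    )
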