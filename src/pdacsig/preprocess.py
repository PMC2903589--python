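"""Two-color microarray preprocessing: lowess normalization, intensity
filtering, and k-nearest-neighbor imputation.

A two-color (Cy5 sample / Cy3 common reference) spot table is represented as a
:class:`pandas.DataFrame` with columns ``gene_id``, ``red_mean``,
``green_mean`` and an optional ``flag`` column (nonzero marks a poor-quality
spot).  Expression is carried downstream as log2(red/green) ratios in a
gene-by-sample :class:`pandas.DataFrame` (rows genes, columns samples),
referred to throughout the package as an expression matrix.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = ["lowess_normalize", "filter_genes", "knn_impute"]

SPOT_COLUMNS = ("gene_id", "red_mean", "green_mean")


def _check_spots(array: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SPOT_COLUMNS if c not in array.columns]
    if missing:
        raise ValueError(f"spot table lacks columns {missing}")
    if (array["red_mean"] < 0).any() or (array["green_mean"] < 0).any():
        raise ValueError("negative channel intensities")
    return array


def lowess_normalize(array: pd.DataFrame, span: float = 0.3) -> pd.Series:
    """Remove intensity-dependent dye bias from log ratios by MA-lowess.

    For each spot, M = log2(R/G) and A = (log2 R + log2 G)/2.  A locally
    weighted regression of M on A (global fit, window fraction ``span``) is
    subtracted, so the returned normalized M-values carry no systematic trend
    in overall spot intensity.

    Parameters
    ----------
    array : DataFrame
        Spot table with gene_id / red_mean / green_mean columns.
    span : float
        Lowess window as a fraction of the data, in (0, 1].

    Returns
    -------
    pandas.Series
        Normalized log2 ratios indexed by gene_id.  Spots where either
        channel is nonpositive get NaN (their log ratio is undefined).
    """
    _check_spots(array)
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    red = array["red_mean"].to_numpy(dtype=float)
    green = array["green_mean"].to_numpy(dtype=float)
    if np.all(red == 0) or np.all(green == 0):
        raise ValueError("normalization failure: a channel is identically zero")
    ok = (red > 0) & (green > 0)
    if ok.sum() < 10:
        raise ValueError("need at least 10 spots with positive intensities in both channels")

    m = np.log2(red[ok] / green[ok])
    a = 0.5 * np.log2(red[ok] * green[ok])
    fitted = _sm_lowess(m, a, frac=span, return_sorted=False)

    out = np.full(len(array), np.nan)
    out[ok] = m - fitted
    return pd.Series(out, index=array["gene_id"].to_numpy(), name="normalized_log2_ratio")


def filter_genes(
    experiments,
    threshold: float = 10.0,
    fraction: float = 0.7,
) -> list:
    """Keep genes measurably expressed in enough experiments.

    A gene passes one experiment when its spot is not flagged poor quality and
    at least one of its two channel mean intensities strictly exceeds
    ``threshold``.  The gene is retained when it passes at least
    ``ceil(fraction * n_experiments)`` experiments; genes absent from an
    experiment count as failing it.

    Returns the retained gene IDs in first-occurrence order.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValueError("empty experiment set")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")

    needed = math.ceil(fraction * len(experiments))
    passes: dict = {}
    order: list = []
    for exp in experiments:
        _check_spots(exp)
        flagged = (
            exp["flag"].to_numpy().astype(bool)
            if "flag" in exp.columns
            else np.zeros(len(exp), dtype=bool)
        )
        bright = (exp["red_mean"].to_numpy() > threshold) | (
            exp["green_mean"].to_numpy() > threshold
        )
        ok = bright & ~flagged
        for gene, good in zip(exp["gene_id"], ok):
            if gene not in passes:
                passes[gene] = 0
                order.append(gene)
            if good:
                passes[gene] += 1
    return [g for g in order if passes[g] >= needed]


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing expression values from the k most similar gene rows.

    For each missing entry, the k nearest gene rows (plain Euclidean distance
    over the columns observed in both rows) that carry a value in the missing
    column contribute an inverse-distance-weighted average.  Rows at distance
    zero (identical on all shared columns) short-circuit to their plain mean.
    Observed entries are never altered.

    Raises
    ------
    ValueError
        If any gene row is entirely missing (those genes cannot be imputed;
        the message lists their IDs), or k < 1.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    values = matrix.to_numpy(dtype=float)
    observed = np.isfinite(values)
    dead = ~observed.any(axis=1)
    if dead.any():
        bad = list(matrix.index[dead])
        raise ValueError(f"unimputable rows (no observed values): {bad}")
    if observed.all():
        return matrix.copy()

    n_genes = values.shape[0]
    filled = values.copy()
    row_means = np.nanmean(values, axis=1)
    # gene-ID tie-break: ties in distance resolved by matrix row order
    order_idx = np.arange(n_genes)

    for i in np.flatnonzero(~observed.all(axis=1)):
        target = values[i]
        shared = observed & observed[i]  # (n_genes, n_cols)
        diff = np.where(shared, values - target, 0.0)
        with np.errstate(invalid="ignore"):
            dist = np.sqrt(np.nansum(diff * diff, axis=1))
        dist[~shared.any(axis=1)] = np.inf
        dist[i] = np.inf
        for j in np.flatnonzero(~observed[i]):
            candidates = np.flatnonzero(observed[:, j] & np.isfinite(dist))
            if candidates.size == 0:
                filled[i, j] = row_means[i]
                continue
            ranking = candidates[np.lexsort((order_idx[candidates], dist[candidates]))]
            nearest = ranking[:k]
            d = dist[nearest]
            if np.any(d == 0.0):
                filled[i, j] = values[nearest[d == 0.0], j].mean()
            else:
                w = 1.0 / d
                filled[i, j] = np.dot(w, values[nearest, j]) / w.sum()

    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)
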