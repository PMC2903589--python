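"""Nearest-centroid single-sample predictor (SSP) over a gene signature.

The derivation cohort defines a centroid — the per-gene mean signature
profile of a class.  Any new sample is then scored one at a time by its
Pearson correlation r to the resected (nonmetastatic) centroid over the
signature genes only; the SSP distance is 1 - r, and a survival-optimized
cut-point on that distance splits samples into high- and low-risk groups.
A distance cut-point of 1 corresponds to r = 0: positively correlated
samples are low risk, negatively correlated samples high risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Centroid", "RiskCall", "build_centroid", "correlate_to_centroid", "classify_risk"]


@dataclass(frozen=True)
class Centroid:
    """Mean signature profile of one class over the derivation samples."""

    values: pd.Series  # indexed by gene, mean expression
    class_name: str

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("centroid gene list is empty")
        if self.values.index.has_duplicates:
            raise ValueError("centroid gene list contains duplicates")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("centroid contains non-finite values")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    def write(self, path) -> None:
        self.values.rename_axis("gene_id").rename("mean").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, class_name: str = "resected") -> "Centroid":
        tab = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=tab.iloc[:, 0], class_name=class_name)


@dataclass(frozen=True)
class RiskCall:
    """Per-sample SSP output: correlation, distance, and risk label."""

    sample_id: str
    r: float
    distance: float
    risk: str

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")
        if self.risk not in ("high", "low"):
            raise ValueError(f"risk label must be 'high' or 'low', got {self.risk}")


def build_centroid(matrix: pd.DataFrame, sample_subset, gene_list, class_name: str) -> Centroid:
    """Average the subset's expression per gene, restricted to the signature.

    Raises a ValueError listing any signature genes absent from the matrix.
    """
    sample_subset = list(sample_subset)
    gene_list = list(gene_list)
    if not sample_subset:
        raise ValueError("sample subset is empty")
    absent = [g for g in gene_list if g not in matrix.index]
    if absent:
        raise ValueError(f"genes absent from matrix: {absent}")
    sub = matrix.loc[gene_list, sample_subset]
    return Centroid(values=sub.mean(axis=1), class_name=class_name)


def correlate_to_centroid(profile: pd.Series, centroid: Centroid) -> tuple[float, float]:
    """Pearson correlation of a single sample to the centroid and its distance.

    Correlation runs over the signature genes only; at least 3 shared genes
    and nonzero variance in both vectors are required (a flat profile has no
    defined correlation).

    Returns ``(r, 1 - r)``.
    """
    genes = [g for g in centroid.genes if g in profile.index]
    if len(genes) < 3:
        raise ValueError("need at least 3 shared signature genes")
    x = profile.loc[genes].to_numpy(dtype=float)
    y = centroid.values.loc[genes].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("profile has missing values over the signature")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("undefined correlation: zero variance over the signature")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, 1.0 - r


def classify_risk(r: float, cutpoint: float = 1.0) -> str:
    """Label a sample high or low risk from its SSP distance.

    distance = 1 - r below the cut-point means low risk; at or above it,
    high risk (the boundary is assigned to high risk, conservative toward
    poor prognosis).
    """
    if not 0.0 <= cutpoint <= 2.0:
        raise ValueError(f"cutpoint must lie in [0, 2], got {cutpoint}")
    distance = 1.0 - r
    return "low" if distance < cutpoint else "high"


def call_samples(matrix: pd.DataFrame, centroid: Centroid, cutpoint: float = 1.0) -> pd.DataFrame:
    """Apply the SSP to every column of an expression matrix.

    Returns a DataFrame with columns sample_id, r, distance, risk.
    """
    rows = []
    for sample in matrix.columns:
        r, dist = correlate_to_centroid(matrix[sample], centroid)
        rows.append(
            {
                "sample_id": sample,
                "r": r,
                "distance": dist,
                "risk": classify_risk(r, cutpoint),
            }
        )
    return pd.DataFrame(rows)
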