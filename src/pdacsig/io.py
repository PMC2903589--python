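"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as tab-separated text: first row sample IDs,
first column gene IDs, blank/NA/NaN cells mark missing values.  Clinical and
survival tables are CSV with a sample_id column.  Spot-level two-color
tables are tab-separated with columns gene_id, red_mean, green_mean and an
optional flag column (nonzero = poor-quality spot).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "read_expression_table",
    "write_expression_table",
    "read_spot_table",
    "read_clinical_table",
    "write_clinical_table",
]

_NA_TOKENS = {"", "na", "nan", "null"}


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


def read_expression_table(path) -> pd.DataFrame:
    """Parse a gene-by-sample tab-separated expression matrix.

    Rejects ragged rows, duplicate gene IDs and non-numeric cells, naming
    the offending line.  Returns a float DataFrame with NaN for missing.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    rows, genes = [], []
    # header may or may not label the gene-ID column
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        gene, cells = fields[0], fields[1:]
        n_samples = len(header) - 1 if len(header) == len(fields) else len(header)
        if len(cells) != n_samples:
            raise ParseError(
                f"{path}:{lineno}: expected {n_samples} values for gene {gene}, "
                f"got {len(cells)}"
            )
        parsed = []
        for col, cell in enumerate(cells):
            token = cell.strip()
            if token.lower() in _NA_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(token))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell '{cell}' in column {col + 2}"
                ) from None
        genes.append(gene)
        rows.append(parsed)
    sample_ids = header[1:] if len(header) - 1 == len(rows[0]) else header
    seen = set()
    for g in genes:
        if g in seen:
            raise ParseError(f"{path}: duplicate gene ID '{g}'")
        seen.add(g)
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=sample_ids)


def write_expression_table(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t", na_rep="NA")


def read_spot_table(path) -> pd.DataFrame:
    """Read a spot-level two-color intensity table."""
    tab = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "red_mean", "green_mean"):
        if col not in tab.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    return tab


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical/survival CSV keyed by sample_id."""
    tab = pd.read_csv(path)
    if "sample_id" not in tab.columns:
        raise ParseError(f"{path}: missing column 'sample_id'")
    return tab


def write_clinical_table(annotation: pd.DataFrame, survival: pd.DataFrame | None, path) -> None:
    """Write annotation merged with survival as one CSV.

    Columns: sample_id, batch, class, time_months, event.  The class column
    collapses tissue and outcome ('normal' for normals, else the outcome
    label).  Samples without survival get blank time/event.
    """
    out = annotation.copy()
    out["class"] = np.where(
        out.get("tissue", "tumor") == "normal", "normal", out.get("outcome", "tumor")
    )
    out = out[["sample_id", "batch", "class"]]
    if survival is not None:
        out = out.merge(survival, on="sample_id", how="left")
    else:
        out["time_months"] = np.nan
        out["event"] = np.nan
    out.to_csv(path, index=False)
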