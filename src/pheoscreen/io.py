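"""Shared table readers and writers.

All tabular IO is tab-delimited UTF-8 with a single header row.  Each
reader validates its schema and reports row-level problems with line
numbers; expression matrices additionally accept the two-line GCT
preamble.  Concentrations are always µM unless a table carries an explicit
unit column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .meta import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table",
           "read_expression", "write_expression"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


#: schema name -> (required columns, numeric columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "plate": (("plate_id", "row", "col", "read", "role"), ("read",)),
    "compound_map": (("compound_id", "plate_id", "row", "col", "concentration"),
                     ("concentration",)),
    "library_truth": (("compound_id", "true_class", "true_ic50", "true_hill",
                       "true_top", "true_bottom"),
                      ("true_ic50", "true_hill", "true_top", "true_bottom")),
    "drug_target": (("drug", "gene"), ()),
    "dose_fa": (("dose", "fa"), ("dose", "fa")),
    "combo": (("dose1", "dose2", "fa"), ("dose1", "dose2", "fa")),
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a tab-delimited table against a named schema.

    Raises
    ------
    SchemaError : unknown schema, missing required column (named), or a
        non-numeric value in a numeric column (with its line number).
    """
    if schema == "expression":
        return read_expression(path).values
    if schema not in SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema!r}; known: {sorted(SCHEMAS) + ['expression']}")
    required, numeric = SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype=str).rename(columns=str.strip)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {bad[0] + 2}")
        df[col] = vals
    for col in ("row", "col"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    n_drop = int(df[list(required)].isna().all(axis=1).sum())
    if n_drop:
        df = df.dropna(subset=list(required), how="all")
        logger.info("%s: dropped %d empty rows", path, n_drop)
    logger.info("%s: read %d rows (schema %s)", path, len(df), schema)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as tab-delimited UTF-8 with one header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_expression(path, species: str = "", normalized: str = "raw") -> ExpressionMatrix:
    """Read a genes x samples expression matrix.

    Plain layout: first column gene symbol, header row of sample ids.  A
    GCT-style preamble (a ``#1.2`` version line plus a dimensions line) is
    detected and skipped, and a GCT ``Description`` column is dropped.
    """
    with open(path) as fh:
        first = fh.readline()
    skip = 2 if first.startswith("#1.") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    drop = [c for c in df.columns if c.lower() == "description"]
    df = df.drop(columns=drop)
    df = df.apply(pd.to_numeric, errors="coerce")
    return ExpressionMatrix(df, species=species, normalized=normalized)


def write_expression(matrix: ExpressionMatrix, path, gene_col: str = "gene") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.rename_axis(gene_col).to_csv(path, sep="\t")
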