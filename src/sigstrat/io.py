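"""TSV readers/writers with location-reporting validation.

Expression TSV: first column ``gene_id``, remaining columns sample IDs,
tab-separated log2 values, ``NA`` for missing.  Clinical TSV: columns
``sample_id, os_time, os_event, rfs_time, rfs_event, subtype``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .data import ClinicalTable, ExpressionMatrix, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_group_labels",
    "write_group_labels",
]

_NA = "NA"


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValidationError(f"{path}: malformed TSV: {exc}") from exc
    return df.replace(_NA, np.nan)


def read_expression(path: Union[str, Path]) -> ExpressionMatrix:
    df = _read_tsv(path)
    if df.columns.empty or df.columns[0] != "gene_id":
        raise ValidationError(f"{path}: first column must be 'gene_id'")
    sample_cols = list(df.columns[1:])
    dupes = pd.Index(sample_cols)[pd.Index(sample_cols).duplicated()].tolist()
    # pandas mangles duplicate headers to name.1; detect both ways
    mangled = [c for c in sample_cols if "." in c and c.rsplit(".", 1)[0] in sample_cols]
    if dupes or mangled:
        raise ValidationError(f"{path}: duplicated sample column(s): {dupes or mangled}")
    if df["gene_id"].duplicated().any():
        lines = (df.index[df["gene_id"].duplicated()] + 2).tolist()
        raise ValidationError(f"{path}: duplicate gene_id at line(s) {lines}")
    values = np.empty((len(df), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValidationError(
                f"{path}: non-numeric expression cell in column {col!r} at line {line}"
            )
        values[:, j] = converted.to_numpy(float)
    return ExpressionMatrix(values, df["gene_id"].tolist(), sample_cols)


def write_expression(expr: ExpressionMatrix, path: Union[str, Path]) -> None:
    df = expr.to_dataframe()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep=_NA, float_format="%.10g")


def read_clinical(path: Union[str, Path]) -> ClinicalTable:
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        lines = (df.index[df["sample_id"].duplicated()] + 2).tolist()
        raise ValidationError(f"{path}: duplicate sample_id at line(s) {lines}")
    try:
        return ClinicalTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_clinical(clinical: ClinicalTable, path: Union[str, Path]) -> None:
    df = clinical.table.copy()
    for col in ("os_event", "rfs_event"):
        df[col] = df[col].astype("Int64")
    df.to_csv(path, sep="\t", na_rep=_NA, float_format="%.10g")


def read_group_labels(path: Union[str, Path]) -> dict:
    """Two-column TSV (sample_id, group) -> mapping."""
    df = _read_tsv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing {col!r} column")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id entries")
    return dict(zip(df["sample_id"], df["group"]))


def write_group_labels(labels: dict, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "group": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)
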