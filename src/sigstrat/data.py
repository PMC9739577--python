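"""Core data containers shared across the pipeline.

Expression values are on the log2 scale, pre-normalized to a reference
median by the producer of the matrix; this package never renormalizes.
Missing values are represented as NaN and are propagated (never imputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise ValidationError(
                f"duplicate {what} {x!r} at positions {seen[x]} and {i}"
            )
        seen[x] = i


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        log2 expression; NaN marks a missing cell.
    gene_ids, sample_ids : sequences of unique strings.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene_id")
        _check_unique(self.sample_ids, "sample_id")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx], list(self.sample_ids)
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.sample_ids[i] for i in idx]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame indexed by gene_id with sample columns."""
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


CLINICAL_COLUMNS = ("sample_id", "os_time", "os_event", "rfs_time", "rfs_event", "subtype")


@dataclass
class ClinicalTable:
    """Per-sample survival and relapse-free survival outcomes.

    ``table`` is indexed by sample_id with columns os_time, os_event,
    rfs_time, rfs_event, subtype.  Times are non-negative (unit is the
    caller's; months in typical use), events are 0/1, subtype may be NA.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise ValidationError("clinical table needs a sample_id column/index")
        df = df.copy()
        for col in ("os_time", "os_event", "rfs_time", "rfs_event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if "subtype" not in df.columns:
            df["subtype"] = pd.NA
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id values: {dupes}")
        for col in ("os_time", "rfs_time"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & vals.isna()
            if bad.any():
                raise ValidationError(
                    f"non-numeric {col} for samples {df.index[bad].tolist()}"
                )
            if (vals.dropna() < 0).any():
                raise ValidationError(f"negative {col} values")
            df[col] = vals
        for col in ("os_event", "rfs_event"):
            vals = pd.to_numeric(df[col], errors="coerce")
            ok = vals.isin([0, 1]) | df[col].isna()
            if not ok.all():
                raise ValidationError(
                    f"non-binary {col} for samples {df.index[~ok].tolist()}"
                )
            df[col] = vals
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def endpoint(self, which: str) -> tuple[np.ndarray, np.ndarray, pd.Index]:
        """Return (times, events, sample index) for 'os' or 'rfs', dropping NA rows."""
        if which not in ("os", "rfs"):
            raise ValidationError(f"endpoint must be 'os' or 'rfs', got {which!r}")
        sub = self.table[[f"{which}_time", f"{which}_event"]].dropna()
        return (
            sub[f"{which}_time"].to_numpy(float),
            sub[f"{which}_event"].to_numpy(int),
            sub.index,
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named, directed set of gene IDs with derivation metadata."""

    name: str
    genes: tuple[str, ...]
    direction: str = "up"
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be 'up' or 'down', got {self.direction!r}")
        genes = tuple(str(g) for g in self.genes)
        if len(set(genes)) != len(genes):
            raise ValidationError(f"signature {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)
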