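"""Derive directed gene signatures from grouped expression data.

A gene enters an "up" signature when its condition-vs-control difference
of group means (log2 scale) strictly exceeds log2(fold_threshold) and its
one-way ANOVA p-value (BH-adjusted on request) is at or below alpha.
"Down" signatures mirror the fold criterion.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import ExpressionMatrix, GeneSignature, ValidationError
from .stats import bh_adjust

__all__ = [
    "derive_signature",
    "anova_pvalues_by_gene",
    "signature_from_de_table",
    "read_signatures",
    "write_signatures",
    "read_gmt",
    "write_gmt",
]


def _resolve_labels(
    expr: ExpressionMatrix, group_labels: Union[Mapping[str, str], pd.Series]
) -> tuple[ExpressionMatrix, np.ndarray, list[str]]:
    if isinstance(group_labels, pd.Series):
        group_labels = group_labels.to_dict()
    missing = [s for s in group_labels if s not in expr.sample_ids]
    if missing:
        raise ValidationError(f"labeled samples absent from matrix: {missing}")
    samples = [s for s in expr.sample_ids if s in group_labels]
    sub = expr.subset_samples(samples)
    labels = np.array([group_labels[s] for s in samples])
    groups = sorted(set(labels))
    return sub, labels, groups


def anova_pvalues_by_gene(
    values: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene one-way ANOVA (NaN-aware).

    Returns (F, p) arrays over genes.  Genes with zero total variance get
    p = 1; zero within-group variance with nonzero between gets p = 0.
    """
    groups = np.unique(labels)
    k = len(groups)
    counts, sums, sumsq = [], [], []
    for g in groups:
        block = values[:, labels == g]
        cnt = np.sum(~np.isnan(block), axis=1).astype(float)
        counts.append(cnt)
        sums.append(np.nansum(block, axis=1))
        sumsq.append(np.nansum(block**2, axis=1))
    cnt = np.stack(counts)  # k x genes
    s = np.stack(sums)
    ss = np.stack(sumsq)
    n_tot = cnt.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = s.sum(axis=0) / n_tot
        gmean = s / cnt
        ssb = np.nansum(cnt * (gmean - grand) ** 2, axis=0)
        ssw = np.nansum(ss - cnt * gmean**2, axis=0)
        ssw = np.maximum(ssw, 0.0)  # guard rounding
        dfb, dfw = k - 1, n_tot - k
        f = (ssb / dfb) / (ssw / dfw)
    p = sps.f.sf(f, dfb, dfw)
    sst = ssb + ssw
    p = np.where(sst <= 1e-300, 1.0, p)
    p = np.where((ssw <= 1e-12 * np.maximum(sst, 1.0)) & (sst > 1e-300), 0.0, p)
    return f, p


def derive_signature(
    expr: ExpressionMatrix,
    group_labels: Union[Mapping[str, str], pd.Series],
    fold_threshold: float,
    alpha: float,
    adjust: str = "bh",
    *,
    condition: str,
    control: str,
    direction: str = "up",
    max_missing_frac: float = 0.5,
    name: Optional[str] = None,
) -> GeneSignature:
    """Filter genes by strict fold-change and ANOVA significance.

    Parameters
    ----------
    fold_threshold : linear fold ratio (> 1); "more than N-fold" is strict.
    alpha : significance cutoff, non-strict (p <= alpha after adjustment).
    adjust : 'bh' for Benjamini–Hochberg, 'none' for raw p-values.
    condition, control : group labels whose mean difference defines the fold.
    max_missing_frac : genes missing in more than this fraction of any
        group's samples are excluded before testing (stand-in for a
        background-level probe filter; configurable).
    """
    if fold_threshold <= 1:
        raise ValidationError(f"fold_threshold must exceed 1, got {fold_threshold}")
    if adjust not in ("bh", "none"):
        raise ValidationError(f"adjust must be 'bh' or 'none', got {adjust!r}")
    sub, labels, groups = _resolve_labels(expr, group_labels)
    for g in (condition, control):
        if g not in groups:
            raise ValidationError(f"group {g!r} not present in labels {groups}")
    for g in groups:
        if np.sum(labels == g) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")

    vals = sub.values
    keep = np.ones(sub.n_genes, dtype=bool)
    for g in groups:
        block = vals[:, labels == g]
        frac_missing = np.mean(np.isnan(block), axis=1)
        n_present = np.sum(~np.isnan(block), axis=1)
        keep &= (frac_missing <= max_missing_frac) & (n_present >= 2)

    idx = np.flatnonzero(keep)
    tested = vals[idx]
    mean_cond = np.nanmean(tested[:, labels == condition], axis=1)
    mean_ctrl = np.nanmean(tested[:, labels == control], axis=1)
    diff = mean_cond - mean_ctrl
    _, p = anova_pvalues_by_gene(tested, labels)
    p_eff = bh_adjust(p) if adjust == "bh" and p.size else p

    cut = np.log2(fold_threshold)
    fold_ok = diff > cut if direction == "up" else diff < -cut
    selected = fold_ok & (p_eff <= alpha)
    genes = tuple(expr.gene_ids[idx[i]] for i in np.flatnonzero(selected))
    if not genes:
        warnings.warn("derive_signature selected no genes", stacklevel=2)
    return GeneSignature(
        name=name or f"{condition}_vs_{control}_{direction}",
        genes=genes,
        direction=direction,
        provenance={
            "test": "anova",
            "fold_threshold": float(fold_threshold),
            "alpha": float(alpha),
            "adjust": adjust,
            "condition": condition,
            "control": control,
            "n_genes_tested": int(idx.size),
        },
    )


def signature_from_de_table(
    table: pd.DataFrame,
    fold_threshold: float,
    alpha: float,
    direction: str = "up",
    p_column: str = "p_value",
    name: str = "de_signature",
) -> GeneSignature:
    """Filter an external differential-expression table.

    Rows pass when |log2_fold_change| strictly exceeds log2(fold_threshold)
    with sign matching ``direction`` and ``p_column`` < alpha.
    """
    if table is None or len(table) == 0:
        raise ValidationError("differential-expression table is empty")
    required = {"gene_id", "log2_fold_change", p_column}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValidationError(f"DE table missing columns: {sorted(missing_cols)}")
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    for i, row in table.iterrows():
        fc, p = row["log2_fold_change"], row[p_column]
        if pd.isna(fc) or pd.isna(p) or not (0 <= p <= 1):
            raise ValidationError(
                f"malformed DE row {i} (gene {row['gene_id']!r}): "
                f"log2_fold_change={fc!r}, p={p!r}"
            )
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate genes in DE table: {dupes}")
    cut = np.log2(fold_threshold)
    fc = table["log2_fold_change"].to_numpy(float)
    p = table[p_column].to_numpy(float)
    mask = (fc > cut) if direction == "up" else (fc < -cut)
    mask &= p < alpha
    return GeneSignature(
        name=name,
        genes=tuple(table.loc[mask, "gene_id"]),
        direction=direction,
        provenance={
            "test": "external",
            "fold_threshold": float(fold_threshold),
            "alpha": float(alpha),
            "p_column": p_column,
        },
    )


# --- signature file formats: GMT and one-gene-per-line lists ---------------


def _dedupe(genes: Sequence[str], name: str) -> tuple[str, ...]:
    seen, out = set(), []
    for g in genes:
        if g in seen:
            warnings.warn(f"duplicate gene {g!r} in signature {name!r} collapsed", stacklevel=3)
        else:
            seen.add(g)
            out.append(g)
    return tuple(out)


def read_gmt(path: Union[str, Path]) -> list[GeneSignature]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sigs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        sigs.append(
            GeneSignature(name=name, genes=_dedupe(genes, name), provenance={"description": desc})
        )
    if not sigs:
        raise ValidationError(f"{path}: no gene sets found")
    return sigs


def write_gmt(signatures: Sequence[GeneSignature], path: Union[str, Path]) -> None:
    lines = []
    for sig in signatures:
        desc = str(sig.provenance.get("description", sig.direction))
        lines.append("\t".join([sig.name, desc, *sig.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_signatures(path: Union[str, Path]) -> list[GeneSignature]:
    """Read GMT (by .gmt suffix) or a plain one-gene-per-line list."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        return read_gmt(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not genes:
        raise ValidationError(f"{path}: empty gene list")
    return [GeneSignature(name=path.stem, genes=_dedupe(genes, path.stem))]


def write_signatures(signatures: Sequence[GeneSignature], path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        write_gmt(signatures, path)
    else:
        if len(signatures) != 1:
            raise ValidationError("plain gene-list format holds exactly one signature")
        path.write_text("\n".join(signatures[0].genes) + "\n")
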