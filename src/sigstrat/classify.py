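"""Per-sample signature classification and four-way stratification.

The central procedure: count a sample's signature genes beyond a log2
threshold (inclusive), compare that count to the rounded cohort-average
count with a one-sided Fisher exact test, call the sample positive when
p < alpha, and cross two such calls (RA-decreased x ERK-increased) into
a four-way category used for survival stratification.

The Fisher 2x2 construction treats the cohort average as a pseudo-sample
of the same signature size: [[k_s, G - k_s], [round(k_bar), G - round(k_bar)]]
with nearest-integer (ties-to-even) rounding.  This convention is isolated
in :func:`call_sample_status` for easy substitution and is recorded in the
result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSignature, ValidationError
from .stats import ContingencyTable2x2, TestResult, fisher_exact_2x2

__all__ = [
    "ClassificationParams",
    "StratificationResult",
    "SignatureScore",
    "count_beyond_threshold",
    "call_sample_status",
    "four_way_category",
    "classify_samples",
    "zscore_classify",
    "change_enrichment",
    "signature_score",
    "score_bin_compare",
    "CATEGORIES",
]

RA_CALLS = ("RA-D", "RA-ND")
ERK_CALLS = ("ERK-I", "ERK-NI")
CATEGORIES = ("RA-ND/ERK-NI", "RA-ND/ERK-I", "RA-D/ERK-NI", "RA-D/ERK-I")
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the counting classifier (log2 scale)."""

    low_threshold: float = -0.5
    high_threshold: float = 1.0
    fisher_alpha: float = 0.1
    fold_change_cut: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 < self.fisher_alpha < 1.0):
            raise ValidationError("fisher_alpha must lie in (0, 1)")
        if self.low_threshold >= self.high_threshold:
            raise ValidationError("low_threshold must be below high_threshold")
        if self.fold_change_cut <= 1.0:
            raise ValidationError("fold_change_cut must exceed 1")


@dataclass
class StratificationResult:
    """Per-sample counts, Fisher p-values, calls, and four-way category."""

    table: pd.DataFrame  # index sample_id; count_low, p_low, ra_call, count_high, p_high, erk_call, category
    params: ClassificationParams
    ra_genes_used: tuple[str, ...]
    erk_genes_used: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def category_counts(self) -> pd.Series:
        return self.table["category"].value_counts().reindex(CATEGORIES, fill_value=0)


@dataclass
class SignatureScore:
    """Per-sample unweighted mean expression over present signature genes."""

    scores: pd.Series
    n_genes_used: pd.Series
    signature: str


def count_beyond_threshold(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    threshold: float,
    mode: str,
) -> tuple[pd.Series, pd.Series, tuple[str, ...]]:
    """Count signature genes at or beyond ``threshold`` per sample.

    Comparison is inclusive ("-0.5 or under" / "1 or over"); missing cells
    are never counted.  Returns (counts, n_non_missing, genes_used).
    """
    if mode not in ("at_or_below", "at_or_above"):
        raise ValidationError(f"mode must be 'at_or_below' or 'at_or_above', got {mode!r}")
    present = set(expr.gene_ids)
    used = tuple(g for g in sig.genes if g in present)
    absent = [g for g in sig.genes if g not in present]
    if not used:
        raise ValidationError(
            f"no gene of signature {sig.name!r} present in matrix; missing: {absent}"
        )
    if absent:
        warnings.warn(
            f"{len(absent)} gene(s) of signature {sig.name!r} absent from matrix, dropped",
            stacklevel=2,
        )
    sub = expr.subset_genes(used)
    vals = sub.values
    with np.errstate(invalid="ignore"):
        hit = vals <= threshold if mode == "at_or_below" else vals >= threshold
    hit &= ~np.isnan(vals)
    counts = pd.Series(hit.sum(axis=0), index=expr.sample_ids, name="count")
    n_avail = pd.Series(
        (~np.isnan(vals)).sum(axis=0), index=expr.sample_ids, name="n_available"
    )
    return counts, n_avail, used


def cohort_reference_count(counts: pd.Series) -> int:
    """Rounded cohort-average count (nearest integer, ties-to-even).

    Single point of substitution for the reference of the Fisher table
    (mean vs median vs pooled counts).
    """
    return int(np.round(float(counts.mean())))


def call_sample_status(
    counts: pd.Series,
    signature_size: int,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Call each sample positive when its count significantly exceeds the cohort average.

    For a sample with count k and signature size G, the one-sided (greater)
    Fisher exact test is applied to [[k, G - k], [r, G - r]] where r is the
    rounded cohort mean count; positive iff p < alpha.
    """
    if signature_size <= 0:
        raise ValidationError("signature size must be positive")
    if len(counts) < 2:
        raise ValidationError("need at least 2 samples to form a cohort average")
    if (counts < 0).any() or (counts > signature_size).any():
        raise ValidationError("counts must lie in [0, signature_size]")
    ref = cohort_reference_count(counts)
    cache: dict[int, float] = {}

    def pval(k: int) -> float:
        if k not in cache:
            tbl = ContingencyTable2x2(k, signature_size - k, ref, signature_size - ref)
            cache[k] = fisher_exact_2x2(tbl, "greater").p_value
        return cache[k]

    p = counts.astype(int).map(pval)
    return pd.DataFrame(
        {"count": counts.astype(int), "p_value": p, "positive": p < alpha},
        index=counts.index,
    )


def four_way_category(ra_calls: pd.Series, erk_calls: pd.Series) -> pd.Series:
    """Concatenate the two per-sample calls into one of the four categories."""
    if set(ra_calls.index) != set(erk_calls.index):
        only_ra = set(ra_calls.index) - set(erk_calls.index)
        only_erk = set(erk_calls.index) - set(ra_calls.index)
        raise ValidationError(
            f"sample universes differ: only in RA calls {sorted(only_ra)}, "
            f"only in ERK calls {sorted(only_erk)}"
        )
    erk = erk_calls.reindex(ra_calls.index)
    out = ra_calls.astype("string") + "/" + erk.astype("string")
    out[ra_calls.isna() | erk.isna()] = UNCLASSIFIABLE
    return out.rename("category")


def classify_samples(
    expr: ExpressionMatrix,
    ra_sig: GeneSignature,
    erk_sig: GeneSignature,
    params: Optional[ClassificationParams] = None,
) -> StratificationResult:
    """Full per-sample stratification into the four RA/ERK categories."""
    params = params or ClassificationParams()
    c_low, avail_low, ra_used = count_beyond_threshold(
        expr, ra_sig, params.low_threshold, "at_or_below"
    )
    c_high, avail_high, erk_used = count_beyond_threshold(
        expr, erk_sig, params.high_threshold, "at_or_above"
    )
    ra_tab = call_sample_status(c_low, len(ra_used), params.fisher_alpha)
    erk_tab = call_sample_status(c_high, len(erk_used), params.fisher_alpha)

    ra_call = pd.Series(
        np.where(ra_tab["positive"], "RA-D", "RA-ND"), index=ra_tab.index, dtype="string"
    )
    erk_call = pd.Series(
        np.where(erk_tab["positive"], "ERK-I", "ERK-NI"), index=erk_tab.index, dtype="string"
    )
    # a sample whose signature genes are all missing is unclassifiable, not ND/NI
    ra_call[avail_low == 0] = pd.NA
    erk_call[avail_high == 0] = pd.NA

    table = pd.DataFrame(
        {
            "count_low": ra_tab["count"],
            "p_low": ra_tab["p_value"],
            "ra_call": ra_call,
            "count_high": erk_tab["count"],
            "p_high": erk_tab["p_value"],
            "erk_call": erk_call,
            "category": four_way_category(ra_call, erk_call),
        },
        index=ra_tab.index,
    )
    table.index.name = "sample_id"
    return StratificationResult(
        table=table,
        params=params,
        ra_genes_used=ra_used,
        erk_genes_used=erk_used,
        metadata={
            "fisher_reference": "rounded cohort mean count (ties-to-even)",
            "fisher_sidedness": "greater",
            "ra_reference_count": cohort_reference_count(c_low),
            "erk_reference_count": cohort_reference_count(c_high),
        },
    )


def zscore_classify(
    z_matrix: ExpressionMatrix, sig: GeneSignature
) -> tuple[pd.Series, tuple[str, ...]]:
    """Two-stage Z-score classification.

    Stage 1 retains signature genes whose cohort-mean Z exceeds 0; stage 2
    labels each sample 'high' iff its mean Z over the retained genes
    exceeds 0, else 'low'.  Z-scores must be relative to an external
    reference population: gene-wise standardization of the cohort itself
    makes every cohort-mean Z zero and stage 1 retains nothing.
    """
    present = [g for g in sig.genes if g in set(z_matrix.gene_ids)]
    if not present:
        raise ValidationError(f"no gene of signature {sig.name!r} present in matrix")
    sub = z_matrix.subset_genes(present)
    gene_mean = np.nanmean(sub.values, axis=1)
    # tolerance keeps exact-zero means (e.g. self-standardized cohorts,
    # where every gene mean is 0 up to float rounding) out of stage 1
    retained = [g for g, m in zip(sub.gene_ids, gene_mean) if m > 1e-12]
    if not retained:
        raise ValidationError(
            "signature not cohort-upregulated: no signature gene has mean Z > 0 "
            "(check that Z-scores reference an external population)"
        )
    kept = z_matrix.subset_genes(retained)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sample_mean = np.nanmean(kept.values, axis=0)
    labels = pd.Series(
        np.where(sample_mean > 0, "high", "low"), index=z_matrix.sample_ids, dtype="string"
    )
    labels[np.isnan(sample_mean)] = pd.NA
    return labels.rename("z_class"), tuple(retained)


def change_enrichment(
    expr_cancer: ExpressionMatrix,
    expr_normal: ExpressionMatrix,
    sig: GeneSignature,
    direction: str,
    fold_change_cut: float = 1.5,
) -> dict:
    """Test whether signature genes are enriched for cancer-vs-normal change.

    A gene is "changed" iff mean log2(cancer) - mean log2(normal) strictly
    exceeds log2(fold_change_cut) in the required direction.  The 2x2
    Fisher test (signature vs rest x changed vs not) is one-sided greater.
    """
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    if set(expr_cancer.gene_ids) != set(expr_normal.gene_ids):
        raise ValidationError("cancer and normal matrices must share the gene universe")
    if expr_normal.n_samples < 1:
        raise ValidationError("need at least one normal sample")
    normal = expr_normal.subset_genes(expr_cancer.gene_ids)
    delta = np.nanmean(expr_cancer.values, axis=1) - np.nanmean(normal.values, axis=1)
    cut = np.log2(fold_change_cut)
    changed = delta > cut if direction == "up" else delta < -cut

    in_sig = np.isin(expr_cancer.gene_ids, list(sig.genes))
    if not in_sig.any():
        raise ValidationError(f"no gene of signature {sig.name!r} present in matrix")
    if in_sig.all():
        raise ValidationError("signature exhausts the gene universe: no background genes")
    a = int(np.sum(changed & in_sig))
    b = int(np.sum(~changed & in_sig))
    c = int(np.sum(changed & ~in_sig))
    d = int(np.sum(~changed & ~in_sig))
    res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), "greater")
    return {
        "percent_changed": 100.0 * a / (a + b),
        "background_percent": 100.0 * c / (c + d),
        "test": res,
        "n_changed_signature": a,
        "n_changed_background": c,
    }


def signature_score(expr: ExpressionMatrix, sig: GeneSignature) -> SignatureScore:
    """Unweighted mean expression over the signature genes present per sample."""
    present = [g for g in sig.genes if g in set(expr.gene_ids)]
    if not present:
        raise ValidationError(f"no gene of signature {sig.name!r} present in matrix")
    sub = expr.subset_genes(present)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        means = np.nanmean(sub.values, axis=0)
    n_used = (~np.isnan(sub.values)).sum(axis=0)
    return SignatureScore(
        scores=pd.Series(means, index=expr.sample_ids, name=f"{sig.name}_score"),
        n_genes_used=pd.Series(n_used, index=expr.sample_ids, name="n_genes_used"),
        signature=sig.name,
    )


def score_bin_compare(
    score_a: pd.Series, score_b: pd.Series, n_bins: int = 3
) -> pd.DataFrame:
    """Mean of score_a within quantile bins of score_b (default tertiles)."""
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if set(score_a.index) != set(score_b.index):
        raise ValidationError("score series must share the sample universe")
    b = score_b.reindex(score_a.index)
    bins = pd.qcut(b, n_bins, labels=False, duplicates="drop")
    out = pd.DataFrame({"a": score_a, "bin": bins}).dropna()
    grouped = out.groupby("bin")["a"].agg(["mean", "count"])
    grouped.columns = ["mean_score_a", "n_samples"]
    grouped.index.name = "bin_of_b"
    return grouped
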