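"""Exact and rank-based statistical primitives.

The Fisher exact test is computed from integer binomial coefficients so
that tail sums are exact up to a single float rounding at the end; the
two-sided p-value follows the "probability mass no greater than observed"
convention of standard statistical software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_2x2",
    "bh_adjust",
    "one_way_anova",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "pairwise_wilcoxon",
    "pearson_correlation_matrix",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts; rows = condition-of-interest vs rest, columns = groups."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("degenerate margins: all cells are zero")

    @classmethod
    def from_rows(cls, rows) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(a, b, c, d)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` is populated only for chi-square-distributed statistics.
    ``note`` flags degenerate inputs handled by convention (e.g. zero
    variance) rather than by the nominal sampling distribution.
    """

    __test__ = False  # not a pytest class

    statistic: float
    p_value: float
    sidedness: str = "two-sided"
    df: Optional[int] = None
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if self.sidedness not in ("two-sided", "greater", "less"):
            raise ValidationError(f"invalid sidedness {self.sidedness!r}")
        if self.df is not None and self.df < 0:
            raise ValidationError("df must be non-negative")


def fisher_exact_2x2(table: ContingencyTable2x2, sidedness: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table at fixed margins.

    One-sided p-values are exact hypergeometric tail sums; the two-sided
    p-value sums the probabilities of all tables whose probability does
    not exceed that of the observed table.  Tail sums are accumulated as
    exact integers, so the result is correct to one float rounding.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_rows(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # unnormalized hypergeometric weights over the support at fixed margins
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = comb(n, c1)
    w_obs = weights[a]
    if sidedness == "greater":
        num = sum(w for x, w in weights.items() if x >= a)
    elif sidedness == "less":
        num = sum(w for x, w in weights.items() if x <= a)
    elif sidedness == "two-sided":
        num = sum(w for w in weights.values() if w <= w_obs)
    else:
        raise ValidationError(f"invalid sidedness {sidedness!r}")
    p = num / total
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = np.nan if a * d == 0 else np.inf
    return TestResult(statistic=odds, p_value=min(p, 1.0), sidedness=sidedness)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_groups(groups: Sequence[Sequence[float]], min_size: int = 1) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < min_size:
            raise ValidationError(f"group {i} has {g.size} observations (< {min_size})")
        if np.any(~np.isfinite(g)):
            raise ValidationError(f"group {i} contains non-finite values")
    return gs


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA F-test across k groups.

    Zero total variance is degenerate by convention: F = 0, p = 1.
    """
    gs = _as_groups(groups, min_size=2)
    allv = np.concatenate(gs)
    k, n = len(gs), allv.size
    grand = allv.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssb + ssw <= 1e-300:
        return TestResult(0.0, 1.0, note="degenerate: zero total variance")
    if ssw <= 1e-300:
        return TestResult(np.inf, 0.0, note="zero within-group variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*gs)
    return TestResult(float(f), float(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H-test with tie correction; df = k - 1."""
    gs = _as_groups(groups, min_size=1)
    k = len(gs)
    allv = np.concatenate(gs)
    if np.all(allv == allv[0]):
        return TestResult(0.0, 1.0, df=k - 1, note="degenerate: all values identical")
    h, p = sps.kruskal(*gs)
    return TestResult(float(h), float(p), df=k - 1)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], continuity: bool = True
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution for combined n <= 20 without ties; otherwise
    the normal approximation with tie correction (continuity correction
    applied by default, switchable off via ``continuity``).
    """
    xs, ys = _as_groups([x, y], min_size=1)
    combined = np.concatenate([xs, ys])
    has_ties = len(np.unique(combined)) < combined.size
    if combined.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        xs, ys, alternative="two-sided", method=method, use_continuity=continuity
    )
    return TestResult(float(res.statistic), float(res.pvalue))


def pairwise_wilcoxon(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjust: bool = True,
) -> list[dict]:
    """Wilcoxon rank-sum tests between all pairs of groups.

    Holm adjustment is applied by default (``adjust=False`` reports the
    raw p-values only, since the source procedure does not state an
    adjustment).
    """
    gs = _as_groups(groups, min_size=1)
    if labels is None:
        labels = [str(i) for i in range(len(gs))]
    pairs, results = [], []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            pairs.append((labels[i], labels[j]))
            results.append(wilcoxon_rank_sum(gs[i], gs[j]))
    raw = [r.p_value for r in results]
    adj = multipletests(raw, method="holm")[1] if adjust else raw
    return [
        {"pair": pair, "result": res, "p_adjusted": float(pa)}
        for pair, res, pa in zip(pairs, results, adj)
    ]


def pearson_correlation_matrix(matrix: np.ndarray) -> np.ndarray:
    """Gene-by-gene Pearson correlation over samples (rows = genes).

    Zero-variance rows yield NaN entries; the matrix is exactly symmetric
    with unit diagonal for well-defined rows.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValidationError("need a 2-d matrix with at least 2 samples (columns)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = np.corrcoef(m)
    corr = np.atleast_2d(corr)
    corr = (corr + corr.T) / 2.0
    np.clip(corr, -1.0, 1.0, out=corr)
    sd = m.std(axis=1)
    ok = sd > 0
    corr[~ok, :] = np.nan
    corr[:, ~ok] = np.nan
    di = np.diag_indices_from(corr)
    corr[di] = np.where(ok, 1.0, np.nan)
    return corr
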