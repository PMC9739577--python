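"""Kaplan–Meier estimation, k-group log-rank tests, and rank-based
location tests on uncensored times.

Tie convention: deaths precede censorings at equal times, i.e. subjects
censored exactly at an event time are counted at risk at that time.

The "events-only" curves condition on the outcome having occurred; they
are descriptive summaries of event-time distributions, not estimates of
the survival function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import ValidationError
from .stats import TestResult, kruskal_wallis, pairwise_wilcoxon

__all__ = [
    "SurvivalCurve",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "uncensored_location_test",
    "events_only_curve",
    "restricted_mean_survival",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        for name in ("event_times", "survival_prob", "at_risk", "n_events"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if np.any(np.diff(self.survival_prob) > 1e-12):
            raise ValidationError("survival probabilities must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation; S = 1 before the first event time."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival_prob[i - 1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


def _validate_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValidationError("need at least one subject")
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValidationError("times must be finite and non-negative")
    if not np.isin(e, [0, 1]).all():
        raise ValidationError("events must be 0 (censored) or 1 (event)")
    return t, e.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    At-risk sets include subjects censored exactly at the event time.
    """
    t, e = _validate_surv(times, events)
    evt = np.unique(t[e == 1])
    sorted_t = np.sort(t)
    n = t.size
    at_risk = n - np.searchsorted(sorted_t, evt, side="left")
    d = np.array([np.sum((t == tt) & (e == 1)) for tt in evt])
    surv = np.cumprod(1.0 - d / at_risk) if evt.size else np.array([])
    return SurvivalCurve(evt, surv, at_risk, d)


def restricted_mean_survival(curve: SurvivalCurve, t_max: float) -> float:
    """Area under the KM step function on [0, t_max] (last value carried forward)."""
    if t_max <= 0:
        raise ValidationError("t_max must be positive")
    knots = np.concatenate([[0.0], curve.event_times, [t_max]])
    knots = np.clip(knots, 0.0, t_max)
    s = np.concatenate([[1.0], curve.survival_prob, [np.nan]])  # value on [knot_i, knot_{i+1})
    area = 0.0
    for i in range(len(knots) - 1):
        area += s[i] * max(knots[i + 1] - knots[i], 0.0)
    return float(area)


def _risk_and_events_by_group(t, e, codes, k, evt):
    """n_gj (at risk) and d_gj (events) per group g at each event time j."""
    n_event_times = evt.size
    n_g = np.zeros((k, n_event_times))
    d_g = np.zeros((k, n_event_times))
    for g in range(k):
        tg = t[codes == g]
        eg = e[codes == g]
        st = np.sort(tg)
        n_g[g] = tg.size - np.searchsorted(st, evt, side="left")
        te = tg[eg == 1]
        if te.size:
            idx = np.searchsorted(evt, te)
            np.add.at(d_g[g], idx, 1)
    return n_g, d_g


def logrank_test(
    times: Sequence[float], events: Sequence[int], group_labels: Sequence
) -> TestResult:
    """k-sample log-rank test.

    Reports sum over groups of (O - E)^2 / E as a chi-square statistic
    with df = k - 1 (the classic k-group approximation); see
    :func:`pairwise_logrank` for the 2-group hypergeometric-variance form.
    """
    t, e = _validate_surv(times, events)
    labels = np.asarray(group_labels)
    if labels.shape != t.shape:
        raise ValidationError("group_labels must match times in length")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValidationError("need at least 2 groups")
    evt = np.unique(t[e == 1])
    if evt.size == 0:
        warnings.warn("no events observed; log-rank degenerate", stacklevel=2)
        return TestResult(0.0, 1.0, df=k - 1, note="degenerate: no events")
    n_g, d_g = _risk_and_events_by_group(t, e, codes, k, evt)
    n_tot = n_g.sum(axis=0)
    d_tot = d_g.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        expd = n_g * (d_tot / n_tot)
    O = d_g.sum(axis=1)
    E = np.nansum(expd, axis=1)
    mask = E > 0
    chi2 = float(np.sum((O[mask] - E[mask]) ** 2 / E[mask]))
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult(chi2, p, df=k - 1)


def _two_group_logrank(t, e, codes) -> TestResult:
    evt = np.unique(t[e == 1])
    if evt.size == 0:
        return TestResult(0.0, 1.0, df=1, note="degenerate: no events")
    n_g, d_g = _risk_and_events_by_group(t, e, codes, 2, evt)
    n_tot = n_g.sum(axis=0)
    d_tot = d_g.sum(axis=0)
    frac = n_g[0] / n_tot
    o_minus_e = np.sum(d_g[0] - frac * d_tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_tot * frac * (1 - frac) * (n_tot - d_tot) / (n_tot - 1)
    var = np.nansum(np.where(n_tot > 1, var, 0.0))
    if var <= 0:
        return TestResult(0.0, 1.0, df=1, note="degenerate: zero variance")
    chi2 = float(o_minus_e**2 / var)
    return TestResult(chi2, float(sps.chi2.sf(chi2, 1)), df=1)


def pairwise_logrank(
    times: Sequence[float], events: Sequence[int], group_labels: Sequence
) -> list[dict]:
    """Exact hypergeometric-variance 2-group log-rank for every pair of groups."""
    t, e = _validate_surv(times, events)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("need at least 2 groups")
    out = []
    for i in range(uniq.size):
        for j in range(i + 1, uniq.size):
            mask = (labels == uniq[i]) | (labels == uniq[j])
            codes = (labels[mask] == uniq[j]).astype(int)
            res = _two_group_logrank(t[mask], e[mask], codes)
            out.append({"pair": (uniq[i], uniq[j]), "result": res})
    return out


def uncensored_location_test(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Sequence,
    gate_alpha: float = 0.05,
    adjust_pairwise: bool = True,
) -> dict:
    """Kruskal–Wallis on event times of uncensored subjects, gatekept pairwise Wilcoxon.

    Restricts to event == 1 rows; groups without any event are dropped
    with a warning.  Pairwise Wilcoxon rank-sum tests over all pairs run
    only when the Kruskal–Wallis p-value falls below ``gate_alpha``.
    """
    t, e = _validate_surv(times, events)
    labels = np.asarray(group_labels)
    if labels.shape != t.shape:
        raise ValidationError("group_labels must match times in length")
    keep = e == 1
    t, labels = t[keep], labels[keep]
    groups, names = [], []
    for g in np.unique(np.asarray(group_labels)):
        vals = t[labels == g]
        if vals.size == 0:
            warnings.warn(f"group {g!r} has no uncensored observations; dropped", stacklevel=2)
            continue
        groups.append(vals)
        names.append(g)
    if len(groups) < 2:
        raise ValidationError("fewer than 2 groups with uncensored observations")
    kw = kruskal_wallis(groups)
    pairwise = (
        pairwise_wilcoxon(groups, labels=[str(n) for n in names], adjust=adjust_pairwise)
        if kw.p_value < gate_alpha
        else []
    )
    return {"kw": kw, "pairwise": pairwise, "groups": [str(n) for n in names]}


def events_only_curve(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """KM curve of the subjects who experienced the event (descriptive only).

    With every retained subject an event, the curve equals 1 minus the
    empirical CDF of the event times.
    """
    t, e = _validate_surv(times, events)
    if e.sum() == 0:
        raise ValidationError("no events: events-only curve undefined")
    return km_estimate(t[e == 1], np.ones(int(e.sum()), dtype=int))
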