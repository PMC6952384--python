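"""Subgroup-stratified clinical and outcome statistics.

Kaplan–Meier product-limit curves, the log-rank test, single-covariate Cox
regression (Newton–Raphson on the Breslow partial likelihood), exact
one-vs-rest cluster–marker association, rank-sum / one-way ANOVA group
comparisons with Benjamini–Hochberg adjustment across a marker panel, and
a Shapiro–Wilk normality screen.

The group-comparison test is the unpaired Mann–Whitney rank-sum test
(exact for small samples without ties, normal approximation with tie
correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import as_float_array
from .enrichment import _bh


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit estimate of survival."""

    event_times: np.ndarray       # distinct times with at least one event
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray          # S(t) just after each event time
    censor_times: np.ndarray
    median: float                 # smallest t with S(t) <= 0.5 (nan if never)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = as_float_array(times)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if (times < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    distinct = np.unique(times[events == 1])
    at_risk, n_events, surv = [], [], []
    s = 1.0
    for t in distinct:
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        n_events.append(d_i)
        surv.append(s)
    surv = np.array(surv)
    median = np.nan
    reached = np.flatnonzero(surv <= 0.5)
    if reached.size:
        median = float(distinct[reached[0]])
    return SurvivalCurve(
        event_times=distinct, at_risk=np.array(at_risk), n_events=np.array(n_events),
        survival=surv, censor_times=np.sort(times[events == 0]), median=median,
    )


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------


def logrank_test(groups: list[tuple]) -> tuple[float, float]:
    """k-sample log-rank chi-square (k - 1 df) and p-value.

    ``groups`` is a list of (times, events) pairs.  Observed minus expected
    event counts per group are accumulated over distinct event times with
    the usual hypergeometric variance.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times = [as_float_array(t) for t, _ in groups]
    events = [np.asarray(e, dtype=int) for _, e in groups]
    if sum(int(e.sum()) for e in events) == 0:
        raise ValueError("no events in any group")
    k = len(groups)
    all_event_times = np.unique(np.concatenate([t[e == 1] for t, e in zip(times, events)]))
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for t in all_event_times:
        n_g = np.array([(tt >= t).sum() for tt in times], dtype=float)
        d_g = np.array([((tt == t) & (ee == 1)).sum() for tt, ee in zip(times, events)], dtype=float)
        n, d = n_g.sum(), d_g.sum()
        if n <= 1:
            continue
        observed += d_g
        expected += d * n_g / n
        frac = n_g / n
        v = d * (n - d) / (n - 1)
        var += v * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[: k - 1]
    vv = var[: k - 1, : k - 1]
    chi2 = float(diff @ np.linalg.pinv(vv) @ diff)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# Cox regression (single binary covariate, Breslow ties)
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    pval: float
    beta: float
    se: float
    converged: bool


def cox_hr(times, events, group) -> CoxResult:
    """Single-covariate Cox regression by Newton iteration (Breslow ties).

    ``group`` is a binary indicator; the returned hazard ratio is
    exp(beta) for group 1 versus group 0 with a Wald 95% CI.  A monotone
    partial likelihood (for example all events in one group) is flagged as
    a non-converged, infinite-HR result.
    """
    times = as_float_array(times)
    events = np.asarray(events, dtype=int)
    x = np.asarray(group, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("group must be binary 0/1")
    for g in (0.0, 1.0):
        if events[x == g].sum() < 1:
            raise ValueError(f"group {int(g)} has no events")

    event_times = np.unique(times[events == 1])
    beta = 0.0
    converged = False
    for _ in range(100):
        u = 0.0
        info = 0.0
        for t in event_times:
            risk = times >= t
            ev = (times == t) & (events == 1)
            d = int(ev.sum())
            w = np.exp(beta * x[risk])
            s0 = w.sum()
            s1 = (w * x[risk]).sum()
            xbar = s1 / s0
            u += x[ev].sum() - d * xbar
            info += d * (xbar - xbar ** 2)   # binary x: E[x^2] = E[x]
        if info <= 1e-12:
            break
        step = u / info
        beta_new = beta + np.clip(step, -5.0, 5.0)
        if abs(beta_new - beta) < 1e-9:
            beta = beta_new
            converged = True
            break
        beta = beta_new
        if abs(beta) > 15:
            break
    if not converged or abs(beta) > 15:
        hr = float(np.inf) if beta > 0 else 0.0
        return CoxResult(hr, np.nan, np.nan, np.nan, beta, np.nan, False)
    # recompute information at the solution for the Wald SE
    info = 0.0
    for t in event_times:
        risk = times >= t
        d = int(((times == t) & (events == 1)).sum())
        w = np.exp(beta * x[risk])
        xbar = (w * x[risk]).sum() / w.sum()
        info += d * (xbar - xbar ** 2)
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        pval=p, beta=float(beta), se=se, converged=True,
    )


# ---------------------------------------------------------------------------
# association and group comparisons
# ---------------------------------------------------------------------------


def cluster_marker_association(clusters, marker) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact one-vs-rest association of a binary marker with each cluster.

    Returns the cluster-by-marker contingency table and a per-cluster frame
    with the 2x2 Fisher exact p (two-sided hypergeometric), the odds ratio,
    and BH-adjusted q across clusters.
    """
    clusters = pd.Series(clusters)
    marker = pd.Series(marker).reindex(clusters.index)
    if marker.isna().all():
        raise ValueError("marker is entirely missing")
    keep = marker.notna()
    clusters, marker = clusters[keep], marker[keep].astype(bool)
    if clusters.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    n_marker = marker.astype(int).groupby(clusters).sum()
    n_total = clusters.value_counts()
    table = pd.DataFrame({
        "absent": (n_total - n_marker).astype(int),
        "present": n_marker.astype(int),
    }).sort_index()
    table.index.name = "cluster"
    rows = []
    for c in table.index:
        a = int(table.loc[c, "present"])
        b = int(table.loc[c, "absent"])
        cc = int(table["present"].sum() - a)
        d = int(table["absent"].sum() - b)
        odds, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
        rows.append({"cluster": c, "n_marker": a, "n_total": a + b, "odds_ratio": odds, "pval": p})
    result = pd.DataFrame(rows).set_index("cluster")
    result["qval"] = _bh(result["pval"].to_numpy())
    return table, result


def group_compare(values, groups, test: str = "wilcoxon_ranksum") -> pd.DataFrame:
    """Compare marker values between groups; BH across the marker panel.

    ``values`` is a Series (single marker) or DataFrame with one column per
    marker (e.g. CD34, p-S6K, p-MAPK positive-cell fractions); ``groups``
    the per-sample group labels.  ``test`` is ``wilcoxon_ranksum``
    (2 groups, unpaired Mann–Whitney) or ``anova`` (one-way F).
    """
    if isinstance(values, pd.Series):
        values = values.to_frame(values.name or "marker")
    values = pd.DataFrame(values)
    groups = pd.Series(groups).reindex(values.index)
    unique = sorted(groups.dropna().unique())
    if len(unique) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for marker in values.columns:
        per_group = [values.loc[(groups == g).to_numpy(), marker].dropna().to_numpy() for g in unique]
        if any(len(v) < 2 for v in per_group):
            raise ValueError(f"marker {marker!r}: every group needs at least 2 values")
        if np.ptp(np.concatenate(per_group)) == 0:
            raise ValueError(f"marker {marker!r}: constant values in all groups")
        if test == "wilcoxon_ranksum":
            if len(unique) != 2:
                raise ValueError("rank-sum test requires exactly 2 groups")
            stat, p = stats.mannwhitneyu(per_group[0], per_group[1], alternative="two-sided")
        elif test == "anova":
            stat, p = stats.f_oneway(*per_group)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"marker": marker, "statistic": float(stat), "pval": float(p)})
    out = pd.DataFrame(rows).set_index("marker")
    out["qval"] = _bh(out["pval"].to_numpy())
    return out


def normality_screen(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p, used to annotate the recommended group test."""
    values = as_float_array(values)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk needs between 3 and 5000 observations")
    if np.ptp(values) == 0:
        raise ValueError("constant input")
    w, p = stats.shapiro(values)
    return float(w), float(p)
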