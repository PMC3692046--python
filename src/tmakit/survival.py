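"""Kaplan-Meier estimation, Mantel-Cox log-rank testing and per-marker screening.

Survival times are right-censored follow-up in months.  Groups come from one
of three stratification modes: MAP labels of a fitted Gaussian mixture
("mixture"), empirical tertiles ("tertile" -- the fallback when mixture
modelling returns a single component), or raw score levels ("categorical").
A screen runs stratify -> log-rank for every marker and applies
Benjamini-Hochberg FDR across the markers actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .distribution import MixtureModel, UNASSIGNED, assign_groups, select_model
from .io import LinkedDataset


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times in ascending order; ``survival``
    the estimate just after each event time; ``at_risk``/``events`` the
    n_i and d_i entering each factor (1 - d_i/n_i).  Ties between events and
    censorings at the same time count the events first (censored subjects
    remain in the risk set at their own time).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censor_times: np.ndarray
    n: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


@dataclass
class LogRankResult:
    """Mantel-Cox log-rank chi-square with df = (non-empty groups) - 1."""

    chi_square: float
    df: int
    p_raw: float
    group_sizes: list[int]
    marker: str | None = None
    mode: str | None = None
    p_fdr: float | None = None


@dataclass
class ScreenResult:
    """Per-marker log-rank results (sorted by adjusted p) plus skipped markers."""

    results: list[LogRankResult]
    skipped: list[dict] = field(default_factory=list)


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise DegenerateDataError("no observations")
    if np.any(t < 0):
        raise ValidationError("negative survival time")
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    d_counts = []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_counts.append(d_i)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        events=np.array(d_counts, dtype=int),
        censor_times=np.sort(t[e == 0]),
        n=t.size,
    )


def logrank_test(group_labels, times, events) -> LogRankResult:
    """Mantel-Cox log-rank test across two or more groups.

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation given the risk sets; the statistic
    is (O-E)' V^{-1} (O-E) over all but one group (dropped so V is
    invertible), referred to chi-square with (groups - 1) df.
    """
    labels = np.asarray(group_labels)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    groups = [g for g in np.unique(labels)]
    sizes = [int(np.sum(labels == g)) for g in groups]
    groups = [g for g, sz in zip(groups, sizes) if sz > 0]
    if len(groups) < 2:
        raise DegenerateDataError("log-rank test needs >=2 non-empty groups")
    if e.sum() == 0:
        raise DegenerateDataError("no events to compare")

    G = len(groups)
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    member = np.stack([labels == g for g in groups])  # [G x n]
    for et in np.unique(t[e == 1]):
        risk = t >= et
        n = risk.sum()
        d = int(np.sum((t == et) & (e == 1)))
        if n <= 1:
            ng = member[:, risk].sum(axis=1)
            O += np.array([np.sum((t == et) & (e == 1) & member[g]) for g in range(G)])
            E += d * ng / n
            continue
        ng = member[:, risk].sum(axis=1).astype(float)
        dg = np.array([np.sum((t == et) & (e == 1) & member[g]) for g in range(G)],
                      dtype=float)
        O += dg
        E += d * ng / n
        frac = ng / n
        hyper = d * (n - d) / (n - 1)
        # V_gh = sum_t d(n-d)/(n-1) * (delta_gh n_g/n - n_g n_h/n^2)
        V += hyper * (np.diag(frac) - np.outer(frac, frac))

    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi = max(chi, 0.0)
    df = G - 1
    p = float(stats.chi2.sf(chi, df))
    return LogRankResult(chi_square=chi, df=df, p_raw=max(p, np.nextafter(0, 1)),
                         group_sizes=[int(np.sum(labels == g)) for g in groups])


def tertile_labels(values) -> np.ndarray:
    """Split at the 1/3 and 2/3 empirical quantiles (linear interpolation).

    Ties with a boundary go to the lower group; missing values are
    ``UNASSIGNED`` (-1).
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if np.unique(obs).size < 3:
        raise DegenerateDataError("tertile split needs >=3 distinct values")
    q1, q2 = np.quantile(obs, [1 / 3, 2 / 3])
    out = np.full(v.shape, UNASSIGNED, dtype=int)
    m = ~np.isnan(v)
    out[m] = np.where(v[m] <= q1, 0, np.where(v[m] <= q2, 1, 2))
    return out


def categorical_labels(values) -> np.ndarray:
    """One group per observed score level, mean-ordered by construction."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, UNASSIGNED, dtype=int)
    m = ~np.isnan(v)
    levels = np.unique(v[m])
    out[m] = np.searchsorted(levels, v[m])
    return out


def stratify(values, mode: str, model: MixtureModel | None = None) -> np.ndarray:
    """Group labels for one marker under the requested stratification mode.

    mixture -> MAP labels of a fitted (K >= 2) mixture; a unimodal model is
    refused with a hint to fall back to tertiles.  tertile -> thirds at the
    1/3 and 2/3 quantiles.  categorical -> one group per score level.
    Missing values are labelled ``UNASSIGNED``.
    """
    if mode == "mixture":
        if model is None:
            raise ValidationError("mixture mode requires a fitted MixtureModel")
        if model.K < 2:
            raise DegenerateDataError(
                "mixture model is unimodal (K=1); survival grouping is not "
                "available -- use tertile stratification instead"
            )
        return assign_groups(model, values)
    if mode == "tertile":
        return tertile_labels(values)
    if mode == "categorical":
        return categorical_labels(values)
    raise ValueError(f"unknown stratification mode {mode!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def survival_screen(linked: LinkedDataset, mode: str = "mixture",
                    seed: int = 0, K_max: int = 9,
                    n_restarts: int = 10) -> ScreenResult:
    """Log-rank screen over every marker with BH FDR across tested markers.

    Markers refused by their stratifier (unimodal mixtures, too few distinct
    values, all-missing, single-group) are excluded from the BH universe and
    listed in ``skipped`` with the reason.  Results are sorted by adjusted p.
    """
    table = linked.markers
    results: list[LogRankResult] = []
    skipped: list[dict] = []
    for marker in table.marker_names:
        v = table.marker_values(marker)
        try:
            if mode == "mixture":
                model = select_model(v, K_max=K_max, seed=seed,
                                     n_restarts=n_restarts)
                labels = stratify(v, "mixture", model=model)
            else:
                labels = stratify(v, mode)
            keep = labels != UNASSIGNED
            if keep.sum() < 2:
                raise DegenerateDataError("too few assigned samples")
            res = logrank_test(labels[keep], linked.survival.time[keep],
                               linked.survival.event[keep])
        except DegenerateDataError as exc:
            skipped.append({"marker": marker, "reason": str(exc)})
            continue
        res.marker = marker
        res.mode = mode
        results.append(res)
    if not results:
        raise DegenerateDataError("no marker could be tested")
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
    results.sort(key=lambda r: (r.p_fdr, r.p_raw, r.marker))
    return ScreenResult(results=results, skipped=skipped)
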