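"""Pairwise marker association and correlation-network construction.

Three association measures are supported: Spearman's rho (monotone
relationships), Pearson's r (linear) and mutual information (arbitrary
dependency, unsigned).  Spearman significance follows a three-regime scheme
keyed on the pairwise-complete sample size n and the presence of rank ties:

* n <= 9, no ties: exact two-sided p from the full permutation null of
  S = sum d_i^2 (computed by dynamic programming over rank subsets, which
  enumerates the same n! distribution without materialising it);
* 10 <= n < 1290, no ties: the Edgeworth-expansion tail approximation of
  algorithm AS 89 (Best & Roberts);
* n >= 1290 or any ties: the Student-t approximation
  t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df.

Pearson p-values always use the t approximation; mutual-information
p-values come from a seeded permutation null.  Adjusted p-values
(Benjamini-Yekutieli recommended, Benjamini-Hochberg, or Bonferroni)
threshold the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import networkx as nx
from scipy import stats

from .errors import DegenerateDataError
from .io import MarkerTable

SPEARMAN_EXACT_MAX_N = 9
SPEARMAN_T_MIN_N = 1290


@dataclass
class EdgeResult:
    """One scored marker pair; ``marker_a`` < ``marker_b`` lexicographically."""

    marker_a: str
    marker_b: str
    method: str
    statistic: float
    sign: int
    n_used: int
    p_raw: float
    p_adj: float | None = None
    p_regime: str | None = None


@dataclass
class Network:
    """Thresholded correlation graph plus the full unthresholded edge table."""

    nodes: list[str]
    edges: list[EdgeResult]
    all_edges: list[EdgeResult]
    degenerate: list[dict]
    components: list[set]
    alpha: float
    method: str
    adjust: str

    @property
    def degrees(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for e in self.edges:
            d[e.marker_a] += 1
            d[e.marker_b] += 1
        return d

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.marker_a, e.marker_b, statistic=e.statistic,
                       sign=e.sign, p_raw=e.p_raw, p_adj=e.p_adj)
        return g


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = ~np.isnan(x) & ~np.isnan(y)
    return x[m], y[m]


@lru_cache(maxsize=16)
def exact_s_distribution(n: int) -> tuple:
    """Null distribution of S = sum (R_i - i)^2 over all n! rank permutations.

    Returned as (counts, total) where counts[s] is the number of
    permutations attaining S = s.  Computed by dynamic programming on the
    subset of ranks already placed, equivalent to full enumeration.
    """
    max_s = n * (n * n - 1) // 3
    size = max_s + 1
    dist = {0: np.zeros(size, dtype=np.int64)}
    dist[0][0] = 1
    for mask in range(1, 1 << n):
        arr = np.zeros(size, dtype=np.int64)
        pos = bin(mask).count("1") - 1  # 0-based position being filled
        rem = mask
        while rem:
            low = rem & -rem
            r = low.bit_length() - 1
            prev = dist.get(mask ^ low)
            if prev is not None:
                d2 = (pos - r) ** 2
                if d2 == 0:
                    arr += prev
                else:
                    arr[d2:] += prev[:-d2]
            rem ^= low
        dist[mask] = arr
    counts = dist[(1 << n) - 1]
    return tuple(int(c) for c in counts), int(counts.sum())


def _spearman_exact_p(rho: float, n: int) -> float:
    counts, total = exact_s_distribution(n)
    denom = n * (n * n - 1)
    s_vals = np.arange(len(counts))
    rho_vals = 1.0 - 6.0 * s_vals / denom
    extreme = np.abs(rho_vals) >= abs(rho) - 1e-12
    return float(np.asarray(counts)[extreme].sum() / total)


# Edgeworth-expansion coefficients of algorithm AS 89 (upper tail of S)
_AS89_C = (0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932,
           0.0879, 0.0151, 0.0072, 0.0831, 0.0131, 0.00046)


def _as89_upper_tail(s: float, n: int) -> float:
    """Pr(S >= s) under the null, AS 89 Edgeworth approximation."""
    c1, c2, c3, c4, c5, c6, c7, c8, c9, c10, c11, c12 = _AS89_C
    nf = float(n)
    b = 1.0 / nf
    x = (6.0 * (s - 1.0) * b / (nf * nf - 1.0) - 1.0) * np.sqrt(1.0 / b - 1.0)
    y = x * x
    u = x * b * (c1 + b * (c2 + c3 * b)
                 + y * (-c4 + b * (c5 + c6 * b)
                        - y * b * (c7 + c8 * b
                                   - y * (c9 - c10 * b
                                          + y * b * (c11 - c12 * y)))))
    p = u / np.exp(y / 2.0) + stats.norm.sf(x)
    return float(min(max(p, 0.0), 1.0))


def _spearman_as89_p(rho: float, n: int) -> float:
    denom = n * (n * n - 1)
    s = (1.0 - rho) * denom / 6.0
    mirror = denom / 3.0 - s  # S is symmetric about (n^3-n)/6 under the null
    upper = _as89_upper_tail(s, n)          # Pr(rho' <= rho)
    lower = _as89_upper_tail(mirror, n)     # Pr(rho' >= rho)
    return float(min(1.0, 2.0 * min(upper, lower)))


def _t_approx_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return np.nextafter(0, 1)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(min(1.0, 2.0 * stats.t.sf(abs(t), n - 2)))


def _edge_names(name_a: str, name_b: str):
    return (name_a, name_b) if name_a <= name_b else (name_b, name_a)


def spearman_edge(x, y, name_a: str = "x", name_b: str = "y") -> EdgeResult:
    """Spearman rank correlation on mid-ranks with regime-dependent p-value."""
    xo, yo = _pairwise_complete(x, y)
    n = xo.size
    if n < 4:
        raise DegenerateDataError(f"need >=4 pairwise-complete values, got {n}")
    if np.ptp(xo) == 0 or np.ptp(yo) == 0:
        raise DegenerateDataError("zero variance in one of the vectors")
    rx = stats.rankdata(xo)
    ry = stats.rankdata(yo)
    ties = (np.unique(rx).size < n) or (np.unique(ry).size < n)
    if ties:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        s = float(np.sum((rx - ry) ** 2))  # exact for untied ranks
        rho = 1.0 - 6.0 * s / (n * (n * n - 1))
    if ties or n >= SPEARMAN_T_MIN_N:
        p = _t_approx_p(rho, n)
        regime = "t_approx"
    elif n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(rho, n)
        regime = "exact_enumeration"
    else:
        p = _spearman_as89_p(rho, n)
        regime = "AS89_edgeworth"
    a, b = _edge_names(name_a, name_b)
    return EdgeResult(marker_a=a, marker_b=b, method="spearman", statistic=rho,
                      sign=int(np.sign(rho)), n_used=n,
                      p_raw=max(p, np.nextafter(0, 1)), p_regime=regime)


def pearson_edge(x, y, name_a: str = "x", name_b: str = "y") -> EdgeResult:
    """Pearson correlation with the Student-t significance approximation."""
    xo, yo = _pairwise_complete(x, y)
    n = xo.size
    if n < 4:
        raise DegenerateDataError(f"need >=4 pairwise-complete values, got {n}")
    if np.ptp(xo) == 0 or np.ptp(yo) == 0:
        raise DegenerateDataError("zero variance in one of the vectors")
    r = float(np.corrcoef(xo, yo)[0, 1])
    p = _t_approx_p(r, n)
    a, b = _edge_names(name_a, name_b)
    return EdgeResult(marker_a=a, marker_b=b, method="pearson", statistic=r,
                      sign=int(np.sign(r)), n_used=n,
                      p_raw=max(p, np.nextafter(0, 1)), p_regime="t_approx")


def _equal_frequency_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    # rank-based assignment: sorted order sliced into n_bins equal chunks
    order = np.argsort(v, kind="stable")
    bins = np.empty(v.size, dtype=int)
    bins[order] = np.minimum((np.arange(v.size) * n_bins) // v.size, n_bins - 1)
    return bins


def _plugin_mi(bx: np.ndarray, by: np.ndarray, n_bx: int, n_by: int) -> float:
    n = bx.size
    joint = np.bincount(bx * n_by + by, minlength=n_bx * n_by).reshape(n_bx, n_by)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def mi_edge(x, y, n_perm: int = 1000, seed: int = 0,
            name_a: str = "x", name_b: str = "y",
            x_categorical: bool = False, y_categorical: bool = False,
            ) -> EdgeResult:
    """Plug-in mutual information (nats) with a seeded permutation p-value.

    Continuous variables are discretised by equal-frequency binning into
    B = clamp(floor(sqrt(n)), 2, 10) bins; categorical markers keep their
    native levels.  p = (1 + #{perm MI >= observed}) / (1 + n_perm).
    """
    xo, yo = _pairwise_complete(x, y)
    n = xo.size
    if n < 8:
        raise DegenerateDataError(f"need >=8 pairwise-complete values, got {n}")
    B = int(np.clip(int(np.sqrt(n)), 2, 10))
    if x_categorical:
        bx = np.searchsorted(np.unique(xo), xo)
        n_bx = int(bx.max()) + 1
    else:
        bx, n_bx = _equal_frequency_bins(xo, B), B
    if y_categorical:
        by = np.searchsorted(np.unique(yo), yo)
        n_by = int(by.max()) + 1
    else:
        by, n_by = _equal_frequency_bins(yo, B), B
    mi = _plugin_mi(bx, by, n_bx, n_by)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(by)
        if _plugin_mi(bx, perm, n_bx, n_by) >= mi - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    a, b = _edge_names(name_a, name_b)
    return EdgeResult(marker_a=a, marker_b=b, method="mi", statistic=mi,
                      sign=0, n_used=n, p_raw=p, p_regime="permutation")


def adjust_pvalues(p_values, method: str = "BY") -> np.ndarray:
    """Multiple-testing adjustment: BY (step-up with harmonic factor), BH, Bonferroni."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    method = method.upper()
    if method == "BONFERRONI":
        return np.minimum(1.0, m * p)
    if method in ("BH", "BY"):
        factor = float(np.sum(1.0 / np.arange(1, m + 1))) if method == "BY" else 1.0
        order = np.argsort(p, kind="stable")
        ranked = p[order] * factor * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def build_network(table: MarkerTable, method: str = "spearman",
                  alpha: float = 0.05, adjust: str = "BY",
                  n_perm: int = 1000, seed: int = 0) -> Network:
    """Score every marker pair, adjust p-values, and threshold at p_adj <= alpha.

    The full (unthresholded) edge table is always retained; pairs refused by
    the edge operation (too few complete observations, zero variance) are
    listed in ``degenerate`` and excluded from the adjustment universe m.
    Connected components cover all markers, isolated nodes included.
    """
    markers = table.marker_names
    if len(markers) < 2:
        raise DegenerateDataError("need >=2 markers to build a network")
    collapsed = {m: table.marker_values(m) for m in markers}
    edges: list[EdgeResult] = []
    degenerate: list[dict] = []
    for ka, kb in combinations(markers, 2):
        try:
            if method == "spearman":
                e = spearman_edge(collapsed[ka], collapsed[kb], ka, kb)
            elif method == "pearson":
                e = pearson_edge(collapsed[ka], collapsed[kb], ka, kb)
            elif method == "mi":
                e = mi_edge(collapsed[ka], collapsed[kb], n_perm=n_perm,
                            seed=seed, name_a=ka, name_b=kb,
                            x_categorical=table.score_kind.get(ka) == "categorical",
                            y_categorical=table.score_kind.get(kb) == "categorical")
            else:
                raise ValueError(f"unknown method {method!r}")
        except DegenerateDataError as exc:
            degenerate.append({"marker_a": ka, "marker_b": kb, "reason": str(exc)})
            continue
        edges.append(e)
    adj = adjust_pvalues([e.p_raw for e in edges], method=adjust)
    for e, a in zip(edges, adj):
        e.p_adj = float(a)
    kept = [e for e in edges if e.p_adj <= alpha]
    net = Network(nodes=list(markers), edges=kept, all_edges=edges,
                  degenerate=degenerate, components=[], alpha=alpha,
                  method=method, adjust=adjust)
    net.components = [set(c) for c in nx.connected_components(net.to_graph())]
    return net
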