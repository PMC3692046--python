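"""Per-marker score distributions: adaptive KDE and BIC-selected Gaussian mixtures.

Continuous marker scores are summarised two ways: an adaptive-bandwidth
kernel density estimate (Abramson square-root law over a Silverman pilot)
for visual exploration, and a univariate Gaussian mixture fitted by EM with
the number of components chosen by the Bayesian information criterion.  The
mixture defines patient groups (MAP responsibilities) that downstream
survival analysis stratifies on.  Categorical markers take a histogram path
and are never passed to the KDE/GMM machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import DegenerateDataError

UNASSIGNED = -1


@dataclass
class DensityEstimate:
    """Adaptive-bandwidth Gaussian-kernel density on an evaluation grid.

    ``pilot_bandwidth`` is the fixed Silverman bandwidth of the pilot pass;
    ``local_bandwidths`` are the per-datum bandwidths of the adaptive pass.
    """

    grid: np.ndarray
    density: np.ndarray
    pilot_bandwidth: float
    local_bandwidths: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class MixtureModel:
    """K-component univariate Gaussian mixture with per-component SDs.

    Components are sorted by ascending mean.  ``bic`` uses the convention
    -2*logL + p*ln(n) with p = 3K - 1 free parameters; smaller is better.
    ``assignments`` holds the MAP component index per fitted sample.
    """

    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    responsibilities: np.ndarray
    assignments: np.ndarray
    n: int
    converged: bool = True
    n_iter: int = 0

    @property
    def unimodal(self) -> bool:
        return self.K == 1

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "weights": [float(w) for w in self.weights],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "log_likelihood": float(self.log_likelihood),
            "bic": float(self.bic),
            "n": int(self.n),
        }


def _clean_values(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[~np.isnan(v)]


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    n = x.size
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = sd if sd > 0 else 1.0
    return 0.9 * scale * n ** (-0.2)


def kde_adaptive(values, grid_size: int = 512) -> DensityEstimate:
    """Adaptive-bandwidth kernel density estimate.

    A Gaussian pilot estimate at Silverman's fixed bandwidth supplies
    per-datum local bandwidths via Abramson's square-root law,
    lambda_i proportional to pilot(x_i)^(-1/2) normalised by the geometric
    mean, so the kernel widens in the tails and sharpens in dense regions.
    The grid spans the data range plus 3 pilot bandwidths on each side.
    """
    x = _clean_values(values)
    if np.unique(x).size < 2:
        raise DegenerateDataError("degenerate distribution: <2 distinct values")
    n = x.size
    h = silverman_bandwidth(x)

    pilot_at_data = norm.pdf((x[:, None] - x[None, :]) / h).sum(axis=1) / (n * h)
    log_lam = -0.5 * np.log(pilot_at_data)
    log_lam -= log_lam.mean()  # normalise by geometric mean
    lam = np.exp(log_lam)
    local_h = h * lam

    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    z = (grid[:, None] - x[None, :]) / local_h[None, :]
    density = (norm.pdf(z) / local_h[None, :]).sum(axis=1) / n
    return DensityEstimate(grid=grid, density=density, pilot_bandwidth=h,
                           local_bandwidths=local_h)


def histogram_counts(values) -> dict[float, int]:
    """Level counts for a categorical marker (the non-KDE display path)."""
    x = _clean_values(values)
    levels, counts = np.unique(x, return_counts=True)
    return {float(l): int(c) for l, c in zip(levels, counts)}


_LOG_2PI = np.log(2.0 * np.pi)


def _loglik_matrix(x, weights, means, sds):
    # hand-rolled normal logpdf: scipy call overhead dominates EM otherwise
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return (np.log(weights)[None, :] - np.log(sds)[None, :]
            - 0.5 * (z * z + _LOG_2PI))


def _em(x: np.ndarray, K: int, weights, means, sds, var_floor: float,
        tol: float = 1e-8, max_iter: int = 1000):
    n = x.size
    ll_old = -np.inf
    xc = x[:, None]
    for it in range(max_iter):
        log_p = _loglik_matrix(x, weights, means, sds)
        mx = log_p.max(axis=1)
        log_norm = mx + np.log(np.exp(log_p - mx[:, None]).sum(axis=1))
        ll = float(log_norm.sum())
        resp = np.exp(log_p - log_norm[:, None])
        nk = np.maximum(resp.sum(axis=0), 1e-300)
        weights = nk / n
        means = (resp * xc).sum(axis=0) / nk
        var = (resp * (xc - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))
        if ll - ll_old < tol and it > 0:
            return weights, means, sds, ll, True, it + 1
        ll_old = ll
    return weights, means, sds, ll_old, False, max_iter


@njit(cache=False)
def _em_kernel(x, W, M, S, var_floor, tol, max_iter):  # pragma: no cover
    """Compiled EM over R restarts; W/M/S are [R x K] parameter stacks.

    Mirrors :func:`_em` (same update equations and convergence rule); the
    per-sample inner loops avoid numpy dispatch overhead, which dominates
    at TMA cohort sizes.
    """
    R, K = W.shape
    n = x.size
    ll_out = np.empty(R)
    conv = np.zeros(R, np.bool_)
    iters = np.zeros(R, np.int64)
    logp = np.empty(K)
    for r in range(R):
        w = W[r]
        mu = M[r]
        sd = S[r]
        ll_old = -np.inf
        it_done = max_iter
        for it in range(max_iter):
            nk = np.zeros(K)
            sx = np.zeros(K)
            sxx = np.zeros(K)
            lconst = np.empty(K)
            inv_sd = np.empty(K)
            for k in range(K):
                lconst[k] = np.log(w[k]) - np.log(sd[k]) - 0.5 * _LOG_2PI
                inv_sd[k] = 1.0 / sd[k]
            ll = 0.0
            for i in range(n):
                xi = x[i]
                mx = -1e308
                for k in range(K):
                    z = (xi - mu[k]) * inv_sd[k]
                    lp = lconst[k] - 0.5 * z * z
                    logp[k] = lp
                    if lp > mx:
                        mx = lp
                ssum = 0.0
                for k in range(K):
                    logp[k] = np.exp(logp[k] - mx)
                    ssum += logp[k]
                ll += mx + np.log(ssum)
                for k in range(K):
                    rk = logp[k] / ssum
                    nk[k] += rk
                    sx[k] += rk * xi
                    sxx[k] += rk * xi * xi
            for k in range(K):
                if nk[k] < 1e-300:
                    nk[k] = 1e-300
                w[k] = nk[k] / n
                mu[k] = sx[k] / nk[k]
                v = sxx[k] / nk[k] - mu[k] * mu[k]
                if v < var_floor:
                    v = var_floor
                sd[k] = np.sqrt(v)
            if it > 0 and ll - ll_old < tol:
                conv[r] = True
                it_done = it + 1
                ll_old = ll
                break
            ll_old = ll
        ll_out[r] = ll_old
        iters[r] = it_done
    return W, M, S, ll_out, conv, iters


def _quantile_init(x: np.ndarray, K: int, var_floor: float):
    xs = np.sort(x)
    chunks = np.array_split(xs, K)
    means = np.array([c.mean() for c in chunks])
    sds = np.array([max(c.std(), np.sqrt(var_floor)) for c in chunks])
    weights = np.array([c.size for c in chunks], dtype=float) / x.size
    return weights, means, sds


def _random_init(x: np.ndarray, K: int, var_floor: float, rng: np.random.Generator):
    resp = rng.dirichlet(np.ones(K), size=x.size)
    nk = resp.sum(axis=0)
    means = (resp * x[:, None]).sum(axis=0) / nk
    var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
    return nk / x.size, means, np.sqrt(np.maximum(var, var_floor))


def fit_gmm(values, K: int, seed: int = 0, n_restarts: int = 10) -> MixtureModel:
    """Fit a K-component Gaussian mixture by EM, best of ``n_restarts``.

    The first restart is initialised by quantile slicing, the remainder by
    seeded random responsibility draws.  Convergence: log-likelihood change
    < 1e-8 (max 1000 iterations); per-component variance is floored at
    1e-6 times the data variance.  Components are returned sorted by mean.
    """
    x = _clean_values(values)
    n = x.size
    if n < 2 * K:
        raise DegenerateDataError(f"need at least {2 * K} values for K={K}, got {n}")
    if np.unique(x).size < 2:
        raise DegenerateDataError("all values identical")
    var_floor = 1e-6 * np.var(x)
    rng = np.random.default_rng(seed)

    # EM runs on sorted values so the fit is invariant to input order
    # (random restarts would otherwise couple the draw to sample order)
    xs = np.sort(x)
    R = max(1, n_restarts)
    W0 = np.empty((R, K))
    M0 = np.empty((R, K))
    S0 = np.empty((R, K))
    W0[0], M0[0], S0[0] = _quantile_init(xs, K, var_floor)
    for r in range(1, R):
        W0[r], M0[r], S0[r] = _random_init(xs, K, var_floor, rng)
    W, M, S, lls, convs, iters = _em_kernel(xs, W0, M0, S0, var_floor,
                                            1e-8, 1000)
    r_best = int(np.argmax(lls))
    w, m, s = W[r_best], M[r_best], S[r_best]
    conv = bool(convs[r_best])
    n_it = int(iters[r_best])

    order = np.argsort(m)
    w, m, s = w[order], m[order], s[order]
    log_p = _loglik_matrix(x, w, m, s)
    log_norm = logsumexp(log_p, axis=1)
    resp = np.exp(log_p - log_norm[:, None])
    assignments = np.argmax(resp, axis=1)
    ll = float(log_norm.sum())  # likelihood of the returned (final) parameters
    bic = -2.0 * ll + (3 * K - 1) * np.log(n)
    return MixtureModel(K=K, weights=w, means=m, sds=s, log_likelihood=ll,
                        bic=bic, responsibilities=resp, assignments=assignments,
                        n=n, converged=conv, n_iter=n_it)


def select_model(values, K_max: int = 9, seed: int = 0,
                 n_restarts: int = 10) -> MixtureModel:
    """Fit K = 1..min(K_max, n // 4) mixtures and return the minimal-BIC fit.

    Ties break toward smaller K (the simpler model wins at equal evidence).
    """
    x = _clean_values(values)
    if x.size < 4:
        raise DegenerateDataError(f"need at least 4 values, got {x.size}")
    upper = min(K_max, x.size // 4)
    best = None
    for K in range(1, max(1, upper) + 1):
        model = fit_gmm(x, K, seed=seed, n_restarts=n_restarts)
        if best is None or model.bic < best.bic:
            best = model
    return best


def assign_groups(model: MixtureModel, values) -> np.ndarray:
    """MAP component index per value; missing values get ``UNASSIGNED`` (-1).

    Components are mean-ordered, so label 0 is the lowest-expression group.
    Exact responsibility ties break toward the lower-mean component.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, UNASSIGNED, dtype=int)
    obs = ~np.isnan(v)
    if not np.any(obs):
        return out
    log_p = _loglik_matrix(v[obs], model.weights, model.means, model.sds)
    out[obs] = np.argmax(log_p, axis=1)  # argmax takes the first (lower-mean) max
    return out


def mixture_pdf(model: MixtureModel, grid) -> np.ndarray:
    """Mixture density evaluated on a grid (for plot-data export)."""
    g = np.asarray(grid, dtype=float)
    return np.exp(logsumexp(_loglik_matrix(g, model.weights, model.means,
                                           model.sds), axis=1))
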