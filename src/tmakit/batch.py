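"""Empirical-Bayes (ComBat-style) batch-effect reduction for TMA marker grids.

The model treats each score as

    y_sg = alpha_g + X_s beta_g + gamma_bg + delta_bg * eps_sg

with marker g, sample s in batch b, optional covariate design X, additive
batch effect gamma_bg and multiplicative batch effect delta_bg.  Parameters
are shrunk across markers with a normal prior on gamma and an inverse-gamma
prior on delta^2, estimated by method of moments, then refined by iterating
the conditional posterior means.  Sums are taken over observed cells only
(pairwise-complete), which is what makes the procedure applicable to TMA
grids with scattered missingness; :func:`screen_problematic` guarantees the
minimum per-batch counts this requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DegenerateDataError, ValidationError
from .io import MarkerTable

#: reason codes used in removal reports
REASON_INSUFFICIENT = "insufficient_in_batch"
REASON_ZERO_VARIANCE = "zero_variance_in_batch"


@dataclass
class BatchAdjustment:
    """Fitted location/scale batch adjustment.

    ``gamma_star`` (additive, standardized scale) and ``delta_star``
    (multiplicative, SD scale, > 0) are [batches x columns]; ``alpha`` and
    ``sigma`` are the pooled per-column mean and residual SD on the raw
    scale; ``beta`` holds covariate coefficients [covariates x columns].
    """

    batches: list[str]
    columns: list[str]
    gamma_star: np.ndarray
    delta_star: np.ndarray
    alpha: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    covariate_names: list[str]
    n_iterations: int
    removed_columns: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.delta_star <= 0):
            raise ValidationError("delta_star must be positive for all (batch, column)")


def _batch_levels(table: MarkerTable) -> list[str]:
    if table.batch is None:
        raise ValidationError("batch labels are required for batch correction")
    levels = list(dict.fromkeys(table.batch))
    if len(levels) < 2:
        raise ValidationError(
            f"batch correction needs >=2 batches, found {len(levels)}"
        )
    return levels


def screen_problematic(table: MarkerTable) -> tuple[MarkerTable, list[dict]]:
    """Drop marker/replicate columns that cannot support per-batch estimates.

    A column is removed iff, within some batch, it has fewer than 2
    non-missing values or zero variance.  The report lists one entry per
    (column, batch, reason).  Screening is deterministic and independent of
    sample order.
    """
    levels = _batch_levels(table)
    report: list[dict] = []
    keep: list[int] = []
    for j, name in enumerate(table.columns):
        ok = True
        for b in levels:
            mask = (table.batch == b) & ~np.isnan(table.values[:, j])
            obs = table.values[mask, j]
            if obs.size < 2:
                report.append({"column": name, "batch": b,
                               "reason": REASON_INSUFFICIENT})
                ok = False
            elif np.ptp(obs) == 0:
                report.append({"column": name, "batch": b,
                               "reason": REASON_ZERO_VARIANCE})
                ok = False
        if ok:
            keep.append(j)
    if not keep:
        raise DegenerateDataError("no markers survive screening")

    new_cols = [table.columns[j] for j in keep]
    replicate_map: dict[str, list[int]] = {}
    for new_j, name in enumerate(new_cols):
        replicate_map.setdefault(name, []).append(new_j)
    filtered = MarkerTable(
        sample_ids=list(table.sample_ids),
        columns=new_cols,
        values=table.values[:, keep],
        replicate_map=replicate_map,
        batch=table.batch.copy(),
        covariates=None if table.covariates is None else table.covariates.copy(),
        score_kind={k: v for k, v in table.score_kind.items() if k in replicate_map},
        corrected=table.corrected,
    )
    return filtered, report


def _design_matrices(table: MarkerTable, levels: list[str],
                     covariates: pd.DataFrame | None):
    n = table.n_samples
    B = np.zeros((n, len(levels)))
    for k, b in enumerate(levels):
        B[:, k] = table.batch == b
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        C = np.zeros((n, 0))
        cov_names = []
    return B, C, cov_names


def _check_design(B: np.ndarray, C: np.ndarray, cov_names: list[str]) -> None:
    Z = np.hstack([B, C])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # find the first covariate that is collinear with batch + earlier covs
        for k in range(C.shape[1]):
            sub = np.hstack([B, C[:, : k + 1]])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise ValidationError(
                    f"covariate {cov_names[k]!r} is collinear with the batch design"
                )
        raise ValidationError("singular batch design")


def fit_combat(table: MarkerTable, covariates: pd.DataFrame | None = None,
               tol: float = 1e-6, max_iter: int = 500) -> BatchAdjustment:
    """Fit the empirical-Bayes location/scale adjustment on a screened table.

    Per column: OLS on (batch indicators + covariates) over observed cells,
    pooled standardization, then moment-matched priors across columns and
    iterated conditional posterior means gamma*, delta*.
    """
    levels = _batch_levels(table)
    if covariates is None:
        covariates = table.covariates
    if covariates is not None:
        covariates = covariates.loc[table.sample_ids] if set(
            covariates.index) >= set(table.sample_ids) else covariates
    B, C, cov_names = _design_matrices(table, levels, covariates)
    _check_design(B, C, cov_names)
    for k, b in enumerate(levels):
        if B[:, k].sum() < 2:
            raise ValidationError(f"batch {b!r} has fewer than 2 samples")

    n_col = len(table.columns)
    n_b = len(levels)
    Z = np.hstack([B, C])
    gamma_hat = np.zeros((n_b, n_col))
    delta2_hat = np.zeros((n_b, n_col))
    n_obs = np.zeros((n_b, n_col))
    alpha = np.zeros(n_col)
    sigma = np.zeros(n_col)
    beta = np.zeros((C.shape[1], n_col))
    z_scores = np.full(table.values.shape, np.nan)

    for j in range(n_col):
        y = table.values[:, j]
        obs = ~np.isnan(y)
        theta, *_ = np.linalg.lstsq(Z[obs], y[obs], rcond=None)
        batch_coef = theta[:n_b]
        beta[:, j] = theta[n_b:]
        counts = B[obs].sum(axis=0)
        alpha[j] = np.dot(counts, batch_coef) / counts.sum()
        resid = y[obs] - Z[obs] @ theta
        sigma2 = np.mean(resid ** 2)
        if sigma2 <= 0:
            raise DegenerateDataError(
                f"column {table.columns[j]!r} has zero residual variance"
            )
        sigma[j] = np.sqrt(sigma2)
        z = (y - alpha[j] - C @ beta[:, j]) / sigma[j]
        z_scores[:, j] = z
        for k, b in enumerate(levels):
            mask = obs & (table.batch == b)
            zb = z[mask]
            n_obs[k, j] = zb.size
            gamma_hat[k, j] = zb.mean()
            delta2_hat[k, j] = zb.var(ddof=1)

    # method-of-moments hyperpriors per batch, across columns
    gamma_bar = gamma_hat.mean(axis=1)
    tau2_bar = gamma_hat.var(axis=1, ddof=1) if n_col > 1 else np.zeros(n_b)
    m_d = delta2_hat.mean(axis=1)
    v_d = delta2_hat.var(axis=1, ddof=1) if n_col > 1 else np.zeros(n_b)

    shrink = (n_col > 1) & (tau2_bar > 0) & (v_d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(v_d > 0, (2 * v_d + m_d ** 2) / v_d, np.inf)
        theta_p = np.where(v_d > 0, (m_d * v_d + m_d ** 3) / v_d, np.inf)

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter = 0
    for k in range(n_b):
        if not shrink[k]:
            continue  # no cross-column information: keep per-batch estimates
        mask_b = table.batch == levels[k]
        zb = z_scores[mask_b]  # [n_k x n_col], NaN where missing
        g = gamma_hat[k].copy()
        d2 = delta2_hat[k].copy()
        for it in range(max_iter):
            g_new = (n_obs[k] * tau2_bar[k] * gamma_hat[k] + d2 * gamma_bar[k]) \
                / (n_obs[k] * tau2_bar[k] + d2)
            sq = np.nansum((zb - g_new) ** 2, axis=0)
            d2_new = (theta_p[k] + 0.5 * sq) / (n_obs[k] / 2 + lam[k] - 1)
            change = max(np.max(np.abs(g_new - g)), np.max(np.abs(d2_new - d2)))
            g, d2 = g_new, d2_new
            if change < tol:
                break
        else:
            raise ConvergenceError(
                f"posterior iteration for batch {levels[k]!r} did not converge "
                f"in {max_iter} iterations"
            )
        n_iter = max(n_iter, it + 1)
        gamma_star[k] = g
        delta2_star[k] = d2

    return BatchAdjustment(
        batches=levels,
        columns=list(table.columns),
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta2_star),
        alpha=alpha,
        sigma=sigma,
        beta=beta,
        covariate_names=cov_names,
        n_iterations=n_iter,
    )


def apply_combat(table: MarkerTable, adj: BatchAdjustment) -> MarkerTable:
    """Apply a fitted adjustment: y* = sigma*(z - gamma*)/delta* + alpha + X beta.

    Missing values stay missing; the output table carries ``corrected=True``.
    """
    levels = _batch_levels(table)
    missing = [c for c in table.columns if c not in adj.columns]
    if missing or len(table.columns) != len(adj.columns):
        raise ValidationError(
            f"marker columns not covered by the adjustment: {missing or table.columns}"
        )
    col_pos = {c: i for i, c in enumerate(adj.columns)}
    order = [col_pos[c] for c in table.columns]
    if adj.covariate_names:
        if table.covariates is None:
            raise ValidationError("adjustment was fitted with covariates; table has none")
        C = table.covariates[adj.covariate_names].to_numpy(dtype=float)
    else:
        C = np.zeros((table.n_samples, 0))

    out = np.full(table.values.shape, np.nan)
    for jj, j in enumerate(order):
        y = table.values[:, jj]
        z = (y - adj.alpha[j] - C @ adj.beta[:, j]) / adj.sigma[j]
        corrected = np.full_like(y, np.nan)
        for k, b in enumerate(adj.batches):
            mask = table.batch == b
            corrected[mask] = (
                adj.sigma[j] * (z[mask] - adj.gamma_star[k, j]) / adj.delta_star[k, j]
                + adj.alpha[j] + (C[mask] @ adj.beta[:, j])
            )
        unknown = ~np.isin(table.batch, adj.batches)
        if np.any(unknown):
            raise ValidationError(
                f"batches not seen at fit time: {sorted(set(table.batch[unknown]))}"
            )
        out[:, jj] = corrected
    out[np.isnan(table.values)] = np.nan
    return MarkerTable(
        sample_ids=list(table.sample_ids),
        columns=list(table.columns),
        values=out,
        replicate_map={k: list(v) for k, v in table.replicate_map.items()},
        batch=table.batch.copy(),
        covariates=None if table.covariates is None else table.covariates.copy(),
        score_kind=dict(table.score_kind),
        corrected=True,
    )


def correct_batch_effects(table: MarkerTable,
                          covariates: pd.DataFrame | None = None,
                          ) -> tuple[MarkerTable, list[dict]]:
    """Screen, fit and apply in one call; returns (corrected table, removal report)."""
    filtered, report = screen_problematic(table)
    adj = fit_combat(filtered, covariates=covariates)
    return apply_combat(filtered, adj), report
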