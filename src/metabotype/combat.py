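"""Parametric empirical-Bayes batch-effect correction.

Implements the standard location/scale adjustment for batch effects in
high-dimensional assays: per-feature standardization, per-batch additive
(location) and multiplicative (scale) effect estimates, shrinkage of those
estimates toward across-feature priors (normal prior for location,
inverse-gamma for scale, both moment-matched), and back-transformation to
the original scale. Operates on log-scale intensity matrices with features
as rows and samples as columns; missing entries are ignored during
estimation and left missing in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class BatchDesignError(ValueError):
    """Raised when the batch layout cannot support estimation."""


def _aprior(delta_hat: np.ndarray) -> float:
    m = np.mean(delta_hat)
    s2 = np.var(delta_hat, ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = np.mean(delta_hat)
    s2 = np.var(delta_hat, ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_solve(s_data: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
              g_bar: float, t2: float, a: float, b: float,
              conv: float = 1e-4, max_iter: int = 500):
    """Iterate the coupled posterior-mean equations for one batch.

    ``s_data`` is the standardized (feature x batch-sample) block, possibly
    containing NaN.
    """
    n = np.sum(~np.isnan(s_data), axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((s_data - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat(data: pd.DataFrame, batches: pd.Series,
           shrink: bool = True) -> pd.DataFrame:
    """Adjust a features x samples log-intensity table for batch effects.

    Parameters
    ----------
    data : DataFrame, features x samples, log scale, NaN = missing.
    batches : Series mapping sample id -> batch label; must cover every
        column of ``data`` and every batch must contain >= 2 samples.
    shrink : apply the empirical-Bayes shrinkage of the per-batch
        location/scale estimates toward their across-feature priors
        (default). ``shrink=False`` uses the raw per-batch estimates —
        the no-shrinkage limit, under which removal of a pure additive
        batch shift is exact and the adjustment is idempotent.

    Returns
    -------
    DataFrame of the same shape on the original log scale. A single batch
    is returned unchanged (no batch effect is estimable).
    """
    missing = set(data.columns) - set(batches.index)
    if missing:
        raise BatchDesignError(f"samples without batch labels: {sorted(missing)}")
    labels = batches.loc[data.columns]
    batch_names = list(pd.unique(labels))
    if len(batch_names) == 1:
        return data.copy()
    for name in batch_names:
        if (labels == name).sum() < 2:
            raise BatchDesignError(
                f"batch {name!r} has fewer than 2 samples")

    X = data.to_numpy(float)
    obs = ~np.isnan(X)
    groups = [np.flatnonzero((labels == name).to_numpy())
              for name in batch_names]
    n_per = np.array([
        obs[:, idx].sum(axis=1) for idx in groups
    ], dtype=float)  # (n_batches, features)
    if (n_per == 0).any():
        # a feature entirely missing within a batch: estimate from the rest
        n_per = np.maximum(n_per, np.nan)

    with np.errstate(invalid="ignore"):
        batch_means = np.array([np.nanmean(X[:, idx], axis=1)
                                for idx in groups])
    weights = np.nan_to_num(n_per) / np.nansum(n_per, axis=0)
    grand_mean = np.nansum(np.nan_to_num(batch_means) * weights, axis=0)

    # pooled variance of residuals about batch means
    resid = X.copy()
    for bi, idx in enumerate(groups):
        resid[:, idx] = X[:, idx] - batch_means[bi][:, None]
    n_obs = obs.sum(axis=1).astype(float)
    var_pooled = np.nansum(resid ** 2, axis=1) / n_obs
    var_pooled = np.maximum(var_pooled, 1e-18)

    s_data = (X - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    adjusted = s_data.copy()
    for bi, idx in enumerate(groups):
        block = s_data[:, idx]
        with np.errstate(invalid="ignore"):
            g_hat = np.nanmean(block, axis=1)
            d_hat = np.nanvar(block, axis=1, ddof=1)
        g_hat = np.nan_to_num(g_hat)
        d_hat = np.where(np.isfinite(d_hat) & (d_hat > 0), d_hat, 1.0)
        if shrink:
            g_bar, t2 = float(np.mean(g_hat)), float(np.var(g_hat, ddof=1))
            a, b = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star = _it_solve(block, g_hat, d_hat, g_bar, t2, a, b)
        else:
            # population (ddof=0) scale keeps the plain location/scale
            # adjustment exactly idempotent
            with np.errstate(invalid="ignore"):
                d0 = np.nanvar(block, axis=1, ddof=0)
            g_star = g_hat
            d_star = np.where(np.isfinite(d0) & (d0 > 0), d0, 1.0)
        adjusted[:, idx] = (block - g_star[:, None]) / \
            np.sqrt(d_star)[:, None]

    out = adjusted * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    out[~obs] = np.nan
    return pd.DataFrame(out, index=data.index, columns=data.columns)
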