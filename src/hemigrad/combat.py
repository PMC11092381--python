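"""Parametric empirical-Bayes ComBat harmonization.

Removes additive (location) and multiplicative (scale) batch effects —
here, acquisition-site effects on asymmetry features — while preserving
covariate effects (age, sex, mean FD). This is the standard parametric
location/scale model: per-feature linear fits with batch indicators and
covariates, standardization by pooled variance, normal / inverse-gamma
priors on the per-batch location and scale parameters estimated across
features, and iterated EB conditional means until convergence. The
implementation follows the canonical algorithm so that results agree with
the widely used R implementation (``sva::ComBat``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HarmonizationModel:
    """Fitted ComBat parameters (one gamma*/delta* pair per batch/feature)."""

    batches: list
    grand_mean: np.ndarray          # n_features
    beta_covariates: np.ndarray     # n_covariates x n_features (may be empty)
    var_pooled: np.ndarray          # n_features
    gamma_star: np.ndarray          # n_batches x n_features
    delta_star: np.ndarray          # n_batches x n_features (strictly > 0)
    n_iterations: np.ndarray        # per batch

    def __post_init__(self) -> None:
        if (self.delta_star <= 0).any():
            raise ValueError("delta* must be strictly positive")


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    sdat: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """EB conditional-mean iteration for one batch (features in columns)."""
    n = (~np.isnan(sdat)).sum(axis=0)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs((g_new - g_old) / g_old).max(),
            np.abs((d_new - d_old) / d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            return g_new, d_new, it
    raise RuntimeError(
        f"ComBat EB iteration did not converge in {max_iter} iterations "
        f"(last relative change {change:.3g})"
    )


def combat_harmonize(
    features: np.ndarray | pd.DataFrame,
    batch: np.ndarray | list,
    covariates: np.ndarray | pd.DataFrame | None = None,
    conv: float = 1e-4,
    max_iter: int = 1000,
) -> tuple[np.ndarray | pd.DataFrame, HarmonizationModel]:
    """Harmonize a subjects x features matrix across batches.

    Parameters
    ----------
    features
        Subjects x features data (AI features downstream).
    batch
        Per-subject batch (site) labels; every batch needs >= 2 subjects.
    covariates
        Optional subjects x covariates design whose effects are preserved
        (no intercept column; it is added internally via the batch
        indicators).

    Returns
    -------
    (harmonized, model)
        Harmonized data in the input container type, and the fitted
        :class:`HarmonizationModel`.
    """
    as_frame = isinstance(features, pd.DataFrame)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (subjects x features)")
    n, p = X.shape
    batch = np.asarray(batch)
    if batch.shape != (n,):
        raise ValueError("batch must have one label per subject")
    batches = [b for b in pd.unique(batch)]
    counts = {b: int((batch == b).sum()) for b in batches}
    thin = [b for b, c in counts.items() if c < 2]
    if thin:
        raise ValueError(f"batch(es) with a single subject: {thin}")

    B = np.column_stack([(batch == b).astype(float) for b in batches])
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C.reshape(n, -1)
        design = np.hstack([B, C])
    else:
        C = np.empty((n, 0))
        design = B
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("design (batch + covariates) is rank deficient")

    # per-feature OLS with batch indicators and covariates
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    n_batch = len(batches)
    props = np.array([counts[b] / n for b in batches])
    grand_mean = props @ beta[:n_batch]                      # n_features
    fitted = design @ beta
    var_pooled = ((X - fitted) ** 2).mean(axis=0)            # 1/n, as in sva
    if (var_pooled <= 0).any():
        raise ValueError("feature(s) with zero pooled residual variance")

    stand_mean = grand_mean[None, :] + C @ beta[n_batch:]
    sd = np.sqrt(var_pooled)[None, :]
    Z = (X - stand_mean) / sd

    gamma_star = np.empty((n_batch, p))
    delta_star = np.empty((n_batch, p))
    iters = np.empty(n_batch, dtype=int)
    if n_batch == 1:
        # nothing to remove: single batch passes through unchanged
        gamma_star[0] = 0.0
        delta_star[0] = 1.0
        iters[0] = 0
        out = X.copy()
    else:
        gamma_hat = np.stack([Z[batch == b].mean(axis=0) for b in batches])
        delta_hat = np.stack([Z[batch == b].var(axis=0, ddof=1) for b in batches])
        for i, b in enumerate(batches):
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var(ddof=1)
            a = _aprior(delta_hat[i])
            bb = _bprior(delta_hat[i])
            g, d, it = _it_sol(
                Z[batch == b], gamma_hat[i], delta_hat[i], g_bar, t2, a, bb,
                conv=conv, max_iter=max_iter,
            )
            gamma_star[i], delta_star[i], iters[i] = g, d, it
        out = Z.copy()
        for i, b in enumerate(batches):
            sel = batch == b
            out[sel] = (Z[sel] - gamma_star[i]) / np.sqrt(delta_star[i])
        out = out * sd + stand_mean

    model = HarmonizationModel(
        batches=batches,
        grand_mean=grand_mean,
        beta_covariates=beta[n_batch:],
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta_star=delta_star,
        n_iterations=iters,
    )
    if as_frame:
        out = pd.DataFrame(out, index=features.index, columns=features.columns)
    return out, model
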