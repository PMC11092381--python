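"""Group comparison statistics for asymmetry features.

The MDD-vs-HC comparison is a multivariate general linear model per unit
(region pair or network): the dependent variable is the AI triplet along
G1-G3, the design holds an intercept, the group indicator and the
covariates (age, sex, mean FD). The group effect is tested jointly with
Hotelling's T² via its exact F transform, FDR-corrected across units;
per-gradient post-hoc t-tests use the same design at the
Bonferroni-style threshold p < 0.05/3. Demographic sex tables are
compared with Pearson's chi-square (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

POSTHOC_ALPHA = 0.05 / 3


@dataclass(frozen=True)
class MultivariateTestResult:
    """Hotelling's T² for the group effect at one unit."""

    unit: object
    t2: float
    f_stat: float
    df1: int
    df2: int
    p: float
    q: float = np.nan

    def __post_init__(self) -> None:
        if self.t2 < 0:
            raise ValueError("T² must be nonnegative")


@dataclass(frozen=True)
class PosthocResult:
    """Per-gradient univariate GLM t-test for the group effect."""

    unit: object
    gradient: int
    t: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < POSTHOC_ALPHA


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = scipy.stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def _design(group, covariates, n: int) -> np.ndarray:
    g = np.asarray(group)
    if g.shape != (n,):
        raise ValueError("group must have one label per subject")
    if g.dtype.kind in "UOS":
        gnum = (g == "MDD").astype(float)
        if set(np.unique(g)) - {"MDD", "HC"}:
            raise ValueError("group labels must be 'MDD' or 'HC'")
    else:
        gnum = g.astype(float)
    parts = [np.ones((n, 1)), gnum[:, None]]
    if covariates is not None:
        parts.append(np.asarray(covariates, dtype=float).reshape(n, -1))
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    return X


def hotelling_group_test(
    Y: np.ndarray, group, covariates=None, unit: object = 0
) -> MultivariateTestResult:
    """Hotelling's T² for the group effect on a multivariate response.

    Fits ``Y = X B + E`` with ``X = [1, group, covariates]`` and tests the
    group coefficient row jointly across the ``p`` response columns:
    ``T² = b^T [(c^T (X^T X)^-1 c) S]^-1 b`` with ``S = E^T E / (n - r)``,
    referred to ``F(p, n - r - p + 1)`` through the exact transform.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    X = _design(group, covariates, n)
    r = X.shape[1]
    if n <= r + p:
        raise ValueError("too few subjects for the multivariate GLM")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    E = Y - X @ B
    S = (E.T @ E) / (n - r)
    b = B[1]  # group coefficient row
    cvar = XtX_inv[1, 1]
    try:
        t2 = float(b @ np.linalg.solve(cvar * S, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular residual covariance; more subjects (or fewer "
            "response columns) are needed"
        ) from exc
    df1, df2 = p, n - r - p + 1
    f_stat = t2 * df2 / (p * (n - r))
    pval = float(scipy.stats.f.sf(f_stat, df1, df2))
    return MultivariateTestResult(
        unit=unit, t2=t2, f_stat=f_stat, df1=df1, df2=df2, p=pval
    )


def posthoc_gradient_tests(
    Y: np.ndarray, group, covariates=None, unit: object = 0
) -> list[PosthocResult]:
    """Univariate GLM t-test for the group effect, one per response column."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    X = _design(group, covariates, n)
    r = X.shape[1]
    if n <= r:
        raise ValueError("too few subjects for the GLM")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    E = Y - X @ B
    dof = n - r
    sigma2 = (E**2).sum(axis=0) / dof
    if np.any(sigma2 <= 0):
        raise ValueError("zero residual variance: degenerate response")
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = B[1] / se
    pvals = 2 * scipy.stats.t.sf(np.abs(t), dof)
    return [
        PosthocResult(unit=unit, gradient=k + 1, t=float(t[k]), p=float(pvals[k]))
        for k in range(p)
    ]


def unitwise_group_comparison(
    ai_stack: np.ndarray, group, covariates=None, unit_ids=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hotelling + post-hoc tests across units with FDR across units.

    Parameters
    ----------
    ai_stack
        subjects x units x gradients array (units are region pairs or
        networks).
    group, covariates
        Shared design across units.

    Returns
    -------
    (multivariate, posthoc)
        Two tidy frames; the multivariate frame carries BH q-values
        across units.
    """
    stack = np.asarray(ai_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("ai_stack must be subjects x units x gradients")
    n_units = stack.shape[1]
    if unit_ids is None:
        unit_ids = list(range(n_units))
    mv_rows, ph_rows = [], []
    for u in range(n_units):
        res = hotelling_group_test(stack[:, u, :], group, covariates, unit=unit_ids[u])
        mv_rows.append(
            {
                "unit": unit_ids[u],
                "T2": res.t2,
                "F": res.f_stat,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
            }
        )
        for ph in posthoc_gradient_tests(stack[:, u, :], group, covariates, unit=unit_ids[u]):
            ph_rows.append(
                {
                    "unit": unit_ids[u],
                    "gradient": f"G{ph.gradient}",
                    "t": ph.t,
                    "p": ph.p,
                    "significant": ph.significant,
                }
            )
    mv = pd.DataFrame(mv_rows)
    mv["q"] = fdr_bh(mv["p"].to_numpy())
    mv["significant"] = mv["q"] < 0.05
    return mv, pd.DataFrame(ph_rows)


def network_aggregate(
    ai_stack: np.ndarray, pair_networks: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Average pair-level AI into network-level features per subject.

    Returns a subjects x networks x gradients array (unweighted mean over
    member pairs) and the network order.
    """
    stack = np.asarray(ai_stack, dtype=float)
    nets = np.asarray(pair_networks)
    if nets.shape[0] != stack.shape[1]:
        raise ValueError("one network label per pair required")
    order: list[str] = []
    for lab in nets:
        if lab not in order:
            order.append(lab)
    out = np.empty((stack.shape[0], len(order), stack.shape[2]))
    for j, lab in enumerate(order):
        members = nets == lab
        if not members.any():
            raise ValueError(f"network {lab!r} has no member pairs")
        out[:, j, :] = stack[:, members, :].mean(axis=1)
    return out, order
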