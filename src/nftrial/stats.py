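"""Permutation-based trial inference.

The trial's confirmatory machinery: one-way permutation ANOVA for
baseline balance, covariate-adjusted permutation ANCOVA on change scores
with the Freedman-Lane residual-permutation scheme, eta-squared effect
sizes, Benjamini-Hochberg FDR across outcome families, Bonferroni
post-hoc pairwise contrasts, permutation multiple regression of NIRS
activation change on cognitive change, and median pooling over multiply
imputed data sets.

Permutation p values use the add-one convention
p = (1 + #{permuted statistic >= observed}) / (1 + B), so they live on
the grid {k/(B+1)} and are never exactly zero.  Unlike sequential-
stopping permutation packages, a fixed number of permutations B is drawn
for exact seed-reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermAncovaResult",
    "PermRegressionResult",
    "change_scores",
    "perm_anova_baseline",
    "perm_ancova",
    "posthoc_pairwise",
    "perm_regression",
    "pool_over_imputations",
    "fdr_adjust",
]


@dataclass
class PermAncovaResult:
    outcome: str
    F: float
    df1: int
    df2: int
    eta_sq: float
    p_perm: float
    p_adj: float | None = None
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass
class PermRegressionResult:
    hemisphere: str
    outcome: str
    beta_std: float
    t: float
    p_perm: float
    meta: dict = field(default_factory=dict)


def change_scores(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Elementwise post-minus-pre scores for matching ids and outcomes."""
    if not pre.index.equals(post.index):
        raise ValueError("pre and post tables must share the same ids")
    if set(pre.columns) != set(post.columns):
        raise ValueError("pre and post tables must share the same outcomes")
    return post[pre.columns] - pre


def _perm_pvalue(observed: float, permuted: np.ndarray) -> float:
    return (1.0 + int(np.sum(permuted >= observed - 1e-12))) \
        / (1.0 + len(permuted))


def _design(group: np.ndarray | None,
            covariates: pd.DataFrame | np.ndarray | None,
            n: int) -> tuple[np.ndarray, list[str], list[str]]:
    """Full-model design matrix: intercept | group dummies | covariates."""
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    group_cols: list[str] = []
    if group is not None:
        levels = sorted(set(group))
        for lvl in levels[1:]:
            cols.append((group == lvl).astype(float))
            names.append(f"group[{lvl}]")
            group_cols.append(f"group[{lvl}]")
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for name in cov.columns:
            col = np.asarray(cov[name], dtype=float)
            cols.append(col)
            names.append(str(name))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1])
                   if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"rank-deficient design: aliased columns {aliased}")
    return X, names, group_cols


def _rss(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y after projecting on Q."""
    return np.einsum("ij,ij->j", Y, Y) - np.einsum(
        "ij,ij->j", Q.T @ Y, Q.T @ Y)


def perm_anova_baseline(values: np.ndarray, groups: np.ndarray,
                        n_perm: int = 5000, seed: int = 0
                        ) -> tuple[float, float]:
    """One-way permutation ANOVA (free label permutation).

    Used for baseline-balance checks.  Returns (F, p_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for lvl in levels:
        if np.sum(groups == lvl) < 2:
            raise ValueError(f"group {lvl!r} has fewer than 2 values")

    def f_stat(y: np.ndarray) -> float:
        grand = y.mean()
        ss_b = sum(np.sum(groups == lvl) * (y[groups == lvl].mean() - grand) ** 2
                   for lvl in levels)
        ss_w = sum(np.sum((y[groups == lvl] - y[groups == lvl].mean()) ** 2)
                   for lvl in levels)
        df1, df2 = len(levels) - 1, len(y) - len(levels)
        if ss_w == 0:
            return 0.0 if ss_b == 0 else np.inf
        return (ss_b / df1) / (ss_w / df2)

    observed = f_stat(values)
    rng = np.random.default_rng(seed)
    permuted = np.array([f_stat(rng.permutation(values))
                         for _ in range(n_perm)])
    return observed, _perm_pvalue(observed, permuted)


def perm_ancova(change: np.ndarray, group: np.ndarray,
                covariates: pd.DataFrame | np.ndarray,
                n_perm: int = 5000, seed: int = 0,
                outcome: str = "") -> PermAncovaResult:
    """Covariate-adjusted permutation test of the group factor.

    F compares the full linear model (change ~ group + covariates)
    against the covariates-only model.  The null distribution follows
    the Freedman-Lane scheme: residuals of the reduced model are
    permuted, added back to the reduced fit, and the full-vs-reduced F
    recomputed.  eta_sq is SS_group / SS_total.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(change, dtype=float)
    group = np.asarray(group)
    n = len(y)
    if np.isnan(y).any():
        raise ValueError("change scores contain missing values; impute first")
    X_full, _, group_cols = _design(group, covariates, n)
    X_red, _, _ = _design(None, covariates, n)
    df1 = len(group_cols)
    df2 = n - X_full.shape[1]
    if df1 < 1:
        raise ValueError("need at least 2 groups")
    if df2 < 1:
        raise ValueError("not enough observations for the full model")

    Q_full, _ = np.linalg.qr(X_full)
    Q_red, _ = np.linalg.qr(X_red)
    rss_full = float(_rss(Q_full, y[:, None])[0])
    rss_red = float(_rss(Q_red, y[:, None])[0])
    ss_group = rss_red - rss_full
    ss_total = float(np.sum((y - y.mean()) ** 2))
    F = (ss_group / df1) / (rss_full / df2) if rss_full > 0 else np.inf
    eta_sq = ss_group / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    yhat_red = Q_red @ (Q_red.T @ y)            # reduced-model fit
    resid_red = y - yhat_red
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Y_star = yhat_red[:, None] + resid_red[idx].T      # n x B
    rss_full_b = _rss(Q_full, Y_star)
    rss_red_b = _rss(Q_red, Y_star)
    with np.errstate(divide="ignore", invalid="ignore"):
        F_b = ((rss_red_b - rss_full_b) / df1) / (rss_full_b / df2)
    F_b = np.nan_to_num(F_b, nan=np.inf, posinf=np.inf)
    return PermAncovaResult(outcome=outcome, F=float(F), df1=df1, df2=df2,
                            eta_sq=float(np.clip(eta_sq, 0.0, 1.0)),
                            p_perm=_perm_pvalue(F, F_b),
                            meta={"n_perm": n_perm, "scheme": "freedman-lane"})


def posthoc_pairwise(change: np.ndarray, group: np.ndarray,
                     covariates: pd.DataFrame, n_perm: int = 5000,
                     seed: int = 0) -> dict[tuple[str, str], float]:
    """Pairwise permutation ANCOVAs with Bonferroni adjustment.

    Each arm pair is tested with the same covariate-adjusted scheme
    restricted to the two arms; raw p values are multiplied by the
    number of pairs and capped at 1.
    """
    group = np.asarray(group)
    change = np.asarray(change, dtype=float)
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    levels = sorted(set(group))
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    out: dict[tuple[str, str], float] = {}
    for k, (a, b) in enumerate(pairs):
        mask = np.isin(group, (a, b))
        if np.sum(group == a) < 2 or np.sum(group == b) < 2:
            raise ValueError(f"arm pair ({a}, {b}) has fewer than 2 "
                             "observations in an arm")
        res = perm_ancova(change[mask], group[mask],
                          covariates.loc[mask].reset_index(drop=True),
                          n_perm=n_perm, seed=seed + k,
                          outcome=f"{a} vs {b}")
        out[(a, b)] = min(1.0, res.p_perm * len(pairs))
    return out


def perm_regression(nirs_change: np.ndarray, cog_change: np.ndarray,
                    covariates: pd.DataFrame | np.ndarray | None = None,
                    n_perm: int = 5000, seed: int = 0,
                    hemisphere: str = "", outcome: str = ""
                    ) -> PermRegressionResult:
    """Permutation multiple regression of NIRS change on cognitive change.

    All variables are standardized to zero mean / unit variance, the
    model nirs ~ cog + covariates is fit by OLS, and the focal
    coefficient is reported as a standardized beta with its t statistic.
    The two-sided permutation p follows Freedman-Lane on the focal
    predictor: residuals of the covariates-only model for the outcome
    are permuted and |t| recomputed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(nirs_change, dtype=float)
    x = np.asarray(cog_change, dtype=float)
    n = len(y)

    def standardize(v: np.ndarray, name: str) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd < 1e-12:
            raise ValueError(f"zero-variance predictor {name!r}")
        return (v - v.mean()) / sd

    y = standardize(y, "nirs_change")
    x = standardize(x, "cog_change")
    cov_mat = None
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cov_mat = np.column_stack(
            [standardize(np.asarray(cov[c], dtype=float), str(c))
             for c in cov.columns])

    X_parts = [np.ones(n), x]
    if cov_mat is not None:
        X_parts.append(cov_mat)
    X = np.column_stack(X_parts) if cov_mat is not None \
        else np.column_stack(X_parts[:2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient regression design")
    df_resid = n - X.shape[1]
    if df_resid < 1:
        raise ValueError("not enough observations")

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T

    def t_and_beta(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Focal t and beta for each column of Y."""
        beta = H @ Y
        resid = Y - X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df_resid
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[1] / se, np.inf)
        return t, beta[1]

    (t_obs,), (beta_std,) = t_and_beta(y[:, None])

    # reduced model: covariates only (intercept if no covariates)
    X_red = np.column_stack([np.ones(n)] + ([cov_mat] if cov_mat is not None
                                            else []))
    Q_red, _ = np.linalg.qr(X_red)
    yhat_red = Q_red @ (Q_red.T @ y)
    resid_red = y - yhat_red
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    t_perm, _ = t_and_beta(yhat_red[:, None] + resid_red[idx].T)
    p = _perm_pvalue(abs(t_obs), np.abs(t_perm))
    return PermRegressionResult(hemisphere=hemisphere, outcome=outcome,
                                beta_std=float(beta_std), t=float(t_obs),
                                p_perm=p, meta={"n_perm": n_perm,
                                                "scheme": "freedman-lane"})


def pool_over_imputations(results: Sequence[PermAncovaResult]
                          ) -> PermAncovaResult:
    """Median-pool permutation results across imputed data sets.

    The pooled F, eta-squared and permutation p are the medians of the
    per-imputation values; the pooling rule is recorded in the result
    metadata.  (Rubin's rules do not apply to permutation p values.)
    """
    if not results:
        raise ValueError("no results to pool")
    if len(results) == 1:
        res = results[0]
        res.meta = dict(res.meta, pooling="median", m=1)
        return res
    pooled = PermAncovaResult(
        outcome=results[0].outcome,
        F=float(np.median([r.F for r in results])),
        df1=results[0].df1, df2=results[0].df2,
        eta_sq=float(np.median([r.eta_sq for r in results])),
        p_perm=float(np.median([r.p_perm for r in results])),
        meta=dict(results[0].meta, pooling="median", m=len(results)))
    return pooled


def fdr_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values, order preserved."""
    pvals = list(pvals)
    if any(not 0.0 < p <= 1.0 for p in pvals):
        raise ValueError("p values must lie in (0, 1]")
    if not pvals:
        return []
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(p) for p in adjusted]
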