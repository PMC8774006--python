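"""Predictive-mean-matching multiple imputation by chained equations.

Each missing post-intervention score is filled with an *observed* value
of the same column, borrowed from one of the k donors whose model-
predicted means are closest to the missing row's prediction.  Columns
are visited cyclically for a fixed number of iterations; the procedure
is repeated m times with independent seeds to yield m completed tables
for intention-to-treat analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ImputationConfig

__all__ = ["pmm_impute"]


def _predictor_matrix(df: pd.DataFrame, exclude: str,
                      columns: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in columns:
        if c != exclude:
            cols.append(df[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def pmm_impute(table: pd.DataFrame, cfg: ImputationConfig | None = None,
               predictors: list[str] | None = None) -> list[pd.DataFrame]:
    """Return ``cfg.m`` completed copies of ``table``.

    Parameters
    ----------
    table
        Cohort table; missing values may appear only in ``*_post`` score
        columns.  Predictors default to all cognitive pre/post columns
        plus age and sex.
    cfg
        m, donor count and chained-equation iterations.

    Every imputed cell is drawn from the observed support of its column
    (the defining property of predictive mean matching), and the whole
    procedure is deterministic given ``cfg.seed``.
    """
    cfg = cfg or ImputationConfig()
    work_cols = [c for c in table.columns
                 if c.endswith("_pre") or c.endswith("_post")]
    if predictors is None:
        predictors = list(work_cols)
        if "age" in table.columns:
            predictors.append("age")
        if "sex" in table.columns:
            predictors.append("sex")

    incomplete = [c for c in table.columns if table[c].isna().any()]
    bad = [c for c in incomplete if not c.endswith("_post")]
    if bad:
        raise ValueError(f"missing values outside post-score columns: {bad}")
    for c in incomplete:
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
    if not incomplete:
        return [table.copy() for _ in range(cfg.m)]

    base = table.copy()
    if "sex" in predictors:
        base = base.assign(sex=(base["sex"] == "F").astype(float)
                           if base["sex"].dtype == object else base["sex"])
    numeric_predictors = [p for p in predictors]

    ss = np.random.SeedSequence([cfg.seed, 0x9A])
    completed: list[pd.DataFrame] = []
    for child in ss.spawn(cfg.m):
        rng = np.random.default_rng(child)
        work = base.copy()
        # initialize each missing cell with a random observed value
        for c in incomplete:
            obs = work[c].dropna().to_numpy(dtype=float)
            miss = work[c].isna()
            work.loc[miss, c] = rng.choice(obs, size=int(miss.sum()))
        for _ in range(cfg.iterations):
            for c in incomplete:
                miss = table[c].isna().to_numpy()
                X = _predictor_matrix(work, c, numeric_predictors)
                y_obs = table.loc[~miss, c].to_numpy(dtype=float)
                beta, *_ = np.linalg.lstsq(X[~miss], y_obs, rcond=None)
                pred_obs = X[~miss] @ beta
                pred_mis = X[miss] @ beta
                filled = np.empty(int(miss.sum()))
                for i, pm in enumerate(pred_mis):
                    dist = np.abs(pred_obs - pm)
                    k = min(cfg.donors, len(dist))
                    donors = np.argpartition(dist, k - 1)[:k]
                    filled[i] = y_obs[donors[rng.integers(k)]]
                work.loc[miss, c] = filled
        result = table.copy()
        for c in incomplete:
            result[c] = work[c].to_numpy(dtype=float)
        completed.append(result)
    return completed
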