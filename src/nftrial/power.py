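"""A-priori sample size for the covariate-adjusted three-arm comparison.

Power of the group F test is computed from the noncentral F distribution
with numerator df = arms - 1, denominator df = N - arms - covariates and
noncentrality lambda = f^2 * N, where Cohen's f is derived from the
expected pairwise standardized difference d (f = d/2 by default, the
two-extreme-groups convention).
"""

from __future__ import annotations

from scipy import stats as sps

from .config import PowerConfig

__all__ = ["ancova_power", "power_sample_size"]


def cohens_f(cfg: PowerConfig) -> float:
    if cfg.d_to_f == "half":
        return cfg.d / 2.0
    raise ValueError(f"unknown d_to_f rule {cfg.d_to_f!r}")


def ancova_power(n_total: int, cfg: PowerConfig) -> float:
    """Power of the group F test at total sample size ``n_total``."""
    df1 = cfg.arms - 1
    df2 = n_total - cfg.arms - cfg.covariates
    if df2 < 1:
        return 0.0
    f = cohens_f(cfg)
    lam = f * f * n_total
    crit = sps.f.isf(cfg.alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def power_sample_size(cfg: PowerConfig, n_max: int = 100000
                      ) -> dict[str, float]:
    """Smallest total N reaching the target power.

    Returns the minimal N, the same rounded up to a multiple of the
    number of arms (equal allocation), and the achieved power at each.
    """
    n_min = cfg.arms + cfg.covariates + 2   # minimum identifiable model
    for n in range(n_min, n_max + 1):
        p = ancova_power(n, cfg)
        if p >= cfg.power:
            n_balanced = n if n % cfg.arms == 0 \
                else n + cfg.arms - n % cfg.arms
            return {"n_total": n, "power": p,
                    "n_balanced": n_balanced,
                    "power_balanced": ancova_power(n_balanced, cfg)}
    raise ValueError(f"target power {cfg.power} unattainable below "
                     f"N = {n_max}")
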