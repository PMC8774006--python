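"""Synthetic cohort generation for the three-arm neurofeedback trial.

Covers the participant-level inputs of the analysis: sex-stratified
permuted-block randomization, baseline cognitive scores drawn from
truncated normals at the published per-arm means, four-week change
scores with a latent brain-behavior coupling in the CT-NF arm, and
missing-completely-at-random post-score dropout.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import params
from .config import EffectSpec, TrialConfig

__all__ = [
    "assign_groups",
    "generate_cohort",
    "simulate_change_scores",
    "inject_missingness",
    "simulate_covariate_null",
]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Sample Normal(mean, sd) restricted to [lo, hi] by resampling.

    Resampling (rather than clipping) avoids point masses at the bounds,
    so the draws follow the exact truncated-normal law.
    """
    if sd < 0:
        raise ValueError(f"negative SD {sd}")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate distribution outside bounds")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _blocked_sequence(n: int, arms: Sequence[str], block_size: int,
                      rng: np.random.Generator) -> list[str]:
    """Permuted-block arm sequence of length n.

    When block_size is a multiple of the number of arms each block is a
    balanced permutation.  Otherwise (e.g. blocks of 4 with 3 arms) each
    block is drawn from an urn topped up with whole permuted arm sets, so
    exact 1:1:1 balance is restored every lcm(block_size, n_arms)
    allocations while every released block still has the configured size.
    """
    arms = list(arms)
    seq: list[str] = []
    if block_size % len(arms) == 0:
        reps = block_size // len(arms)
        while len(seq) < n:
            block = arms * reps
            rng.shuffle(block)
            seq.extend(block)
    else:
        urn: list[str] = []
        while len(seq) < n:
            while len(urn) < block_size:
                refill = list(arms)
                rng.shuffle(refill)
                urn.extend(refill)
            block = urn[:block_size]
            del urn[:block_size]
            rng.shuffle(block)
            seq.extend(block)
    return seq[:n]


def assign_groups(ids: Sequence[str], sexes: Sequence[str],
                  cfg: TrialConfig) -> dict[str, str]:
    """Sex-stratified permuted-block randomization at 1:1:1.

    Returns a mapping id -> arm.  Within each sex stratum, arms are
    assigned in permuted blocks of ``cfg.block_size``; with the default
    block of 3 and stratum sizes divisible by 3 the final allocation is
    exactly balanced.  Deterministic given ``cfg.seed``.
    """
    if len(ids) != len(sexes):
        raise ValueError("ids and sexes must have equal length")
    bad = sorted({s for s in sexes if s not in ("M", "F")})
    if bad:
        raise ValueError(f"unknown sex codes: {bad}; expected M/F")
    if cfg.exact_allocation and len(ids) % len(cfg.arms):
        raise ValueError(
            f"{len(ids)} participants not divisible by {len(cfg.arms)} arms "
            f"(remainder {len(ids) % len(cfg.arms)}) with exact allocation")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5A]))
    assignment: dict[str, str] = {}
    for stratum in ("M", "F"):
        members = [i for i, s in zip(ids, sexes) if s == stratum]
        seq = _blocked_sequence(len(members), cfg.arms, cfg.block_size, rng)
        assignment.update(zip(members, seq))
    return assignment


def generate_cohort(cfg: TrialConfig,
                    baselines: Mapping[str, Mapping[str, tuple[float, float]]]
                    | None = None) -> pd.DataFrame:
    """Generate the randomized cohort with baseline scores and adherence.

    Parameters
    ----------
    cfg
        Trial design; ``cfg.seed`` drives all randomness.
    baselines
        Per-arm {measure: (mean, sd)} baseline parameters; defaults to the
        published per-arm table.  Scores are truncated normals at the
        instrument bounds (digit span forward <= 9, backward <= 8, ...).

    Returns a DataFrame with one row per participant: id, age, sex, group,
    ``<measure>_pre`` columns and training_days.
    """
    baselines = baselines if baselines is not None else params.BASELINE_PARAMS
    n = cfg.n_total
    ids = [f"P{i + 1:03d}" for i in range(n)]
    sexes = ["M" if i < n // 2 else "F" for i in range(n)]
    groups = assign_groups(ids, sexes, cfg)
    arm = np.array([groups[i] for i in ids])

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0]))
    table = pd.DataFrame({"id": ids, "sex": sexes, "group": arm})

    lo_age, hi_age = cfg.age_range
    if cfg.age_mode == "uniform":
        table["age"] = rng.integers(lo_age, hi_age + 1, size=n)
    elif cfg.age_mode == "normal":
        age = np.empty(n)
        for a in cfg.arms:
            mask = arm == a
            mean, sd = params.AGE_PARAMS[a]
            age[mask] = np.round(_truncated_normal(
                rng, mean, sd, lo_age, hi_age, int(mask.sum())))
        table["age"] = age.astype(int)
    else:
        raise ValueError(f"unknown age_mode {cfg.age_mode!r}")

    for measure in params.BASELINE_MEASURES:
        lo, hi = params.SCORE_BOUNDS[measure]
        col = np.empty(n)
        for a in cfg.arms:
            mask = arm == a
            mean, sd = baselines[a][measure]
            col[mask] = _truncated_normal(rng, mean, sd, lo, hi,
                                          int(mask.sum()))
        table[f"{measure}_pre"] = col

    days = np.empty(n, dtype=int)
    for a in cfg.arms:
        mask = arm == a
        mean, sd = cfg.adherence[a]
        draw = np.round(_truncated_normal(rng, mean, sd, 6, cfg.days,
                                          int(mask.sum())))
        days[mask] = draw.astype(int)
    table["training_days"] = days
    return table[["id", "age", "sex", "group"]
                 + [f"{m}_pre" for m in params.BASELINE_MEASURES]
                 + ["training_days"]]


def simulate_change_scores(cohort: pd.DataFrame, eff: EffectSpec,
                           seed: int, truncate_post: bool = False
                           ) -> pd.DataFrame:
    """Add post scores and NIRS activation changes to a cohort table.

    Each participant's change score for outcome ``o`` is drawn from the
    arm's Normal(mean, sd); ``post = pre + change``.  In the CT-NF arm
    the coupled outcomes and both hemisphere NIRS changes load
    sqrt(coupling) on a shared standard-normal factor, inducing a
    NIRS-cognition correlation equal to ``eff.coupling`` while keeping
    every marginal exactly Normal(mean, sd).

    With ``truncate_post=True`` the change draw is resampled until the
    post score respects the instrument bounds; this biases the realized
    change means away from the configured ones near instrument ceilings
    (digit span backward especially), so it is off by default.
    """
    known = set(eff.change)
    unknown = sorted(set(cohort["group"]) - known)
    if unknown:
        raise ValueError(f"unknown arm label(s) {unknown}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCE]))
    out = cohort.copy()
    n = len(out)
    arm = out["group"].to_numpy()
    is_nf = arm == "CT-NF"
    latent = rng.standard_normal(n)          # shared brain-behavior factor
    load = math.sqrt(eff.coupling)
    resid = math.sqrt(1.0 - eff.coupling)

    outcomes = list(next(iter(eff.change.values())))
    for outcome in outcomes:
        eps = rng.standard_normal(n)
        z = eps.copy()
        if outcome in eff.coupled_outcomes:
            z[is_nf] = load * latent[is_nf] + resid * eps[is_nf]
        mean = np.array([eff.change[a][outcome][0] for a in arm])
        sd = np.array([eff.change[a][outcome][1] for a in arm])
        change = mean + sd * z
        pre = out[f"{outcome}_pre"].to_numpy()
        if truncate_post:
            lo, hi = params.SCORE_BOUNDS.get(outcome, (-math.inf, math.inf))
            post = pre + change
            bad = (post < lo) | (post > hi)
            while bad.any():
                k = int(bad.sum())
                redraw = mean[bad] + sd[bad] * rng.standard_normal(k)
                post[bad] = pre[bad] + redraw
                bad = (post < lo) | (post > hi)
        else:
            post = pre + change
        out[f"{outcome}_post"] = post

    for hemi in params.HEMISPHERES:
        eps = rng.standard_normal(n)
        z = eps.copy()
        z[is_nf] = load * latent[is_nf] + resid * eps[is_nf]
        mean = np.array([eff.nirs[a][hemi][0] for a in arm])
        sd = np.array([eff.nirs[a][hemi][1] for a in arm])
        out[f"nirs_{hemi}_change"] = mean + sd * z
    return out


def inject_missingness(cohort: pd.DataFrame, rate: float,
                       mechanism: str = "MCAR", seed: int = 0
                       ) -> pd.DataFrame:
    """Mask post-score cells missing-completely-at-random.

    Each ``<outcome>_post`` cell is independently set to NaN with
    probability ``rate``; baseline columns are never masked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missingness rate must be in [0, 1), got {rate}")
    if mechanism != "MCAR":
        raise ValueError(f"unsupported missingness mechanism {mechanism!r}")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x31]))
    post_cols = [c for c in out.columns if c.endswith("_post")]
    mask = rng.random((len(out), len(post_cols))) < rate
    for j, col in enumerate(post_cols):
        out.loc[mask[:, j], col] = np.nan
    return out


def simulate_covariate_null(n: int, seed: int,
                            arms: Sequence[str] = params.ARMS
                            ) -> pd.DataFrame:
    """Null trial with real covariate effects but no group effect.

    Used for type-I-error calibration of the permutation ANCOVA: the
    change score depends on the baseline score, age and sex identically
    in every arm, and arms are balanced.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x17]))
    group = np.array([arms[i % len(arms)] for i in range(n)])
    rng.shuffle(group)
    pre = rng.normal(15.7, 3.0, n)
    age = rng.integers(20, 31, n).astype(float)
    sex = rng.integers(0, 2, n).astype(float)
    change = (0.4 * (pre - pre.mean()) + 0.15 * (age - age.mean())
              + 0.8 * sex + rng.normal(0.0, 2.8, n))
    return pd.DataFrame({"group": group, "pre": pre, "age": age,
                         "sex": sex, "change": change})
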