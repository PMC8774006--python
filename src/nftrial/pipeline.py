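"""End-to-end trial orchestration.

``run_trial`` composes the stages into one reproducible run: simulate
the cohort and every training session, score the neurofeedback, run the
offline NIRS chain, impute, test, and render the change-score report.
All randomness descends from the single top-level seed; every stage
writes its output to disk so stages are independently inspectable.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, params
from .cohort import generate_cohort, inject_missingness, simulate_change_scores
from .config import AnalysisConfig, RunConfig, dump_config
from .imputation import pmm_impute
from .neurofeedback import run_feedback_session
from .preprocess import compute_change, session_activation
from .signals import simulate_participant_sessions
from .stats import (fdr_adjust, perm_ancova, perm_anova_baseline,
                    perm_regression, pool_over_imputations, posthoc_pairwise)

__all__ = ["run_trial", "analyze", "make_report", "simulate_all_sessions"]


def simulate_all_sessions(cohort: pd.DataFrame, cfg: RunConfig, seed: int,
                          out_dir: Path | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, NF-score and preprocess every participant's sessions.

    The CT-NF participant's session gain is tied to their drawn left-
    DLPFC activation change (gain = drawn change / arm mean change), so
    the session-level recordings physically realize the cohort-level
    brain-behavior coupling.  Returns (activations, nf_scores) tables.
    """
    target_mean = cfg.effects.nirs["CT-NF"]["left"][0]
    act_rows, nf_rows = [], []
    for _, row in cohort.iterrows():
        gain = None
        if (row["group"] == "CT-NF" and "nirs_left_change" in row.index
                and abs(target_mean) > 1e-12):
            gain = max(0.05, float(row["nirs_left_change"]) / target_mean)
        recordings = simulate_participant_sessions(
            row["id"], row["group"], int(row["training_days"]),
            cfg.trial, cfg.design, cfg.model, seed, gain=gain)
        for rec in recordings:
            if out_dir is not None:
                io.write_recording(rec, out_dir / f"{rec.participant}"
                                   f"_day{rec.day:02d}.csv")
            act = session_activation(rec, cfg.preprocess)
            act_rows.append({"id": rec.participant, "day": rec.day,
                             "left": act["left"], "right": act["right"]})
            _, score = run_feedback_session(rec, row["group"], cfg.nf)
            nf_rows.append({"id": rec.participant, "day": rec.day,
                            "score": score.score})
    return pd.DataFrame(act_rows), pd.DataFrame(nf_rows)


def channel_changes(activations: pd.DataFrame) -> pd.DataFrame:
    """Per-participant last-3-minus-first-3-days change per hemisphere."""
    rows = []
    for pid, grp in activations.groupby("id", sort=True):
        row = {"id": pid}
        for hemi in ("left", "right"):
            cc = compute_change(dict(zip(grp["day"], grp[hemi])), pid, hemi)
            row[f"{hemi}_pre"] = cc.pre_signal
            row[f"{hemi}_post"] = cc.post_signal
            row[f"{hemi}_change"] = cc.change
        rows.append(row)
    return pd.DataFrame(rows)


def _covariates(table: pd.DataFrame, pre_col: str) -> pd.DataFrame:
    return pd.DataFrame({
        "pre": table[pre_col].to_numpy(dtype=float),
        "age": table["age"].to_numpy(dtype=float)
        - table["age"].to_numpy(dtype=float).mean(),
        "sex": (table["sex"] == "F").astype(float).to_numpy(),
    })


def analyze(cohort: pd.DataFrame, changes: pd.DataFrame | None,
            cfg: AnalysisConfig, seed: int) -> dict:
    """Full inferential pipeline on a scored (possibly incomplete) cohort.

    Per cognitive outcome: PMM multiple imputation, covariate-adjusted
    permutation ANCOVA per imputed table, median pooling, BH-FDR across
    the eight cognitive outcomes, Bonferroni post-hoc pairwise contrasts.
    NIRS activation changes (if provided) form their own two-outcome FDR
    family, and the CT-NF brain-behavior permutation regressions are run
    per hemisphere and outcome.
    """
    results: dict = {"baseline": {}, "cognitive": {}, "nirs": {},
                     "regression": {}}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA7]))
    groups = cohort["group"].to_numpy()

    for measure in params.BASELINE_MEASURES:
        F, p = perm_anova_baseline(cohort[f"{measure}_pre"].to_numpy(),
                                   groups, n_perm=min(cfg.n_perm, 2000),
                                   seed=int(rng.integers(2**31)))
        results["baseline"][measure] = {"F": F, "p": p}

    icfg = dataclasses.replace(cfg.imputation,
                               seed=int(rng.integers(2**31)))
    imputed = pmm_impute(cohort, icfg)

    pooled = {}
    for outcome in params.COGNITIVE_OUTCOMES:
        per_imp, per_imp_posthoc = [], []
        for k, table in enumerate(imputed):
            change = (table[f"{outcome}_post"]
                      - table[f"{outcome}_pre"]).to_numpy()
            cov = _covariates(table, f"{outcome}_pre")
            per_imp.append(perm_ancova(change, groups, cov,
                                       n_perm=cfg.n_perm,
                                       seed=seed * 1000 + k,
                                       outcome=outcome))
            per_imp_posthoc.append(posthoc_pairwise(
                change, groups, cov, n_perm=cfg.n_perm,
                seed=seed * 1000 + 500 + k))
        res = pool_over_imputations(per_imp)
        pairs = {pair: float(np.median([ph[pair] for ph in per_imp_posthoc]))
                 for pair in per_imp_posthoc[0]}
        arm_stats = {}
        complete = imputed[0]
        for arm in sorted(set(groups)):
            deltas = np.column_stack(
                [(t.loc[t["group"] == arm, f"{outcome}_post"]
                  - t.loc[t["group"] == arm, f"{outcome}_pre"]).to_numpy()
                 for t in imputed]).mean(axis=1)
            arm_stats[arm] = {"mean": float(deltas.mean()),
                              "sd": float(deltas.std(ddof=1))}
        pooled[outcome] = (res, pairs, arm_stats)
        del complete

    p_adj = fdr_adjust([pooled[o][0].p_perm
                        for o in params.COGNITIVE_OUTCOMES])
    for adj, outcome in zip(p_adj, params.COGNITIVE_OUTCOMES):
        res, pairs, arm_stats = pooled[outcome]
        results["cognitive"][outcome] = {
            "arms": arm_stats, "F": res.F, "df1": res.df1, "df2": res.df2,
            "eta_sq": res.eta_sq, "p": res.p_perm, "p_adj": adj,
            "posthoc": {f"{a} vs {b}": p for (a, b), p in pairs.items()},
            "meta": res.meta,
        }

    if changes is not None:
        merged = cohort.merge(changes, on="id")
        nirs_res = {}
        for hemi_idx, hemi in enumerate(("left", "right")):
            cov = pd.DataFrame({
                "pre": merged[f"{hemi}_pre"].to_numpy(dtype=float),
                "age": merged["age"].to_numpy(dtype=float)
                - merged["age"].mean(),
                "sex": (merged["sex"] == "F").astype(float).to_numpy(),
            })
            res = perm_ancova(merged[f"{hemi}_change"].to_numpy(),
                              merged["group"].to_numpy(), cov,
                              n_perm=cfg.n_perm, seed=seed * 77 + hemi_idx,
                              outcome=hemi)
            pairs = posthoc_pairwise(merged[f"{hemi}_change"].to_numpy(),
                                     merged["group"].to_numpy(), cov,
                                     n_perm=cfg.n_perm, seed=seed * 79)
            arm_stats = {
                arm: {"mean": float(merged.loc[merged["group"] == arm,
                                               f"{hemi}_change"].mean()),
                      "sd": float(merged.loc[merged["group"] == arm,
                                             f"{hemi}_change"].std(ddof=1))}
                for arm in sorted(set(groups))}
            nirs_res[hemi] = (res, pairs, arm_stats)
        adj = fdr_adjust([nirs_res[h][0].p_perm for h in ("left", "right")])
        for a, hemi in zip(adj, ("left", "right")):
            res, pairs, arm_stats = nirs_res[hemi]
            results["nirs"][hemi] = {
                "arms": arm_stats, "F": res.F, "df1": res.df1,
                "df2": res.df2, "eta_sq": res.eta_sq, "p": res.p_perm,
                "p_adj": a,
                "posthoc": {f"{x} vs {y}": p for (x, y), p in pairs.items()},
            }

        ctnf = merged[merged["group"] == "CT-NF"].reset_index(drop=True)
        table = imputed[0].merge(changes, on="id")
        ctnf_imp = table[table["group"] == "CT-NF"].reset_index(drop=True)
        for hemi in ("left", "right"):
            results["regression"][hemi] = {}
            for outcome in params.COGNITIVE_OUTCOMES:
                cog = (ctnf_imp[f"{outcome}_post"]
                       - ctnf_imp[f"{outcome}_pre"]).to_numpy()
                cov = _covariates(ctnf_imp, f"{outcome}_pre")
                try:
                    reg = perm_regression(
                        ctnf_imp[f"{hemi}_change"].to_numpy(), cog, cov,
                        n_perm=cfg.n_perm, seed=seed * 31 + 1,
                        hemisphere=hemi, outcome=outcome)
                except ValueError:
                    continue
                results["regression"][hemi][outcome] = {
                    "beta_std": reg.beta_std, "t": reg.t, "p": reg.p_perm}
        del ctnf
    return results


def run_trial(cfg: RunConfig, out_dir: str | Path, seed: int) -> dict:
    """Execute simulate -> nf-score -> preprocess -> analyze -> report.

    Writes cohort.csv, activations.csv, nf_scores.csv, changes.csv,
    results.json, report.md and manifest.json under ``out_dir`` and
    returns the results dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial_cfg = dataclasses.replace(cfg.trial, seed=seed)

    cohort = generate_cohort(trial_cfg)
    scored = simulate_change_scores(cohort, cfg.effects, seed=seed + 1)
    observed = inject_missingness(scored, trial_cfg.missing_rate,
                                  seed=seed + 2)
    io.write_cohort(observed, out / "cohort.csv")

    session_dir = None
    if cfg.save_sessions:
        session_dir = out / "sessions"
        session_dir.mkdir(exist_ok=True)
    activations, nf_scores = simulate_all_sessions(scored, cfg, seed + 3,
                                                   session_dir)
    activations.to_csv(out / "activations.csv", index=False)
    nf_scores.to_csv(out / "nf_scores.csv", index=False)
    changes = channel_changes(activations)
    changes.to_csv(out / "changes.csv", index=False)

    results = analyze(observed, changes, cfg.analysis, seed + 4)
    io.write_json(results, out / "results.json")
    report = make_report(out)
    (out / "report.md").write_text(report)

    config_text = dump_config(cfg)
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "timestamp": datetime.datetime.now(datetime.timezone.utc)
        .isoformat(),
    }
    io.write_json(manifest, out / "manifest.json")
    return results


_REPORT_COLUMNS = ("CT-NF", "CT", "ACT")


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def make_report(results_dir: str | Path) -> str:
    """Render the change-score report as a markdown table.

    Layout mirrors the published change-score table: per-arm mean (SD),
    effect size, raw and FDR-adjusted p, pairwise Bonferroni-adjusted p.
    """
    results_dir = Path(results_dir)
    path = results_dir / "results.json"
    if not path.exists():
        raise FileNotFoundError(f"missing results file {path}")
    results = io.read_json(path)
    if not results.get("cognitive"):
        raise ValueError("results contain no cognitive outcomes")

    pairs = ("CT vs CT-NF", "ACT vs CT-NF", "ACT vs CT")
    lines = ["# Trial change-score report", "",
             "| Outcome | " + " | ".join(_REPORT_COLUMNS)
             + " | eta^2 | p | adj. p | "
             + " | ".join(p.replace(" vs ", "/") for p in pairs) + " |",
             "|" + "---|" * (len(_REPORT_COLUMNS) + len(pairs) + 4)]

    def row(name: str, entry: dict) -> str:
        cells = [name]
        for arm in _REPORT_COLUMNS:
            stats = entry["arms"][arm]
            cells.append(f"{_fmt(stats['mean'])} ({_fmt(stats['sd'])})")
        cells += [_fmt(entry["eta_sq"]), _fmt(entry["p"], 3),
                  _fmt(entry["p_adj"], 3)]
        for pair in pairs:
            cells.append(_fmt(entry["posthoc"].get(pair, float("nan")), 3))
        return "| " + " | ".join(cells) + " |"

    for outcome, entry in results["cognitive"].items():
        lines.append(row(outcome, entry))
    if results.get("nirs"):
        lines += ["", "## NIRS activation change", "",
                  lines[2], lines[3]]
        for hemi, entry in results["nirs"].items():
            lines.append(row(f"{hemi} DLPFC", entry))
    if results.get("regression"):
        lines += ["", "## CT-NF brain-behavior regression", "",
                  "| Hemisphere | Outcome | std. beta | t | p |",
                  "|---|---|---|---|---|"]
        for hemi, entries in results["regression"].items():
            for outcome, reg in entries.items():
                lines.append(f"| {hemi} | {outcome} | "
                             f"{_fmt(reg['beta_std'])} | {_fmt(reg['t'])} "
                             f"| {_fmt(reg['p'], 3)} |")
    return "\n".join(lines) + "\n"
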