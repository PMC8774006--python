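"""Configuration objects for every stage of the trial pipeline.

All stages are driven by small frozen-ish dataclasses with validated
invariants; ``load_config``/``dump_config`` round-trip them through YAML
so a whole run is reproducible from one file plus one seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import params


@dataclass
class TrialConfig:
    """Trial design: cohort size, arms, randomization and schedule."""

    n_total: int = 60
    arms: tuple[str, ...] = params.ARMS
    block_size: int = 3          # permuted-block length per sex stratum
    days: int = 28
    adherence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(params.ADHERENCE_PARAMS))
    session_minutes: float = 20.0
    age_range: tuple[int, int] = (20, 30)
    age_mode: str = "uniform"    # "uniform" | "normal" (baseline-table ages)
    missing_rate: float = 0.05
    exact_allocation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 6:
            raise ValueError("days must be >= 6: the activation change "
                             "needs first and last 3 training days")
        if self.exact_allocation and self.n_total % len(self.arms):
            raise ValueError(
                f"n_total={self.n_total} not divisible by {len(self.arms)} "
                f"arms (remainder {self.n_total % len(self.arms)}) with "
                "exact 1:1:1 allocation")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")


@dataclass
class EffectSpec:
    """Per-arm change-score and NIRS-change distributions plus the
    brain-behavior coupling.

    ``coupling`` is the latent-factor correlation between the CT-NF arm's
    NIRS activation change and its coupled cognitive change scores: both
    load sqrt(coupling) on a shared standard-normal factor, so the induced
    NIRS-cognition correlation equals ``coupling`` while every marginal
    stays exactly Normal(mean, sd).
    """

    change: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {a: dict(v) for a, v in params.CHANGE_PARAMS.items()})
    nirs: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {a: dict(v) for a, v in params.NIRS_CHANGE_PARAMS.items()})
    coupling: float = 0.3
    coupled_outcomes: tuple[str, ...] = ("LM-delay", "DS-B", "D-CAT")

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        for arm, outcomes in self.change.items():
            for outcome, (_, sd) in outcomes.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {arm}/{outcome}")
        for arm, hemis in self.nirs.items():
            for hemi, (_, sd) in hemis.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {arm}/{hemi} NIRS")


@dataclass
class SessionDesign:
    """Rest/task block layout of one training session."""

    rest_s: float = 30.0
    task_s: float = 60.0
    n_cycles: int = 13           # 13 x 90 s = 19.5 min
    fs: float = 10.0             # device sampling rate, Hz

    def __post_init__(self) -> None:
        if self.rest_s <= 0 or self.task_s <= 0:
            raise ValueError("rest_s and task_s must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def cycle_s(self) -> float:
        return self.rest_s + self.task_s

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.cycle_s

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class SessionModel:
    """Generative model for one raw 4-channel total-Hb recording.

    The long channels are drift + systemic oscillations + motion spikes +
    an HRF-convolved task boxcar + white noise; the short channels share
    the identical drift/systemic/motion realizations scaled by
    ``short_scale`` plus independent white noise and no neural term.
    Amplitudes are in the device's arbitrary ΔtotalHb units.
    """

    drift_slope_sd: float = 2e-4     # a.u./s, random linear drift
    mayer_freq_range: tuple[float, float] = (0.08, 0.12)  # Hz
    mayer_amp: float = 0.04
    cardiac_freq_range: tuple[float, float] = (1.0, 1.3)  # Hz
    cardiac_amp: float = 0.015
    motion_rate_per_min: float = 0.5
    motion_amp: float = 0.08
    motion_decay_s: float = 0.5
    white_sd: float = 0.02
    short_scale: float = 0.7
    short_white_sd: float = 0.02
    hrf_shape: float = 4.0           # gamma kernel, mode (shape-1)*scale = 6 s
    hrf_scale: float = 2.0
    base_amp: float = params.BASE_AMP
    ctnf_ceiling: Mapping[str, float] = field(default_factory=lambda: {
        "left": params.CTNF_CEILING_LEFT, "right": params.CTNF_CEILING_RIGHT})
    gain_sd: float = params.GAIN_SD


@dataclass
class PreprocessConfig:
    """Offline NIRS preprocessing chain parameters."""

    lowpass_cutoff: float = 0.1      # Hz
    filter_order: int = 4
    detrend_mode: str = "linear"
    regression_mode: str = "per-session OLS"

    def __post_init__(self) -> None:
        if self.lowpass_cutoff <= 0:
            raise ValueError("lowpass_cutoff must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass
class NFConfig:
    """Real-time neurofeedback computation parameters."""

    window_s: float = 5.0
    clamp_lo: float = 0.0
    clamp_hi: float = 0.2
    update_hz: float = 1.0
    score_lo: float = 0.0
    score_hi: float = 100.0

    def __post_init__(self) -> None:
        if not self.clamp_lo < self.clamp_hi:
            raise ValueError("clamp_lo must be below clamp_hi")
        if self.window_s <= 0 or self.update_hz <= 0:
            raise ValueError("window_s and update_hz must be positive")


@dataclass
class ImputationConfig:
    """Predictive-mean-matching multiple imputation settings."""

    m: int = 20
    method: str = "pmm"
    donors: int = 5
    iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.donors < 1:
            raise ValueError("donors must be >= 1")


@dataclass
class PowerConfig:
    """A-priori power computation for the covariate-adjusted group test."""

    d: float = 0.79
    alpha: float = 0.05
    power: float = 0.80
    arms: int = 3
    covariates: int = 3
    d_to_f: str = "half"            # Cohen's f = d / 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.arms < 2:
            raise ValueError("need at least 2 arms")


@dataclass
class AnalysisConfig:
    """Inference settings for the trial analysis stage."""

    n_perm: int = 5000
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Top-level configuration tying all stages together."""

    trial: TrialConfig = field(default_factory=TrialConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)
    design: SessionDesign = field(default_factory=SessionDesign)
    model: SessionModel = field(default_factory=SessionModel)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    nf: NFConfig = field(default_factory=NFConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    save_sessions: bool = False


def _build(cls, data):
    """Recursively construct a dataclass from a plain mapping."""
    if not dataclasses.is_dataclass(cls) or not isinstance(data, Mapping):
        return data
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise KeyError(f"unknown config key {key!r} for {cls.__name__}")
        sub = _FIELD_CLASSES.get((cls.__name__, key))
        kwargs[key] = _build(sub, value) if sub else value
    return cls(**kwargs)


_FIELD_CLASSES = {
    ("RunConfig", "trial"): TrialConfig,
    ("RunConfig", "effects"): EffectSpec,
    ("RunConfig", "design"): SessionDesign,
    ("RunConfig", "model"): SessionModel,
    ("RunConfig", "preprocess"): PreprocessConfig,
    ("RunConfig", "nf"): NFConfig,
    ("RunConfig", "analysis"): AnalysisConfig,
    ("AnalysisConfig", "imputation"): ImputationConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, validating every section."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data)


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a run configuration to canonical YAML."""
    text = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
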