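"""Raw 2-channel (bilateral DLPFC) total-Hb session simulation.

Each simulated session carries four series: a long-separation (cortex +
scalp) and a short-separation (scalp-only) detector per hemisphere.  The
long channels contain a hemodynamic task response whose amplitude ramps
across training days only in the neurofeedback arm; the short channels
share the identical drift/systemic/motion realizations scaled by a
partial-volume factor, which is what the offline dual source-detector
regression exploits.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SessionDesign, SessionModel, TrialConfig

__all__ = [
    "NIRSRecording",
    "make_schedule",
    "neural_amplitude",
    "hemodynamic_kernel",
    "simulate_session",
    "simulate_participant_sessions",
]

CHANNELS = ("left_long", "left_short", "right_long", "right_short")


@dataclass
class NIRSRecording:
    """One session's four total-Hb series plus its block schedule."""

    participant: str
    day: int
    fs: float
    channels: dict[str, np.ndarray]
    schedule: list[tuple[str, float, float]]   # (kind, start_s, end_s)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channel series must have equal length")
        prev_end, prev_kind = 0.0, None
        for kind, start, end in self.schedule:
            if kind not in ("rest", "task"):
                raise ValueError(f"unknown block kind {kind!r}")
            if start != prev_end:
                raise ValueError("schedule blocks must tile the session")
            if kind == prev_kind:
                raise ValueError("schedule must alternate rest/task")
            prev_end, prev_kind = end, kind

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"time_s": self.time})
        for name in CHANNELS:
            frame[name] = self.channels[name]
        return frame


def make_schedule(design: SessionDesign) -> list[tuple[str, float, float]]:
    """Alternating rest/task block schedule covering the session."""
    schedule = []
    t = 0.0
    for _ in range(design.n_cycles):
        schedule.append(("rest", t, t + design.rest_s))
        t += design.rest_s
        schedule.append(("task", t, t + design.task_s))
        t += design.task_s
    return schedule


def neural_amplitude(arm: str, day: int, days: int, model: SessionModel,
                     hemisphere: str, gain: float = 1.0) -> float:
    """Task-response amplitude for a given arm, day and hemisphere.

    CT-NF ramps linearly from ``base_amp`` on day 1 to the hemisphere
    ceiling on the final day (the neurofeedback upregulation effect);
    CT and ACT stay flat at ``base_amp``.
    """
    if not 1 <= day <= days:
        raise ValueError(f"day {day} outside [1, {days}]")
    if arm == "CT-NF":
        ceiling = model.ctnf_ceiling[hemisphere]
        frac = (day - 1) / (days - 1) if days > 1 else 1.0
        return gain * (model.base_amp + (ceiling - model.base_amp) * frac)
    if arm in ("CT", "ACT"):
        return gain * model.base_amp
    raise ValueError(f"unknown arm {arm!r}")


def hemodynamic_kernel(fs: float, shape: float = 4.0, scale: float = 2.0,
                       length_s: float = 30.0) -> np.ndarray:
    """Gamma-family hemodynamic impulse response, unit area.

    Mode at (shape-1)*scale seconds (6 s by default).  Unit discrete area
    makes the convolved boxcar plateau at the configured amplitude.
    """
    t = np.arange(0.0, length_s, 1.0 / fs)
    kernel = sps.gamma.pdf(t, a=shape, scale=scale)
    return kernel / kernel.sum()


def simulate_session(participant: str, arm: str, day: int, days: int,
                     design: SessionDesign, model: SessionModel,
                     seed, gain: float = 1.0) -> NIRSRecording:
    """Simulate one raw four-channel training-session recording.

    Long channel = linear drift + Mayer-wave and cardiac oscillations +
    sparse exponentially-decaying motion spikes + HRF-convolved task
    boxcar (amplitude from :func:`neural_amplitude`) + white noise.
    Short channel = the same drift/systemic/motion realization scaled by
    ``model.short_scale`` + independent white noise, no neural term.
    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if design.fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    n = design.n_samples
    if n == 0:
        raise ValueError("empty session schedule")
    t = np.arange(n) / design.fs
    schedule = make_schedule(design)

    # Systemic/motion/drift realization shared by all four channels.
    drift = rng.normal(0.0, model.drift_slope_sd) * t
    f_mayer = rng.uniform(*model.mayer_freq_range)
    f_card = rng.uniform(*model.cardiac_freq_range)
    systemic = (model.mayer_amp * np.sin(2 * np.pi * f_mayer * t
                                         + rng.uniform(0, 2 * np.pi))
                + model.cardiac_amp * np.sin(2 * np.pi * f_card * t
                                             + rng.uniform(0, 2 * np.pi)))
    motion = np.zeros(n)
    n_events = rng.poisson(model.motion_rate_per_min * design.duration_s / 60)
    if n_events:
        starts = rng.uniform(0.0, design.duration_s, n_events)
        amps = rng.laplace(0.0, model.motion_amp, n_events)
        for t0, a in zip(starts, amps):
            idx = t >= t0
            motion[idx] += a * np.exp(-(t[idx] - t0) / model.motion_decay_s)
    shared = drift + systemic + motion

    box = np.zeros(n)
    for kind, start, end in schedule:
        if kind == "task":
            i0, i1 = int(round(start * design.fs)), int(round(end * design.fs))
            box[i0:i1] = 1.0
    kernel = hemodynamic_kernel(design.fs, model.hrf_shape, model.hrf_scale)
    response = np.convolve(box, kernel)[:n]

    channels: dict[str, np.ndarray] = {}
    for hemi in ("left", "right"):
        amp = neural_amplitude(arm, day, days, model, hemi, gain)
        channels[f"{hemi}_long"] = (shared + amp * response
                                    + rng.normal(0.0, model.white_sd, n))
        channels[f"{hemi}_short"] = (model.short_scale * shared
                                     + rng.normal(0.0, model.short_white_sd, n))
    return NIRSRecording(participant=participant, day=day, fs=design.fs,
                         channels=channels, schedule=schedule)


def simulate_participant_sessions(participant: str, arm: str,
                                  training_days: int, cfg: TrialConfig,
                                  design: SessionDesign, model: SessionModel,
                                  seed: int,
                                  gain: float | None = None
                                  ) -> list[NIRSRecording]:
    """Simulate a participant's full session set.

    The participant trains on a uniformly random subset of
    ``training_days`` of the ``cfg.days`` calendar days and carries one
    multiplicative response gain (Normal(1, gain_sd), resampled positive)
    applied to every session — the between-subject spread behind the
    published activation-change SDs.  An explicit ``gain`` overrides the
    drawn one (used to couple activation to cognitive change).
    """
    if not 1 <= training_days <= cfg.days:
        raise ValueError(f"training_days {training_days} outside "
                         f"[1, {cfg.days}]")
    ss = np.random.SeedSequence([seed, zlib.crc32(participant.encode())])
    rng = np.random.default_rng(ss)
    trained = np.sort(rng.choice(cfg.days, size=training_days,
                                 replace=False)) + 1
    drawn = rng.normal(1.0, model.gain_sd)
    while drawn <= 0.05:
        drawn = rng.normal(1.0, model.gain_sd)
    gain = drawn if gain is None else gain
    children = ss.spawn(training_days)
    return [simulate_session(participant, arm, int(day), cfg.days, design,
                             model, child, gain)
            for day, child in zip(trained, children)]
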