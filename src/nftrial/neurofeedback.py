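"""Real-time neurofeedback computation.

During each 60 s task period the feedback value is the mean total Hb over
the last 5 s minus the mean over the preceding 30 s rest period, clamped
to [0, 0.2].  It is displayed as a background color interpolating blue
(no activation) to red (ceiling), and the session ends with a brain
activation score: the mean feedback value rescaled to 0-100.  The CT
and ACT arms run the identical computation but show a constant color.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NFConfig
from .signals import NIRSRecording

__all__ = [
    "nf_signal",
    "to_color",
    "session_score",
    "run_feedback_session",
    "NFSignalSeries",
    "SessionScore",
]

#: Background color shown to the no-feedback arms.
NO_FEEDBACK_COLOR = (128, 128, 128)


@dataclass
class NFSignalSeries:
    """Clamped feedback values at each update tick of a session."""

    times: np.ndarray                 # seconds from session start
    values: np.ndarray                # clamped to [clamp_lo, clamp_hi]
    colors: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class SessionScore:
    participant: str
    day: int
    score: float                      # 0-100, one decimal


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def nf_signal(task_series: np.ndarray, fs: float, t_rel: float,
              rest_mean: float, cfg: NFConfig | None = None) -> float:
    """Clamped feedback value at time ``t_rel`` within a task block.

    ``task_series`` holds the task-block samples recorded so far; the raw
    value is the mean over the window (t_rel - window_s, t_rel] minus
    ``rest_mean`` (the full preceding-rest average), clamped to
    [clamp_lo, clamp_hi].  During the first 5 s of the block the window
    covers whatever samples are available.
    """
    cfg = cfg or NFConfig()
    task_series = np.asarray(task_series, dtype=float)
    i1 = int(round(t_rel * fs))
    i0 = max(0, i1 - int(round(cfg.window_s * fs)))
    window = task_series[i0:i1]
    if window.size == 0:
        raise ValueError(f"empty feedback window at t={t_rel:.2f} s")
    raw = float(window.mean()) - rest_mean
    return min(max(raw, cfg.clamp_lo), cfg.clamp_hi)


def to_color(nf: float, cfg: NFConfig | None = None) -> tuple[int, int, int]:
    """Map a clamped feedback value to a blue-to-red RGB color.

    Linear interpolation from pure blue (0, 0, 255) at the floor to pure
    red (255, 0, 0) at the ceiling, rounding half up.  Out-of-range input
    is an error: clamping is :func:`nf_signal`'s job.
    """
    cfg = cfg or NFConfig()
    if not cfg.clamp_lo <= nf <= cfg.clamp_hi:
        raise ValueError(f"feedback value {nf} outside "
                         f"[{cfg.clamp_lo}, {cfg.clamp_hi}]")
    frac = (nf - cfg.clamp_lo) / (cfg.clamp_hi - cfg.clamp_lo)
    return (_round_half_up(255 * frac), 0, _round_half_up(255 * (1 - frac)))


def session_score(values: np.ndarray, cfg: NFConfig | None = None,
                  participant: str = "", day: int = 0) -> SessionScore:
    """Brain activation score: mean feedback value rescaled to 0-100."""
    cfg = cfg or NFConfig()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot score an empty feedback series")
    span = cfg.clamp_hi - cfg.clamp_lo
    score = (float(values.mean()) - cfg.clamp_lo) / span
    score = cfg.score_lo + score * (cfg.score_hi - cfg.score_lo)
    return SessionScore(participant=participant, day=day,
                        score=round(score, 1))


def run_feedback_session(recording: NIRSRecording, arm: str,
                         cfg: NFConfig | None = None
                         ) -> tuple[NFSignalSeries, SessionScore]:
    """Run the feedback loop over one session recording.

    The fed-back signal is the mean of the two raw long channels (no
    short-channel correction in real time).  Feedback values are emitted
    at ``update_hz`` through every task block; the CT-NF arm gets the
    blue-to-red color trace while CT and ACT get a constant color, but
    the activation score is computed identically for all arms.
    """
    cfg = cfg or NFConfig()
    if arm not in ("CT-NF", "CT", "ACT"):
        raise ValueError(f"unknown arm {arm!r}")
    signal = 0.5 * (recording.channels["left_long"]
                    + recording.channels["right_long"])
    fs = recording.fs
    times, values, colors = [], [], []
    rest_mean = None
    for kind, start, end in recording.schedule:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        if kind == "rest":
            rest_mean = float(signal[i0:i1].mean())
            continue
        if rest_mean is None:
            raise ValueError("task block without preceding rest")
        task = signal[i0:i1]
        n_ticks = int(np.floor((end - start) * cfg.update_hz))
        for k in range(1, n_ticks + 1):
            t_rel = k / cfg.update_hz
            value = nf_signal(task, fs, t_rel, rest_mean, cfg)
            times.append(start + t_rel)
            values.append(value)
            colors.append(to_color(value, cfg) if arm == "CT-NF"
                          else NO_FEEDBACK_COLOR)
    series = NFSignalSeries(times=np.asarray(times),
                            values=np.asarray(values), colors=colors)
    score = session_score(series.values, cfg,
                          participant=recording.participant,
                          day=recording.day)
    return series, score


def feedback_frame(series: NFSignalSeries) -> pd.DataFrame:
    """Tabular view of a feedback trace (time_s, nf, r, g, b)."""
    r, g, b = (list(c) for c in zip(*series.colors)) if series.colors \
        else ([], [], [])
    return pd.DataFrame({"time_s": series.times, "nf": series.values,
                         "r": r, "g": g, "b": b})
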