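"""Offline NIRS preprocessing: raw recording -> per-hemisphere activation.

The chain is detrend -> zero-phase 0.1 Hz low-pass -> dual source-detector
regression (per-session OLS of the long channel on the short channel,
residual = estimated neural component) -> rest-baseline correction of each
task block -> session mean over task samples.  The participant-level
quantity analysed downstream is the mean activation over the last three
training days minus the first three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sig

from .config import PreprocessConfig
from .signals import NIRSRecording

__all__ = [
    "detrend",
    "lowpass",
    "dual_sd_regress",
    "baseline_correct",
    "session_activation",
    "compute_change",
    "ChannelChange",
]


@dataclass
class ChannelChange:
    """Baseline-to-end activation change for one participant/hemisphere."""

    participant: str
    hemisphere: str
    pre_signal: float     # mean activation over first 3 training days
    post_signal: float    # mean activation over last 3 training days

    @property
    def change(self) -> float:
        return self.post_signal - self.pre_signal


def detrend(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (and mean)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("detrend needs a 1-D series of length >= 2")
    return sig.detrend(series, type="linear")


def lowpass(series: np.ndarray, fs: float,
            cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward filtfilt).

    DC gain is exactly 1; the magnitude response is -3 dB per pass at the
    cutoff (default 0.1 Hz, matching the slow hemodynamic band).
    """
    cfg = cfg or PreprocessConfig()
    series = np.asarray(series, dtype=float)
    if cfg.lowpass_cutoff >= fs / 2:
        raise ValueError(f"cutoff {cfg.lowpass_cutoff} Hz must be below "
                         f"Nyquist {fs / 2} Hz")
    sos = sig.butter(cfg.filter_order, cfg.lowpass_cutoff, btype="low",
                     fs=fs, output="sos")
    return sig.sosfiltfilt(sos, series)


def dual_sd_regress(long: np.ndarray, short: np.ndarray) -> np.ndarray:
    """Regress scalp/systemic signal out of the long channel.

    Per-session OLS of the long (cortex + scalp) channel on the short
    (scalp-only) channel with intercept; the residual is the estimated
    neural component and is uncorrelated with the short channel by
    construction.  A zero-variance short channel leaves nothing to
    regress out: the long channel is returned unchanged with a warning.
    """
    long = np.asarray(long, dtype=float)
    short = np.asarray(short, dtype=float)
    if long.shape != short.shape:
        raise ValueError("long and short series must have equal length")
    sd = short.std()
    if sd < 1e-12:
        warnings.warn("short channel has zero variance; returning long "
                      "channel unchanged", RuntimeWarning, stacklevel=2)
        return long.copy()
    beta = np.cov(long, short, bias=True)[0, 1] / short.var()
    alpha = long.mean() - beta * short.mean()
    return long - (alpha + beta * short)


def _block_indices(schedule: Sequence[tuple[str, float, float]],
                   fs: float) -> list[tuple[str, int, int]]:
    return [(kind, int(round(start * fs)), int(round(end * fs)))
            for kind, start, end in schedule]


def baseline_correct(series: np.ndarray,
                     schedule: Sequence[tuple[str, float, float]],
                     fs: float) -> list[np.ndarray]:
    """Subtract each task block's preceding-rest mean from its samples.

    Returns the list of corrected task-block arrays in schedule order.
    """
    series = np.asarray(series, dtype=float)
    if not schedule:
        raise ValueError("empty schedule")
    if schedule[0][0] == "task":
        raise ValueError("first block is a task block: no preceding rest")
    blocks = _block_indices(schedule, fs)
    corrected = []
    rest_mean = None
    for kind, i0, i1 in blocks:
        if kind == "rest":
            rest_mean = series[i0:i1].mean()
        else:
            if rest_mean is None:
                raise ValueError("task block without preceding rest")
            corrected.append(series[i0:i1] - rest_mean)
    if not corrected:
        raise ValueError("schedule contains no task blocks")
    return corrected


def session_activation(recording: NIRSRecording,
                       cfg: PreprocessConfig | None = None
                       ) -> dict[str, float]:
    """Per-hemisphere mean task activation for one session.

    Both the long and short channel are detrended and low-pass filtered
    over the full session (avoiding per-block filter transients), the
    short channel is regressed out, each task block is corrected by its
    preceding rest mean, and the grand mean over all task samples is
    returned per hemisphere.
    """
    cfg = cfg or PreprocessConfig()
    out = {}
    for hemi in ("left", "right"):
        long = lowpass(detrend(recording.channels[f"{hemi}_long"]),
                       recording.fs, cfg)
        short = lowpass(detrend(recording.channels[f"{hemi}_short"]),
                        recording.fs, cfg)
        neural = dual_sd_regress(long, short)
        blocks = baseline_correct(neural, recording.schedule, recording.fs)
        out[hemi] = float(np.concatenate(blocks).mean())
    return out


def compute_change(activations: Mapping[int, float], participant: str,
                   hemisphere: str) -> ChannelChange:
    """Last-3-days minus first-3-days activation change.

    ``activations`` maps training-day index -> session activation; the
    first/last three *available* days are used (adherence is < 100%).
    """
    days = sorted(activations)
    if len(days) < 6:
        raise ValueError(f"participant {participant}: needs >= 6 valid "
                         f"training days, got {len(days)}")
    pre = float(np.mean([activations[d] for d in days[:3]]))
    post = float(np.mean([activations[d] for d in days[-3:]]))
    return ChannelChange(participant=participant, hemisphere=hemisphere,
                         pre_signal=pre, post_signal=post)
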