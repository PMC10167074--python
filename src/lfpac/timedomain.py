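"""Trial averaging, rectified-RMS z-score maps and slope/latency measures.

These are the classic stimulus-locked analyses: the trial average (ERP),
a per-trial map of relative power (RMS of the rectified signal, z-scored
within each trial), and maximum-derivative measurement of evoked events
such as EPSP rising slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ChannelSignal
from .segmentation import TrialSet

__all__ = ["RmsZscoreMap", "EventMeasures", "trial_average", "rms_zscore", "measure_event"]


@dataclass
class RmsZscoreMap:
    """Per-trial z-scored RMS time course.

    ``z[i, j]`` is the z-score of the sliding-window RMS of the rectified
    trial ``i`` at window ``j``; each row is normalized against its own
    mean and SD, so values are in units of per-trial standard deviations.
    """

    z: np.ndarray
    window_len: float
    hop: float
    t_centers: np.ndarray
    trial_ids: np.ndarray


@dataclass
class EventMeasures:
    """Slope/latency/amplitude measures of one evoked event window."""

    max_slope: float
    slope_time: float
    peak_amplitude: float
    peak_time: float
    window: tuple[float, float]


def trial_average(ts: TrialSet) -> ChannelSignal:
    """Pointwise mean across trials (the event-related potential)."""
    if ts.n_trials < 1:
        raise ValueError("cannot average an empty TrialSet")
    return ChannelSignal(ts.data.mean(axis=0), ts.fs, t0=float(ts.t_axis[0]))


def erp_matrix(ts: TrialSet) -> np.ndarray:
    """Trials x samples matrix for the ERP image display (row per trial)."""
    return ts.data.copy()


def rms_zscore(
    ts: TrialSet,
    window_len: float = 0.050,
    hop: float = 0.010,
    absolute: bool = False,
) -> RmsZscoreMap:
    """Sliding-window RMS of the rectified signal, z-scored per trial.

    Each trial is rectified (absolute value), the RMS is computed in
    windows of ``window_len`` seconds advancing by ``hop`` seconds, and
    the resulting RMS series is z-scored against its own mean and SD —
    the map shows activity relative to that trial's mean level.  A trial
    with constant rectified RMS (zero SD) yields a row of zeros with a
    warning.  ``absolute=True`` additionally returns |z|.
    """
    if hop <= 0:
        raise ValueError(f"hop must be positive, got {hop}")
    n_win = int(round(window_len * ts.fs))
    n_hop = int(round(hop * ts.fs))
    if n_win < 1 or n_hop < 1:
        raise ValueError("window_len and hop must be at least one sample")
    if n_win > ts.n_samples:
        raise ValueError(
            f"window_len {window_len}s exceeds trial duration "
            f"{ts.n_samples / ts.fs}s"
        )

    starts = np.arange(0, ts.n_samples - n_win + 1, n_hop)
    rect = np.abs(ts.data)
    # RMS over each window via cumulative sum of squares
    sq = np.concatenate([np.zeros((ts.n_trials, 1)), np.cumsum(rect**2, axis=1)], axis=1)
    rms = np.sqrt((sq[:, starts + n_win] - sq[:, starts]) / n_win)

    mu = rms.mean(axis=1, keepdims=True)
    sd = rms.std(axis=1, keepdims=True)
    flat = sd[:, 0] < 1e-12
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} trial(s) have constant RMS; their z-scores are 0",
            stacklevel=2,
        )
    sd[flat] = 1.0
    z = (rms - mu) / sd
    z[flat] = 0.0
    if absolute:
        z = np.abs(z)

    t_centers = ts.t_axis[0] + (starts + n_win / 2) / ts.fs
    return RmsZscoreMap(
        z=z, window_len=window_len, hop=hop, t_centers=t_centers, trial_ids=ts.trial_ids
    )


def measure_event(
    sig: ChannelSignal,
    t_start: float,
    t_end: float,
    smooth_len: float = 0.001,
) -> EventMeasures:
    """Maximum slope and peak of an evoked response inside [t_start, t_end].

    The derivative is the first difference scaled by fs, after an optional
    moving-average smoothing of ``smooth_len`` seconds (raw differentiation
    of noisy traces is slope-unstable; pass 0 to disable).  ``max_slope``
    is the largest absolute derivative in the window, signed as observed;
    ties break to the earliest time.  ``peak_amplitude`` is the signal
    extremum of largest magnitude in the window.  Works identically on a
    single trial or a trial average.
    """
    if smooth_len < 0:
        raise ValueError("smooth_len must be >= 0")
    t = sig.times
    if t_start >= t_end:
        raise ValueError(f"t_start ({t_start}) must be < t_end ({t_end})")
    if t_start < t[0] - 0.5 / sig.fs or t_end > t[-1] + 0.5 / sig.fs:
        raise ValueError(
            f"window [{t_start}, {t_end}] outside signal range [{t[0]}, {t[-1]}]"
        )

    x = sig.samples
    n_smooth = int(round(smooth_len * sig.fs))
    if n_smooth > 1:
        kernel = np.ones(n_smooth) / n_smooth
        pad = n_smooth // 2
        xp = np.pad(x, pad, mode="edge")
        x = np.convolve(xp, kernel, mode="same")[pad : pad + sig.n_samples]

    deriv = np.diff(x) * sig.fs
    t_deriv = t[:-1] + 0.5 / sig.fs  # derivative lives between samples

    in_win = (t >= t_start - 1e-12) & (t <= t_end + 1e-12)
    in_win_d = (t_deriv >= t_start - 1e-12) & (t_deriv <= t_end + 1e-12)
    if not in_win.any() or not in_win_d.any():
        raise ValueError("window contains too few samples to measure")

    d_win = deriv[in_win_d]
    i_slope = int(np.argmax(np.abs(d_win)))  # argmax returns first maximum
    max_slope = float(d_win[i_slope])
    slope_time = float(t_deriv[in_win_d][i_slope])

    x_win = sig.samples[in_win]
    i_peak = int(np.argmax(np.abs(x_win)))
    peak_amplitude = float(x_win[i_peak])
    peak_time = float(t[in_win][i_peak])

    return EventMeasures(
        max_slope=max_slope,
        slope_time=slope_time,
        peak_amplitude=peak_amplitude,
        peak_time=peak_time,
        window=(t_start, t_end),
    )
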