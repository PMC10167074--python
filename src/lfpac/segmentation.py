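"""Stimulus detection and peristimulus trial windowing.

Stimulation is detected on a dedicated channel by rising-edge threshold
crossing; trials are then cut time-locked to each stimulus, with t = 0 at
stimulus onset (the pre-stimulus window therefore has negative times).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ChannelSignal

__all__ = ["StimulusTrain", "TrialSet", "detect_stimuli", "segment_trials", "NoStimuliError"]


class NoStimuliError(ValueError):
    """No threshold crossings found on the stimulation channel."""


@dataclass
class StimulusTrain:
    """Detected stimulus onset times.

    ``times`` are in seconds from the start of the recording, strictly
    increasing.  ``isi_nominal`` is the experimenter-declared interstimulus
    interval used for the refractory rule.
    """

    times: np.ndarray
    threshold: float
    isi_nominal: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("stimulus times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.times.size


@dataclass
class TrialSet:
    """Trials x samples matrix time-locked to stimuli (t = 0 at stimulus)."""

    data: np.ndarray
    fs: float
    t_axis: np.ndarray
    trial_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.t_axis = np.asarray(self.t_axis, dtype=float).ravel()
        if self.t_axis.size != self.data.shape[1]:
            raise ValueError("t_axis length does not match trial length")
        if self.trial_ids is None:
            self.trial_ids = np.arange(1, self.data.shape[0] + 1)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int).ravel()
        if len(set(self.trial_ids.tolist())) != self.trial_ids.size:
            raise ValueError("trial_ids must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def trial(self, trial_id: int) -> ChannelSignal:
        """Return one trial (by original 1-based id) as a ChannelSignal."""
        idx = np.flatnonzero(self.trial_ids == trial_id)
        if idx.size == 0:
            raise KeyError(f"trial id {trial_id} not in set {self.trial_ids.tolist()}")
        return ChannelSignal(self.data[idx[0]], self.fs, t0=float(self.t_axis[0]))


def detect_stimuli(
    stim: ChannelSignal,
    threshold: float,
    isi_nominal: float,
    paired_interval: float | None = None,
) -> StimulusTrain:
    """Detect stimulus onsets as rising threshold crossings.

    An onset is the first sample at or above ``threshold`` following a
    sample below it.  Crossings within half the expected inter-event
    interval after an accepted event are suppressed, so ringing on the
    stimulation artifact does not double-count.  For paired-pulse
    protocols, pass the within-pair interval as ``paired_interval``; the
    refractory period then shrinks to half that interval so both pulses
    of a pair are kept.

    Parameters
    ----------
    stim : ChannelSignal
        The stimulation channel (TTL or waveform).
    threshold : float
        Minimal stimulation amplitude, in the channel's units (mV for a
        waveform channel).
    isi_nominal : float
        Declared interstimulus interval in seconds.
    paired_interval : float, optional
        Within-pair interval in seconds for double-pulse protocols.
    """
    if isi_nominal <= 0:
        raise ValueError(f"isi_nominal must be positive, got {isi_nominal}")
    if threshold <= 0:
        warnings.warn(
            f"threshold {threshold} is not positive; detection on a TTL-like "
            "channel may trigger on baseline",
            stacklevel=2,
        )
    x = stim.samples
    above = x >= threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    if onsets.size == 0:
        raise NoStimuliError(
            f"no rising crossings of threshold {threshold} on the stimulation "
            "channel; check threshold against the pulse amplitude"
        )

    min_gap = 0.5 * isi_nominal
    if paired_interval is not None:
        if paired_interval <= 0 or paired_interval >= isi_nominal:
            raise ValueError("paired_interval must lie in (0, isi_nominal)")
        min_gap = 0.5 * paired_interval
    gap_samples = min_gap * stim.fs

    accepted = [onsets[0]]
    for s in onsets[1:]:
        if s - accepted[-1] >= gap_samples:
            accepted.append(s)
    times = stim.t0 + np.asarray(accepted) / stim.fs
    return StimulusTrain(times=times, threshold=threshold, isi_nominal=isi_nominal)


def segment_trials(
    sig: ChannelSignal,
    train: StimulusTrain | None,
    t_initial: float,
    t_final: float,
    selection: str | list[int] = "all",
) -> TrialSet:
    """Cut peristimulus windows [t_initial, t_final] around each stimulus.

    ``t_initial`` may be negative (pre-stimulus baseline).  Trials whose
    window would overrun the recording are dropped with a warning rather
    than zero-padded.  ``selection`` filters by 1-based trial number.

    With ``train=None`` (or an empty train) the whole trace is returned as
    a single trial — the no-stimulation mode for spontaneous recordings.
    """
    if t_initial >= t_final:
        raise ValueError(f"t_initial ({t_initial}) must be < t_final ({t_final})")

    if train is None or train.n_events == 0:
        data = sig.samples[None, :]
        t_axis = sig.t0 + np.arange(sig.n_samples) / sig.fs
        return TrialSet(data=data, fs=sig.fs, t_axis=t_axis, trial_ids=[1])

    n_win = int(round((t_final - t_initial) * sig.fs)) + 1
    t_axis = t_initial + np.arange(n_win) / sig.fs

    rows, ids, dropped = [], [], []
    for i, t_stim in enumerate(train.times, start=1):
        start = int(round((t_stim - sig.t0 + t_initial) * sig.fs))
        stop = start + n_win
        if start < 0 or stop > sig.n_samples:
            dropped.append(i)
            continue
        rows.append(sig.samples[start:stop])
        ids.append(i)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} trial(s) overrunning the recording edges: "
            f"{dropped}",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no trial window fits inside the recording")

    data = np.vstack(rows)
    ids = np.asarray(ids)

    if selection != "all":
        sel = np.asarray(sorted(set(int(s) for s in selection)))
        bad = sorted(set(sel.tolist()) - set(ids.tolist()))
        if bad:
            raise ValueError(
                f"selected trial numbers {bad} out of range; available: {ids.tolist()}"
            )
        keep = np.isin(ids, sel)
        data, ids = data[keep], ids[keep]

    return TrialSet(data=data, fs=sig.fs, t_axis=t_axis, trial_ids=ids)
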