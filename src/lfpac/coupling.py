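"""Phase-amplitude coupling estimators, comodulogram and phase coherence.

Three PAC quantifications are implemented:

``kl_mi``
    Kullback-Leibler modulation index: the amplitude distribution over
    phase bins is compared with the uniform distribution,
    MI = (log N - H) / log N with H its Shannon entropy.  MI is 0 for a
    flat profile and 1 when all amplitude mass sits in one bin.
``mvl``
    Mean vector length |mean(A e^{i phi})| / mean(A), normalized by the
    mean amplitude so the index is dimensionless and scale-free.
``plv``
    Phase-locking value between the modulating phase and the phase of
    the amplitude envelope's fluctuation in the modulating band.

Three PAC procedures consume them: the Hilbert comodulogram over a
(phase frequency x amplitude frequency) grid, a wavelet-power variant
for a single band pair, and a cycle-detection variant that restricts the
estimate to detected cycles of the slow rhythm — useful when the
modulating oscillation is not continuously present.  Two-channel phase
coherence over a time x frequency-window grid completes the set.

All estimators accept either one signal in both roles (local coupling)
or two signals (modulating channel vs modulated channel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import ChannelSignal
from .segmentation import TrialSet
from .spectral import BandFilterSpec, filter_and_decompose, AnalyticDecomposition
from .timefreq import morlet_coefficients

__all__ = [
    "PhaseAmplitudeProfile",
    "Comodulogram",
    "CycleSet",
    "CoherenceMap",
    "phase_amplitude_profile",
    "modulation_index",
    "comodulogram",
    "pac_wavelet_phase_power",
    "detect_cycles",
    "pac_cycle_based",
    "phase_coherence",
    "circular_shift",
    "pac_surrogates",
]

DEFAULT_N_BINS = 18  # 20 degree bins, the convention of the KL-MI literature
_FILTER_ORDER = 3
# the modulated band needs a steeper rolloff: with a gentle filter the cell
# below the carrier passes both a sideband and the carrier's skirt, and the
# resulting beat envelope can out-modulate the true cell
_AMP_FILTER_ORDER = 5


@dataclass
class PhaseAmplitudeProfile:
    """Mean amplitude (or power) per phase bin, plus a modulation index."""

    bin_edges: np.ndarray  # n_bins + 1 edges covering (-pi, pi]
    mean_amplitude: np.ndarray
    normalized: np.ndarray  # sums to 1
    mi: float | None
    method: str  # kl_mi | mvl | plv | wavelet_power | cycle_power
    n_samples: int = 0

    @property
    def n_bins(self) -> int:
        return self.mean_amplitude.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak_phase(self) -> float:
        """Center of the bin with the largest mean amplitude (radians)."""
        return float(self.bin_centers[int(np.argmax(self.mean_amplitude))])


@dataclass
class Comodulogram:
    """MI over a (phase frequency x amplitude frequency) grid.

    ``mi[i, j]`` couples phase frequency ``phase_freqs[j]`` with amplitude
    frequency ``amp_freqs[i]`` (amplitude on rows, phase on columns).
    """

    mi: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    p_step: float
    a_step: float
    method: str

    def argmax_freqs(self) -> tuple[float, float]:
        """(phase frequency, amplitude frequency) of the strongest cell."""
        i, j = np.unravel_index(int(np.argmax(self.mi)), self.mi.shape)
        return float(self.phase_freqs[j]), float(self.amp_freqs[i])


@dataclass
class CycleSet:
    """Trough-to-trough windows of the modulating rhythm."""

    windows: list[tuple[int, int]]  # sample index [start, end) per cycle
    trough_times: np.ndarray
    band: tuple[float, float]

    @property
    def n_cycles(self) -> int:
        return len(self.windows)


@dataclass
class CoherenceMap:
    """Phase coherence per (frequency window x time window) cell, in [0, 1]."""

    pc: np.ndarray
    time_windows: list[tuple[float, float]]
    freq_windows: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# profile + indices


def phase_amplitude_profile(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    method: str = "kl_mi",
) -> PhaseAmplitudeProfile:
    """Bin amplitudes by phase and average within each bin.

    ``phase`` is in radians (wrapped to (-pi, pi]); ``amplitude`` is the
    non-negative envelope or power series of equal length.  The returned
    profile has ``mi`` unset; see :func:`modulation_index`.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.size != amplitude.size:
        raise ValueError(
            f"phase ({phase.size}) and amplitude ({amplitude.size}) lengths differ"
        )
    if n_bins < 4:
        raise ValueError(f"n_bins must be >= 4, got {n_bins}")
    if np.any(amplitude < 0):
        raise ValueError("amplitude series must be non-negative")

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    wrapped = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    idx = np.clip(np.digitize(wrapped, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(
            f"phase bins {empty} received no samples; use a longer signal "
            f"or fewer bins (currently {n_bins})"
        )
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    mean_amp = sums / counts
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("total binned amplitude is zero; profile undefined")
    return PhaseAmplitudeProfile(
        bin_edges=edges,
        mean_amplitude=mean_amp,
        normalized=mean_amp / total,
        mi=None,
        method=method,
        n_samples=phase.size,
    )


def _kl_mi(normalized: np.ndarray) -> float:
    p = np.asarray(normalized, dtype=float)
    n = p.size
    nz = p[p > 0]
    entropy = -np.sum(nz * np.log(nz))
    # clamp the float residual so a uniform profile reads exactly 0
    return max(float((np.log(n) - entropy) / np.log(n)), 0.0)


def modulation_index(
    profile: PhaseAmplitudeProfile | None = None,
    *,
    phase: np.ndarray | None = None,
    amplitude: np.ndarray | None = None,
    method: str = "kl_mi",
    fs: float | None = None,
    phase_band: tuple[float, float] | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Scalar PAC index by one of three methods.

    ``kl_mi`` needs a profile (or builds one from the raw series);
    ``mvl`` and ``plv`` operate on the raw phase and amplitude series.
    ``plv`` additionally needs ``fs`` and ``phase_band`` to extract the
    phase of the amplitude envelope's slow fluctuation.
    """
    if method == "kl_mi":
        if profile is None:
            if phase is None or amplitude is None:
                raise ValueError("kl_mi needs a profile or phase+amplitude series")
            profile = phase_amplitude_profile(phase, amplitude, n_bins)
        return _kl_mi(profile.normalized)

    if phase is None or amplitude is None:
        raise ValueError(f"{method} needs the raw phase and amplitude series")
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.size != amplitude.size:
        raise ValueError("phase and amplitude lengths differ")
    mean_amp = amplitude.mean()
    if mean_amp <= 0:
        raise ValueError("zero total amplitude; modulation index undefined")

    if method == "mvl":
        return float(np.abs(np.mean(amplitude * np.exp(1j * phase))) / mean_amp)

    if method == "plv":
        if fs is None or phase_band is None:
            raise ValueError("plv needs fs and phase_band to phase the envelope")
        spec = BandFilterSpec(phase_band[0], phase_band[1], _FILTER_ORDER, fs)
        env_sig = ChannelSignal(amplitude, fs)
        env_phase = filter_and_decompose(env_sig, spec).phase
        return float(np.abs(np.mean(np.exp(1j * (phase - env_phase)))))

    raise ValueError(f"unknown method {method!r}; use kl_mi, mvl or plv")


# ---------------------------------------------------------------------------
# Hilbert comodulogram


def _amp_band(f_a: float, f_p: float, a_step: float, nyquist: float) -> tuple[float, float]:
    """Amplitude band around f_a wide enough to carry f_p's sidebands."""
    bw = max(a_step, 2.0 * f_p)
    lo = max(f_a - bw / 2.0, 0.1)
    hi = min(f_a + bw / 2.0, nyquist * 0.99)
    return lo, hi


def comodulogram(
    sig_phase: ChannelSignal,
    sig_amp: ChannelSignal | None = None,
    phase_range: tuple[float, float] = (2.0, 14.0),
    amp_range: tuple[float, float] = (30.0, 120.0),
    p_step: float = 1.0,
    a_step: float = 5.0,
    n_bins: int = DEFAULT_N_BINS,
    method: str = "kl_mi",
) -> Comodulogram:
    """MI over every (phase frequency, amplitude frequency) band pair.

    The modulating signal is filtered in narrow bands of width ``p_step``
    centred on each phase frequency; the modulated signal in bands wide
    enough (at least twice the phase frequency) to carry the modulation
    sidebands.  Phase and amplitude come from the Hilbert analytic
    signal.  ``sig_amp=None`` uses ``sig_phase`` in both roles (local,
    single-channel coupling).
    """
    if sig_amp is None:
        sig_amp = sig_phase
    if sig_amp.fs != sig_phase.fs:
        raise ValueError("phase and amplitude signals must share one sampling rate")
    if sig_amp.n_samples != sig_phase.n_samples:
        raise ValueError("phase and amplitude signals must have equal length")
    if amp_range[0] < phase_range[1]:
        warnings.warn(
            "amplitude band overlaps or lies below the phase band; "
            "physiologically inverted but computed as requested",
            stacklevel=2,
        )
    fs = sig_phase.fs
    phase_freqs = np.arange(phase_range[0], phase_range[1] + p_step / 2, p_step)
    amp_freqs = np.arange(amp_range[0], amp_range[1] + a_step / 2, a_step)

    mi = np.empty((amp_freqs.size, phase_freqs.size))
    for j, f_p in enumerate(phase_freqs):
        p_lo = max(f_p - p_step / 2.0, 0.05)
        p_spec = BandFilterSpec(p_lo, f_p + p_step / 2.0, _FILTER_ORDER, fs)
        phase = filter_and_decompose(sig_phase, p_spec).phase
        for i, f_a in enumerate(amp_freqs):
            a_lo, a_hi = _amp_band(f_a, f_p, a_step, fs / 2.0)
            a_spec = BandFilterSpec(a_lo, a_hi, _AMP_FILTER_ORDER, fs)
            amp = filter_and_decompose(sig_amp, a_spec).envelope
            if method == "kl_mi":
                prof = phase_amplitude_profile(phase, amp, n_bins)
                mi[i, j] = _kl_mi(prof.normalized)
            else:
                mi[i, j] = modulation_index(
                    phase=phase, amplitude=amp, method=method,
                    fs=fs, phase_band=(p_spec.f_low, p_spec.f_high),
                )
    return Comodulogram(
        mi=mi, phase_freqs=phase_freqs, amp_freqs=amp_freqs,
        p_step=p_step, a_step=a_step, method=method,
    )


# ---------------------------------------------------------------------------
# wavelet-power PAC (single band pair)


def _amp_freq_grid(amp_range: tuple[float, float]) -> np.ndarray:
    n = max(int(round(amp_range[1] - amp_range[0])) + 1, 2)
    n = min(n, 64)  # cap the grid; band-mean power gains little beyond this
    return np.linspace(amp_range[0], amp_range[1], n)


def _wavelet_pair_profile(
    sig_phase: ChannelSignal,
    sig_amp: ChannelSignal,
    phase_band: tuple[float, float],
    amp_range: tuple[float, float],
    n_bins: int,
    n_cycles: float,
) -> PhaseAmplitudeProfile:
    spec = BandFilterSpec(phase_band[0], phase_band[1], _FILTER_ORDER, sig_phase.fs)
    phase = filter_and_decompose(sig_phase, spec).phase
    coeffs, _ = morlet_coefficients(sig_amp, _amp_freq_grid(amp_range), n_cycles)
    band_power = (np.abs(coeffs) ** 2).mean(axis=0)  # mean over the modulated band
    prof = phase_amplitude_profile(phase, band_power, n_bins, method="wavelet_power")
    return replace(prof, mi=_kl_mi(prof.normalized))


def pac_wavelet_phase_power(
    sig_phase: ChannelSignal | TrialSet,
    sig_amp: ChannelSignal | TrialSet | None = None,
    phase_band: tuple[float, float] = (6.0, 10.0),
    amp_range: tuple[float, float] = (60.0, 100.0),
    n_bins: int = DEFAULT_N_BINS,
    n_cycles: float = 7.0,
) -> PhaseAmplitudeProfile:
    """Mean wavelet power of the modulated band per modulating phase bin.

    Phase comes from the Hilbert transform of the phase-band-filtered
    modulating signal; power from a Morlet transform of the modulated
    signal averaged over ``amp_range``.  The profile's ``mi`` is the KL
    modulation index of the binned power distribution.

    Passing TrialSets computes one profile per trial and averages the
    normalized profiles (``mi`` is then the index of the average).
    """
    if sig_amp is None:
        sig_amp = sig_phase
    if isinstance(sig_phase, TrialSet) != isinstance(sig_amp, TrialSet):
        raise TypeError("phase and amplitude inputs must both be trials or both signals")

    if isinstance(sig_phase, TrialSet):
        if sig_phase.n_trials != sig_amp.n_trials:
            raise ValueError("trial counts differ between phase and amplitude inputs")
        profs = []
        for p_row, a_row in zip(sig_phase.data, sig_amp.data):
            profs.append(
                _wavelet_pair_profile(
                    ChannelSignal(p_row, sig_phase.fs, t0=float(sig_phase.t_axis[0])),
                    ChannelSignal(a_row, sig_amp.fs, t0=float(sig_amp.t_axis[0])),
                    phase_band, amp_range, n_bins, n_cycles,
                )
            )
        mean_amp = np.mean([p.mean_amplitude for p in profs], axis=0)
        normalized = mean_amp / mean_amp.sum()
        return PhaseAmplitudeProfile(
            bin_edges=profs[0].bin_edges,
            mean_amplitude=mean_amp,
            normalized=normalized,
            mi=_kl_mi(normalized),
            method="wavelet_power",
            n_samples=sum(p.n_samples for p in profs),
        )

    return _wavelet_pair_profile(
        sig_phase, sig_amp, phase_band, amp_range, n_bins, n_cycles
    )


# ---------------------------------------------------------------------------
# cycle-detection PAC


def detect_cycles(
    decomp: AnalyticDecomposition,
    band: tuple[float, float] | None = None,
    min_prominence_frac: float = 0.25,
) -> CycleSet:
    """Trough-to-trough cycles of the band-filtered modulating rhythm.

    Troughs are local minima of the filtered trace with prominence at
    least ``min_prominence_frac`` x the 95th percentile of the envelope,
    so stretches where the rhythm is absent produce no troughs even when
    the rhythm is present for only a small fraction of the recording
    (an upper percentile tracks the oscillation's amplitude rather than
    the silence in between).  Consecutive troughs bound a candidate
    cycle; cycles whose duration falls outside the band's period range
    (with 25% tolerance) are rejected, so only well-formed oscillatory
    cycles survive.
    """
    if band is None:
        band = (decomp.spec.f_low, decomp.spec.f_high)
    f_low, f_high = band
    if not 0 < f_low < f_high:
        raise ValueError(f"invalid band {band}")
    fs = decomp.fs
    x = decomp.filtered

    prominence = min_prominence_frac * float(np.percentile(decomp.envelope, 95))
    distance = max(int(0.5 / f_high * fs), 1)
    troughs, _ = sps.find_peaks(-x, distance=distance, prominence=prominence)
    if troughs.size < 2:
        raise ValueError(
            f"found {troughs.size} trough(s); need at least 2 to delimit a cycle — "
            "is the modulating rhythm present in this band?"
        )

    d_min = 0.75 / f_high
    d_max = 1.25 / f_low
    windows, kept_troughs = [], []
    for a, b in zip(troughs[:-1], troughs[1:]):
        duration = (b - a) / fs
        if d_min <= duration <= d_max:
            windows.append((int(a), int(b)))
            kept_troughs.append(a)
    return CycleSet(
        windows=windows,
        trough_times=decomp.t0 + np.asarray(kept_troughs, dtype=float) / fs,
        band=(f_low, f_high),
    )


def pac_cycle_based(
    sig_phase: ChannelSignal,
    sig_amp: ChannelSignal | None = None,
    phase_band: tuple[float, float] = (6.0, 10.0),
    amp_range: tuple[float, float] = (60.0, 100.0),
    n_bins: int = DEFAULT_N_BINS,
    n_cycles: float = 7.0,
    min_cycles: int = 5,
) -> tuple[PhaseAmplitudeProfile, CycleSet]:
    """PAC restricted to detected cycles of the modulating rhythm.

    The modulating signal is filtered in ``phase_band`` and its
    trough-to-trough cycles detected; phase and modulated-band wavelet
    power are then binned using only samples inside accepted cycle
    windows.  Because stretches without the slow rhythm contribute
    nothing, this estimator stays sensitive when the modulating
    oscillation is intermittent.  Single-channel mode: ``sig_amp=None``.
    """
    if sig_amp is None:
        sig_amp = sig_phase
    if sig_amp.fs != sig_phase.fs or sig_amp.n_samples != sig_phase.n_samples:
        raise ValueError("phase and amplitude signals must match in fs and length")

    spec = BandFilterSpec(phase_band[0], phase_band[1], _FILTER_ORDER, sig_phase.fs)
    decomp = filter_and_decompose(sig_phase, spec)
    cycles = detect_cycles(decomp, phase_band)
    if cycles.n_cycles < min_cycles:
        raise ValueError(
            f"only {cycles.n_cycles} accepted cycle(s) in {phase_band} Hz; "
            f"need >= {min_cycles}"
        )

    coeffs, _ = morlet_coefficients(sig_amp, _amp_freq_grid(amp_range), n_cycles)
    band_power = (np.abs(coeffs) ** 2).mean(axis=0)

    mask = np.zeros(sig_phase.n_samples, dtype=bool)
    for a, b in cycles.windows:
        mask[a:b] = True
    prof = phase_amplitude_profile(
        decomp.phase[mask], band_power[mask], n_bins, method="cycle_power"
    )
    return replace(prof, mi=_kl_mi(prof.normalized)), cycles


# ---------------------------------------------------------------------------
# two-channel phase coherence


def phase_coherence(
    sig1: ChannelSignal,
    sig2: ChannelSignal,
    wd_time: float = 1.0,
    f_low: float = 4.0,
    f_high: float = 40.0,
    n_freq_windows: int = 6,
    n_cycles: float = 7.0,
) -> CoherenceMap:
    """Phase coherence between two channels over time x frequency windows.

    Both signals are wavelet-transformed; the recording is split into
    consecutive windows of ``wd_time`` seconds and [f_low, f_high] into
    ``n_freq_windows`` contiguous bands.  Within each (frequency window,
    time window) epoch the instantaneous phase difference d = P1 - P2 is
    pooled over all time samples and wavelet frequencies, and
    pc = |mean(e^{i d})| — 1 for a perfectly consistent phase relation
    (any constant lag), near 0 for independent phases.
    """
    if sig1.fs != sig2.fs:
        raise ValueError("channels must share one sampling rate")
    if sig1.n_samples != sig2.n_samples:
        raise ValueError(
            f"channel lengths differ: {sig1.n_samples} vs {sig2.n_samples}"
        )
    if wd_time < 2.0 / f_low:
        raise ValueError(
            f"wd_time {wd_time}s too short; need >= two periods of f_low "
            f"({2.0 / f_low:.3f}s)"
        )
    n_win = int(sig1.duration / wd_time)
    if n_win < 1:
        raise ValueError("signal shorter than one time window")

    n_freqs = max(3 * n_freq_windows, int(round(f_high - f_low)) + 1)
    freqs = np.linspace(f_low, f_high, n_freqs)
    c1, _ = morlet_coefficients(sig1, freqs, n_cycles)
    c2, _ = morlet_coefficients(sig2, freqs, n_cycles)
    # unit phasors of the phase difference at every (f, t) sample
    phasor = np.exp(1j * (np.angle(c1) - np.angle(c2)))

    band_edges = np.linspace(f_low, f_high, n_freq_windows + 1)
    f_idx = np.clip(np.searchsorted(band_edges, freqs, side="right") - 1, 0, n_freq_windows - 1)
    wlen = int(round(wd_time * sig1.fs))

    pc = np.empty((n_freq_windows, n_win))
    t_windows, f_windows = [], []
    for k in range(n_freq_windows):
        f_windows.append((float(band_edges[k]), float(band_edges[k + 1])))
    for j in range(n_win):
        sl = slice(j * wlen, (j + 1) * wlen)
        t_windows.append((sig1.t0 + j * wd_time, sig1.t0 + (j + 1) * wd_time))
        for k in range(n_freq_windows):
            pc[k, j] = np.abs(np.mean(phasor[f_idx == k, sl]))
    return CoherenceMap(pc=pc, time_windows=t_windows, freq_windows=f_windows)


# ---------------------------------------------------------------------------
# surrogates


def circular_shift(sig: ChannelSignal, shift: float) -> ChannelSignal:
    """Circularly rotate a signal by ``shift`` seconds (surrogate builder)."""
    n = int(round(shift * sig.fs)) % sig.n_samples
    return ChannelSignal(np.roll(sig.samples, n), sig.fs, t0=sig.t0)


def pac_surrogates(
    sig_phase: ChannelSignal,
    sig_amp: ChannelSignal | None = None,
    phase_band: tuple[float, float] = (6.0, 10.0),
    amp_band: tuple[float, float] = (60.0, 100.0),
    n_surrogates: int = 100,
    min_shift: float = 1.0,
    method: str = "kl_mi",
    n_bins: int = DEFAULT_N_BINS,
    seed: int | None = None,
) -> np.ndarray:
    """Null MI distribution from circularly time-shifted amplitude signals.

    Each surrogate rotates the modulated signal by a random lag of at
    least ``min_shift`` seconds before re-estimating the index, which
    destroys phase-amplitude alignment while preserving both spectra.
    Thresholding against this distribution is left to the caller.
    """
    if sig_amp is None:
        sig_amp = sig_phase
    rng = np.random.default_rng(seed)
    fs = sig_phase.fs
    p_spec = BandFilterSpec(phase_band[0], phase_band[1], _FILTER_ORDER, fs)
    a_spec = BandFilterSpec(amp_band[0], amp_band[1], _AMP_FILTER_ORDER, fs)
    phase = filter_and_decompose(sig_phase, p_spec).phase
    amp = filter_and_decompose(sig_amp, a_spec).envelope

    max_shift = sig_amp.duration - min_shift
    if max_shift <= min_shift:
        raise ValueError("signal too short for the requested minimum shift")
    out = np.empty(n_surrogates)
    for s in range(n_surrogates):
        lag = rng.uniform(min_shift, max_shift)
        rolled = np.roll(amp, int(round(lag * fs)))
        out[s] = modulation_index(
            phase=phase, amplitude=rolled, method=method,
            fs=fs, phase_band=phase_band, n_bins=n_bins,
        )
    return out
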