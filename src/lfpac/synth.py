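"""Synthetic signals with known ground truth.

Every analysis in this package is validated against signals generated
here: a slow oscillation whose phase modulates a fast oscillation's
amplitude (with controllable depth, coupling phase, SNR and optional
intermittency), stimulus-pulse recordings with stereotyped evoked
responses, and coherent channel pairs sharing a band-limited source.

All generators are deterministic under a fixed seed, and the parameter
objects double as the ground truth tests assert against.  Noise is
Gaussian white by default; ``snr`` is the ratio RMS(clean)/RMS(noise).
A pink-noise option exists for realism but analytic expectations are
simplest under white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ChannelSignal, Recording

__all__ = [
    "PacSpec",
    "StimTruth",
    "make_pac_signal",
    "make_stim_recording",
    "make_coherent_pair",
    "alpha_epsp",
]


@dataclass(frozen=True)
class PacSpec:
    """Parameters of a phase-amplitude coupled test signal.

    The generated trace is

        x(t) = g(t) * cos(phi(t))
               + [1 + depth * g(t) * cos(phi(t) - coupling_phase)]
                 * sin(2 pi f_a t) + noise

    With the default deterministic modulator, phi(t) = 2 pi f_p t, so the
    Hilbert phase of the slow (cosine) component equals 2 pi f_p t and
    the fast envelope peaks exactly at phase ``coupling_phase`` — the
    profile peak location is known by construction.

    ``modulator="stochastic"`` draws phi(t) from narrowband Gaussian
    noise (bandwidth ``modulator_bw`` around f_p), emulating the phase
    diffusion of real slow rhythms: the modulator decoheres over
    ~1/modulator_bw seconds, which is what makes time-shifted surrogates
    meaningful.  A strictly periodic modulator is invariant under
    circular shifts (the phase-amplitude profile merely rotates), so
    surrogate tests require this mode.

    ``bursts`` gates g(t): outside the listed (start, end) intervals the
    slow rhythm is silent and the fast oscillation runs unmodulated at
    unit envelope — the intermittent regime where the modulating band is
    not continuously present but fast activity persists.
    """

    fs: float = 1000.0
    duration: float = 60.0
    f_p: float = 8.0
    f_a: float = 80.0
    depth: float = 0.7
    coupling_phase: float = 0.0
    snr: float | None = 3.0
    bursts: tuple[tuple[float, float], ...] | None = None
    modulator: str = "sine"
    modulator_bw: float = 2.0
    pink_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_p < self.f_a < self.fs / 2:
            raise ValueError(
                f"need 0 < f_p < f_a < fs/2, got f_p={self.f_p}, "
                f"f_a={self.f_a}, fs={self.fs}"
            )
        if not 0 <= self.depth <= 1:
            raise ValueError(f"depth must be in [0, 1], got {self.depth}")
        if self.modulator not in ("sine", "stochastic"):
            raise ValueError("modulator must be 'sine' or 'stochastic'")


def _noise(rng: np.random.Generator, n: int, pink: bool) -> np.ndarray:
    white = rng.standard_normal(n)
    if not pink:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def make_pac_signal(spec: PacSpec) -> ChannelSignal:
    """Generate the coupled oscillation described by ``spec``."""
    from scipy import signal as sps

    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(spec.seed)

    if spec.modulator == "sine":
        phi = 2 * np.pi * spec.f_p * t
    else:
        lo = max(spec.f_p - spec.modulator_bw / 2, 0.1)
        hi = spec.f_p + spec.modulator_bw / 2
        sos = sps.butter(4, [lo, hi], btype="band", fs=spec.fs, output="sos")
        narrow = sps.sosfiltfilt(sos, rng.standard_normal(n))
        phi = np.angle(sps.hilbert(narrow))

    gate = np.ones(n)
    if spec.bursts is not None:
        gate = np.zeros(n)
        for start, end in spec.bursts:
            gate[int(start * spec.fs) : int(end * spec.fs)] = 1.0
        # 50 ms smoothing avoids clicks at burst edges
        ramp = int(0.05 * spec.fs)
        if ramp > 1:
            kernel = np.hanning(2 * ramp + 1)
            gate = np.convolve(gate, kernel / kernel.sum(), mode="same")

    slow = gate * np.cos(phi)
    envelope = 1.0 + spec.depth * gate * np.cos(phi - spec.coupling_phase)
    clean = slow + envelope * np.sin(2 * np.pi * spec.f_a * t)

    x = clean
    if spec.snr is not None and np.isfinite(spec.snr):
        noise = _noise(rng, n, spec.pink_noise)
        rms_clean = np.sqrt(np.mean(clean**2))
        noise *= rms_clean / (spec.snr * np.sqrt(np.mean(noise**2)))
        x = clean + noise
    return ChannelSignal(x, spec.fs, t0=0.0)


def alpha_epsp(fs: float, amp: float = 1.0, tau: float = 0.01, duration: float | None = None) -> np.ndarray:
    """Alpha-function EPSP template a(t) = amp * (t/tau) * exp(1 - t/tau).

    Peak amplitude is ``amp`` at t = tau; the maximum rising slope is
    ``amp * e / tau`` at t = 0 (the closed form used as a slope oracle).
    """
    if duration is None:
        duration = 8 * tau
    t = np.arange(int(round(duration * fs))) / fs
    return amp * (t / tau) * np.exp(1 - t / tau)


@dataclass
class StimTruth:
    """Ground truth of a generated stimulation recording."""

    stim_times: np.ndarray
    latency: float
    template: np.ndarray
    pulse_amplitude: float
    isi: float
    paired_interval: float | None = None
    extras: dict = field(default_factory=dict)


def make_stim_recording(
    fs: float = 1000.0,
    n_trials: int = 10,
    isi: float = 3.0,
    paired_interval: float | None = None,
    response_template: np.ndarray | None = None,
    latency: float = 0.020,
    noise_sd: float = 0.0,
    pulse_amplitude: float = 5.0,
    pulse_width: float = 0.002,
    pre_time: float = 1.0,
    seed: int = 0,
) -> tuple[Recording, StimTruth]:
    """Two-channel recording: evoked responses plus a stimulus pulse train.

    Channel 0 carries noise with ``response_template`` inserted
    ``latency`` seconds after each stimulus; channel 1 is the rectangular
    pulse train (amplitude ``pulse_amplitude``, width ``pulse_width``) at
    interval ``isi``, optionally doubled ``paired_interval`` seconds
    apart for paired-pulse protocols.  Stimulation starts ``pre_time``
    seconds in so pre-stimulus baselines exist.
    """
    if response_template is None:
        response_template = alpha_epsp(fs)
    if isi <= response_template.size / fs:
        raise ValueError("isi must exceed the response template duration")
    rng = np.random.default_rng(seed)

    stim_times = pre_time + isi * np.arange(n_trials)
    if paired_interval is not None:
        if not 0 < paired_interval < isi:
            raise ValueError("paired_interval must lie in (0, isi)")
        stim_times = np.sort(np.concatenate([stim_times, stim_times + paired_interval]))

    total = stim_times[-1] + isi
    n = int(round(total * fs))
    signal = rng.standard_normal(n) * noise_sd if noise_sd > 0 else np.zeros(n)
    stim = np.zeros(n)
    w = max(int(round(pulse_width * fs)), 1)
    for t_s in stim_times:
        i0 = int(round(t_s * fs))
        stim[i0 : i0 + w] = pulse_amplitude
        j0 = i0 + int(round(latency * fs))
        j1 = min(j0 + response_template.size, n)
        signal[j0:j1] += response_template[: j1 - j0]

    rec = Recording(
        data=np.vstack([signal, stim]),
        fs=fs,
        channel_labels=["signal", "stim"],
        units=["mV", "mV"],
    )
    truth = StimTruth(
        stim_times=stim_times,
        latency=latency,
        template=response_template,
        pulse_amplitude=pulse_amplitude,
        isi=isi,
        paired_interval=paired_interval,
    )
    return rec, truth


def make_coherent_pair(
    fs: float = 1000.0,
    duration: float = 30.0,
    band: tuple[float, float] = (8.0, 12.0),
    coupling: float = 1.0,
    lag: float = 0.0,
    seed: int = 0,
) -> tuple[ChannelSignal, ChannelSignal]:
    """Two channels sharing a band-limited source.

    Each channel is sqrt(coupling) * shared + sqrt(1 - coupling) * own,
    where shared and the per-channel components are unit-variance noise
    band-filtered to ``band`` — ``coupling`` is the shared-variance
    fraction in the band, so 1 gives identical in-band content (phase
    coherence ~1) and 0 gives independent channels.  ``lag`` delays
    channel 2 by whole samples.
    """
    from scipy import signal as sps

    if not 0 <= coupling <= 1:
        raise ValueError(f"coupling must be in [0, 1], got {coupling}")
    if band[1] >= fs / 2:
        raise ValueError("band must lie below Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    sos = sps.butter(4, band, btype="band", fs=fs, output="sos")

    def band_noise() -> np.ndarray:
        x = sps.sosfiltfilt(sos, rng.standard_normal(n))
        return x / x.std()

    shared = band_noise()
    ch1 = np.sqrt(coupling) * shared + np.sqrt(1 - coupling) * band_noise()
    ch2 = np.sqrt(coupling) * shared + np.sqrt(1 - coupling) * band_noise()
    if lag:
        ch2 = np.roll(ch2, int(round(lag * fs)))
    return ChannelSignal(ch1, fs), ChannelSignal(ch2, fs)
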