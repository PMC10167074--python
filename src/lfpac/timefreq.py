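"""Morlet-wavelet scalograms with normalization and log display transforms.

The transform convolves the signal with complex Morlet wavelets — a
complex exponential under a Gaussian whose width scales with frequency —
so temporal resolution adapts across the frequency axis, unlike a
fixed-window spectrogram.  The Gaussian SD at frequency f is
``n_cycles / (2 pi f)``; larger ``n_cycles`` sharpens frequency resolution
at the cost of temporal resolution.

Wavelets are amplitude-normalized so a unit-amplitude sine at a grid
frequency yields power ~1 in its row, making rows comparable across
frequencies before any display transform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ChannelSignal
from .segmentation import TrialSet

__all__ = [
    "Scalogram",
    "morlet_coefficients",
    "morlet_transform",
    "scalogram_average",
    "transform_scalogram",
]


@dataclass
class Scalogram:
    """Time-frequency power matrix (freqs x times).

    ``transform_state`` tracks display transforms already applied:
    "raw", "normalized", "log" or "normalized+log".  ``coi_samples`` gives,
    per frequency, the number of edge samples inside one wavelet
    half-length (the cone of influence); these samples are flagged, not
    blanked.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_cycles: float
    transform_state: str = "raw"
    coi_samples: np.ndarray | None = None
    n_avg: int = 1


def _morlet_kernel(f: float, fs: float, n_cycles: float) -> np.ndarray:
    sigma_t = n_cycles / (2 * np.pi * f)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2 * sigma_t**2))
    # amplitude normalization: unit sine at f -> |coef| ~ 1
    kernel = 2.0 * np.exp(2j * np.pi * f * t) * gauss / gauss.sum()
    return kernel


def morlet_coefficients(
    sig: ChannelSignal, freqs: np.ndarray, n_cycles: float = 7.0
) -> tuple[np.ndarray, np.ndarray]:
    """Complex wavelet coefficients at the given frequencies.

    Returns ``(coeffs, coi)`` where ``coeffs`` is (n_freqs x n_samples)
    complex and ``coi[i]`` is the per-frequency cone-of-influence width
    in samples.  The signal is reflect-padded by the longest wavelet
    half-length so edges carry no wrap-around.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= sig.fs / 2):
        raise ValueError(
            f"wavelet frequencies must lie in (0, {sig.fs / 2}) Hz; "
            f"got range [{freqs.min()}, {freqs.max()}]"
        )
    if n_cycles < 3:
        raise ValueError(f"n_cycles must be >= 3, got {n_cycles}")

    n = sig.n_samples
    max_half = int(np.ceil(3.5 * n_cycles / (2 * np.pi * freqs.min()) * sig.fs))
    n_pad = min(max_half, n - 1)
    x = np.pad(sig.samples, n_pad, mode="reflect")
    nfft = int(2 ** np.ceil(np.log2(x.size + 2 * max_half + 1)))
    X = np.fft.fft(x, nfft)

    coeffs = np.empty((freqs.size, n), dtype=complex)
    coi = np.empty(freqs.size, dtype=int)
    for i, f in enumerate(freqs):
        k = _morlet_kernel(f, sig.fs, n_cycles)
        half = k.size // 2
        K = np.fft.fft(k, nfft)
        conv = np.fft.ifft(X * K)
        # align: kernel center sits `half` samples into the convolution
        coeffs[i] = conv[n_pad + half : n_pad + half + n]
        coi[i] = min(half, n)
    return coeffs, coi


def morlet_transform(
    sig: ChannelSignal,
    f_low: float,
    f_high: float,
    n_freqs: int | None = None,
    n_cycles: float = 7.0,
    log_spacing: bool = False,
) -> Scalogram:
    """Complex-Morlet scalogram of one channel over [f_low, f_high].

    ``n_freqs`` defaults to one frequency per Hz (linear grid); pass
    ``log_spacing=True`` for a geometric grid.  Power is the squared
    modulus of the wavelet coefficients.
    """
    if not 0 < f_low < f_high:
        raise ValueError(f"need 0 < f_low < f_high, got ({f_low}, {f_high})")
    if f_high >= sig.fs / 2:
        raise ValueError(
            f"f_high {f_high} Hz at or above Nyquist ({sig.fs / 2} Hz); "
            "resample or lower the band"
        )
    if n_freqs is None:
        n_freqs = max(int(round(f_high - f_low)) + 1, 2)
    if n_freqs < 2:
        raise ValueError("n_freqs must be >= 2")
    if log_spacing:
        freqs = np.geomspace(f_low, f_high, n_freqs)
    else:
        freqs = np.linspace(f_low, f_high, n_freqs)

    coeffs, coi = morlet_coefficients(sig, freqs, n_cycles)
    return Scalogram(
        power=np.abs(coeffs) ** 2,
        freqs=freqs,
        times=sig.t0 + np.arange(sig.n_samples) / sig.fs,
        n_cycles=float(n_cycles),
        coi_samples=coi,
    )


def scalogram_average(
    ts: TrialSet,
    f_low: float,
    f_high: float,
    n_freqs: int | None = None,
    n_cycles: float = 7.0,
    log_spacing: bool = False,
) -> Scalogram:
    """Average of per-trial scalograms (power averaged, not coefficients).

    Averaging power keeps induced (non-phase-locked) activity that the
    scalogram of the trial average would cancel.
    """
    if ts.n_trials < 1:
        raise ValueError("empty TrialSet")
    acc = None
    for row in ts.data:
        sc = morlet_transform(
            ChannelSignal(row, ts.fs, t0=float(ts.t_axis[0])),
            f_low, f_high, n_freqs, n_cycles, log_spacing,
        )
        acc = sc if acc is None else replace(acc, power=acc.power + sc.power)
    return replace(acc, power=acc.power / ts.n_trials, n_avg=ts.n_trials)


def transform_scalogram(sc: Scalogram, normalize: bool = False, log: bool = False) -> Scalogram:
    """Apply display transforms: log scale and/or per-frequency z-scoring.

    ``log`` converts to decibels relative to the maximum cell
    (10 log10(P / max P), so the peak reads 0 dB).  ``normalize``
    z-scores each frequency row across time, flattening the 1/f power
    gradient.  When both are requested the log transform is applied
    first, then normalization.  Re-applying a transform already present
    in ``transform_state`` raises.
    """
    state = sc.transform_state
    if log and "log" in state:
        raise ValueError(f"log transform already applied (state={state!r})")
    if normalize and "normalized" in state:
        raise ValueError(f"normalization already applied (state={state!r})")
    if not (normalize or log):
        return sc

    power = sc.power.copy()
    if log:
        peak = power.max()
        if peak <= 0:
            raise ValueError("all-zero scalogram cannot be log-scaled")
        power = 10 * np.log10(np.maximum(power, peak * 1e-12) / peak)
        state = state + "+log" if state != "raw" else "log"
    if normalize:
        mu = power.mean(axis=1, keepdims=True)
        sd = power.std(axis=1, keepdims=True)
        sd[sd < 1e-15] = 1.0
        power = (power - mu) / sd
        state = "normalized" if state in ("raw",) else "normalized+log"
    return replace(sc, power=power, transform_state=state)
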