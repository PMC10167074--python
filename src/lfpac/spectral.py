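"""Band filtering, analytic envelope/phase, FFT spectra and Welch PSD.

Filtering is an adjustable Butterworth bandpass applied forward-backward
(zero phase), so the instantaneous phase estimates that feed the coupling
analyses carry no filter delay.  Note the two-pass application squares the
magnitude response: the response table reported by :func:`design_bandpass`
is this effective response, so a single pass's -3 dB band edge appears at
-6.02 dB there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ChannelSignal
from .segmentation import TrialSet

__all__ = [
    "BandFilterSpec",
    "AnalyticDecomposition",
    "Spectrum",
    "design_bandpass",
    "filter_and_decompose",
    "fft_spectrum",
    "welch_psd",
    "band_power",
]


@dataclass(frozen=True)
class BandFilterSpec:
    """Butterworth bandpass specification: passband (f_low, f_high) Hz, order."""

    f_low: float
    f_high: float
    order: int
    fs: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high < self.fs / 2:
            raise ValueError(
                f"need 0 < f_low < f_high < fs/2, got "
                f"({self.f_low}, {self.f_high}) at fs={self.fs}"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


@dataclass
class AnalyticDecomposition:
    """Band-filtered signal with its Hilbert envelope and instantaneous phase."""

    filtered: np.ndarray
    envelope: np.ndarray
    phase: np.ndarray
    fs: float
    t0: float
    spec: BandFilterSpec

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.filtered.size) / self.fs


@dataclass
class Spectrum:
    """One-sided spectrum: FFT magnitude or Welch power spectral density."""

    freqs: np.ndarray
    power: np.ndarray
    kind: str  # "fft-magnitude" | "psd-welch"
    n_avg: int = 1


def design_bandpass(spec: BandFilterSpec, n_points: int = 2048):
    """Design the bandpass and tabulate its effective frequency response.

    Returns ``(sos, response)`` where ``sos`` is the second-order-section
    cascade (numerically stable for narrow bands) and ``response`` is an
    (n_points, 2) array of (frequency Hz, gain dB) over [0, fs/2].  The
    gain column is the zero-phase effective response — the squared
    magnitude of one pass — because that is what forward-backward
    filtering actually applies to the data.
    """
    sos = sps.butter(
        spec.order, [spec.f_low, spec.f_high], btype="band", fs=spec.fs, output="sos"
    )
    # stability check: poles of each section inside the unit circle
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                f"unstable Butterworth design (order {spec.order}, band "
                f"[{spec.f_low}, {spec.f_high}] Hz at fs={spec.fs}); "
                "lower the order or resample the signal first"
            )
    freqs, h = sps.sosfreqz(sos, worN=n_points, fs=spec.fs)
    mag2 = np.abs(h) ** 2  # effective (two-pass) magnitude
    gain_db = 20 * np.log10(np.maximum(mag2, 1e-300))
    response = np.column_stack([freqs, gain_db])
    return sos, response


def filter_and_decompose(sig: ChannelSignal, spec: BandFilterSpec) -> AnalyticDecomposition:
    """Zero-phase bandpass then Hilbert envelope and instantaneous phase.

    The signal is reflect-padded by three low-frequency periods before
    filtering and the Hilbert transform, and the padding trimmed, which
    keeps filter and analytic-signal edge transients out of the returned
    arrays.
    """
    if sig.fs != spec.fs:
        raise ValueError(f"signal fs {sig.fs} does not match filter fs {spec.fs}")
    n_min = 3 * (2 * spec.order + 1)
    if sig.n_samples <= n_min:
        raise ValueError(
            f"signal too short to filter: {sig.n_samples} samples, need > {n_min}"
        )
    sos, _ = design_bandpass(spec)

    n_pad = min(int(3 * sig.fs / spec.f_low), sig.n_samples - 1)
    x = np.pad(sig.samples, n_pad, mode="reflect")
    filt = sps.sosfiltfilt(sos, x)
    analytic = sps.hilbert(filt)
    filt = filt[n_pad : n_pad + sig.n_samples]
    analytic = analytic[n_pad : n_pad + sig.n_samples]

    return AnalyticDecomposition(
        filtered=filt,
        envelope=np.abs(analytic),
        phase=np.angle(analytic),
        fs=sig.fs,
        t0=sig.t0,
        spec=spec,
    )


def _as_trial_matrix(x: TrialSet | ChannelSignal) -> tuple[np.ndarray, float]:
    if isinstance(x, TrialSet):
        if x.n_trials < 1:
            raise ValueError("empty TrialSet")
        return x.data, x.fs
    return x.samples[None, :], x.fs


def fft_spectrum(x: TrialSet | ChannelSignal, average: bool = True) -> Spectrum:
    """One-sided FFT magnitude spectrum (amplitude units).

    Magnitudes are scaled 2|X|/N so a unit-amplitude sine reads 1 at its
    frequency bin.  With a TrialSet and ``average=True`` the per-trial
    magnitude spectra are arithmetically averaged; ``average=False``
    uses only the first trial.
    """
    data, fs = _as_trial_matrix(x)
    n = data.shape[1]
    if n < 2:
        raise ValueError("input too short for a spectrum")
    if not average:
        data = data[:1]
    mags = np.abs(np.fft.rfft(data, axis=1)) * 2.0 / n
    mags[:, 0] /= 2.0
    if n % 2 == 0:
        mags[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Spectrum(
        freqs=freqs, power=mags.mean(axis=0), kind="fft-magnitude", n_avg=data.shape[0]
    )


def welch_psd(
    x: TrialSet | ChannelSignal,
    seg_len: float = 1.0,
    overlap: float = 0.5,
    average: bool = True,
) -> Spectrum:
    """Welch power spectral density (units^2/Hz), Hann window.

    ``seg_len`` is the segment length in seconds, ``overlap`` the fractional
    overlap between segments.  With a TrialSet and ``average=True`` the
    per-trial PSDs are averaged.
    """
    data, fs = _as_trial_matrix(x)
    nperseg = int(round(seg_len * fs))
    if nperseg < 8:
        raise ValueError(f"seg_len {seg_len}s too short at fs={fs}")
    if nperseg > data.shape[1]:
        raise ValueError(
            f"seg_len {seg_len}s exceeds trial duration {data.shape[1] / fs}s"
        )
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if not average:
        data = data[:1]
    freqs, psd = sps.welch(
        data, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), axis=1,
    )
    return Spectrum(
        freqs=freqs, power=psd.mean(axis=0), kind="psd-welch", n_avg=data.shape[0]
    )


def band_power(sp: Spectrum, f_low: float, f_high: float, relative: bool = False) -> float:
    """Trapezoidal integral of the spectrum over [f_low, f_high].

    ``relative=True`` divides by the integral over the full frequency
    range, giving the fraction of total power in the band (in [0, 1]).
    """
    if f_low >= f_high:
        raise ValueError(f"f_low ({f_low}) must be < f_high ({f_high})")
    if f_low < sp.freqs[0] - 1e-9 or f_high > sp.freqs[-1] + 1e-9:
        raise ValueError(
            f"band [{f_low}, {f_high}] outside spectrum range "
            f"[{sp.freqs[0]}, {sp.freqs[-1]}]"
        )
    # integrate on a grid that includes the exact band edges
    grid = np.unique(np.concatenate([
        [f_low, f_high], sp.freqs[(sp.freqs > f_low) & (sp.freqs < f_high)]
    ]))
    vals = np.interp(grid, sp.freqs, sp.power)
    num = float(np.trapezoid(vals, grid))
    if not relative:
        return num
    den = float(np.trapezoid(sp.power, sp.freqs))
    if den <= 0:
        raise ValueError("total spectral power is zero; relative power undefined")
    return num / den
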