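"""Reading electrophysiology recordings into a common in-memory model.

Two container types are shared across the package:

``Recording``
    A multichannel trace (channels x samples) with one sampling rate.
``ChannelSignal``
    A single-channel view with its own time origin, used by every
    analysis function.

EDF/EDF+ files are parsed with MNE.  ABF version-1 files are parsed by a
small reader implemented here against the published ABF-1 header layout
(Axon's file format is not covered by any library in this stack); both
int16 (gain/offset scaled) and float32 data sections are supported.
Plain-text writers for both formats exist so synthetic fixtures can be
round-tripped through the real loading path.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "ChannelSignal",
    "load_recording",
    "resample",
    "write_edf",
    "write_abf",
    "UnsupportedFormatError",
]


class UnsupportedFormatError(ValueError):
    """Raised when a file is in a format this package cannot read."""


@dataclass
class Recording:
    """Multichannel sampled signal with shared sampling rate.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in recorded physical units (typically mV).
    fs : float
        Sampling frequency in Hz.
    channel_labels : list of str
    units : list of str
        Physical unit per channel.
    source_path : str
        Originating file, or "" for in-memory recordings.
    sweep_boundaries : list of int
        Sample indices where acquisition sweeps were concatenated
        (empty for gap-free recordings).  Kept as metadata only;
        segmentation is driven by the stimulus channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    units: list[str] = field(default_factory=list)
    source_path: str = ""
    sweep_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        n_ch = self.data.shape[0]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(n_ch)]
        if not self.units:
            self.units = ["mV"] * n_ch
        if len(self.channel_labels) != n_ch or len(self.units) != n_ch:
            raise ValueError("channel metadata length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, index: int) -> "ChannelSignal":
        """Single-channel view. ``index`` is 0-based."""
        if not 0 <= index < self.n_channels:
            raise IndexError(
                f"channel {index} out of range (recording has {self.n_channels})"
            )
        return ChannelSignal(samples=self.data[index], fs=self.fs, t0=0.0)


@dataclass
class ChannelSignal:
    """One sampled channel with time origin ``t0`` (s) for its first sample."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.isfinite(self.samples).all():
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# loading


def _sniff_format(path: str) -> str:
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic[:4] in (b"ABF ", b"ABF2"):
        return "abf"
    # EDF: 8-byte ASCII version field, "0       " for EDF/EDF+
    if magic[:1] in (b"0", b"\xff") and magic[:8].strip() in (b"0", b"\xffBIOSEMI"):
        return "edf"
    raise UnsupportedFormatError(
        f"cannot identify format of {path!r} from content (magic={magic[:4]!r})"
    )


def load_recording(path: str, format: str = "auto") -> Recording:
    """Load an ABF or EDF file into a :class:`Recording`.

    Format resolution under ``format="auto"`` is by file content, not
    extension; a mislabelled file loads under its true format.  Episodic
    (multi-sweep) ABF files are concatenated into one continuous trace in
    acquisition order, with sweep boundaries retained as metadata.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format == "edf":
        return _load_edf(path)
    if format == "abf":
        return _load_abf1(path)
    raise UnsupportedFormatError(f"unsupported format {format!r} (use abf or edf)")


def _load_edf(path: str) -> Recording:
    import tempfile

    import mne

    read_path = path
    tmp = None
    if not path.lower().endswith(".edf"):
        # content said EDF but MNE insists on the extension; alias the file
        tmp = tempfile.NamedTemporaryFile(suffix=".edf", delete=False)
        tmp.close()
        os.unlink(tmp.name)
        os.symlink(os.path.abspath(path), tmp.name)
        read_path = tmp.name
    try:
        raw = mne.io.read_raw_edf(read_path, preload=True, verbose="error")
    finally:
        if tmp is not None:
            os.unlink(tmp.name)
    data = raw.get_data()  # MNE rescales known units to SI
    units = []
    for name in raw.ch_names:
        orig = getattr(raw, "_orig_units", {}).get(name, "") or ""
        units.append(orig if orig not in ("n/a", "NA") else "")
    # undo MNE's SI conversion so data are in the file's physical units
    factors = {"mV": 1e3, "uV": 1e6, "µV": 1e6, "V": 1.0}
    for i, u in enumerate(units):
        data[i] *= factors.get(u, 1.0)
    rec = Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        units=[u or "mV" for u in units],
        source_path=path,
    )
    return rec


# --- minimal ABF-1 reader/writer ------------------------------------------
# Header offsets follow the ABF-1 "ABFFileHeader" layout (little-endian).
_ABF1 = {
    "fFileVersionNumber": (4, "<f"),
    "nOperationMode": (8, "<h"),
    "lActualAcqLength": (10, "<i"),
    "lActualEpisodes": (16, "<i"),
    "lDataSectionPtr": (40, "<i"),
    "nDataFormat": (100, "<h"),
    "nADCNumChannels": (120, "<h"),
    "fADCSampleInterval": (122, "<f"),
    "fADCRange": (244, "<f"),
    "lADCResolution": (252, "<i"),
}
_ABF1_BLOCK = 512
_ABF1_HEADER_LEN = 2048
_OFF_SAMPLING_SEQ = 410  # int16[16]
_OFF_CHANNEL_NAME = 442  # char[16][10]
_OFF_UNITS = 602  # char[16][8]
_OFF_PROG_GAIN = 730  # float[16]
_OFF_INSTR_SCALE = 922  # float[16]
_OFF_INSTR_OFFSET = 986  # float[16]
_OFF_SIGNAL_GAIN = 1050  # float[16]
_OFF_SIGNAL_OFFSET = 1114  # float[16]


def _load_abf1(path: str) -> Recording:
    with open(path, "rb") as fh:
        buf = fh.read()
    if buf[:4] == b"ABF2":
        raise UnsupportedFormatError(
            "ABF2 files are not supported; convert to ABF1 or EDF"
        )
    if buf[:4] != b"ABF " or len(buf) < _ABF1_HEADER_LEN:
        raise IOError(f"{path!r}: not a valid ABF1 file (bad signature or truncated header)")

    h = {k: struct.unpack_from(fmt, buf, off)[0] for k, (off, fmt) in _ABF1.items()}
    n_ch = h["nADCNumChannels"]
    if n_ch <= 0:
        raise IOError(f"{path!r}: header reports {n_ch} ADC channels")
    total = h["lActualAcqLength"]
    fs = 1e6 / (h["fADCSampleInterval"] * n_ch)

    seq = struct.unpack_from("<16h", buf, _OFF_SAMPLING_SEQ)[:n_ch]
    labels, units = [], []
    for i, adc in enumerate(seq):
        raw_name = buf[_OFF_CHANNEL_NAME + 10 * adc : _OFF_CHANNEL_NAME + 10 * (adc + 1)]
        raw_unit = buf[_OFF_UNITS + 8 * adc : _OFF_UNITS + 8 * (adc + 1)]
        labels.append(raw_name.decode("ascii", "replace").strip() or f"ch{i}")
        units.append(raw_unit.decode("ascii", "replace").strip() or "mV")

    start = h["lDataSectionPtr"] * _ABF1_BLOCK
    itemsize = 4 if h["nDataFormat"] == 1 else 2
    available = max(len(buf) - start, 0) // itemsize
    if available < total:
        raise IOError(
            f"{path!r}: data section truncated "
            f"(header promises {total} samples, file holds {available})"
        )
    if h["nDataFormat"] == 1:
        raw = np.frombuffer(buf, dtype="<f4", count=total, offset=start)
        data = raw.reshape(-1, n_ch).T.astype(float)
    elif h["nDataFormat"] == 0:
        raw = np.frombuffer(buf, dtype="<i2", count=total, offset=start)
        data = raw.reshape(-1, n_ch).T.astype(float)
        for i, adc in enumerate(seq):
            gain = (
                struct.unpack_from("<f", buf, _OFF_INSTR_SCALE + 4 * adc)[0]
                * struct.unpack_from("<f", buf, _OFF_PROG_GAIN + 4 * adc)[0]
                * struct.unpack_from("<f", buf, _OFF_SIGNAL_GAIN + 4 * adc)[0]
            ) or 1.0
            offset = (
                struct.unpack_from("<f", buf, _OFF_INSTR_OFFSET + 4 * adc)[0]
                - struct.unpack_from("<f", buf, _OFF_SIGNAL_OFFSET + 4 * adc)[0]
            )
            data[i] = data[i] * h["fADCRange"] / (h["lADCResolution"] * gain) + offset
    else:
        raise IOError(f"{path!r}: unknown ABF data format code {h['nDataFormat']}")

    n_per_ch = data.shape[1]
    boundaries = []
    episodes = h["lActualEpisodes"]
    if h["nOperationMode"] == 5 and episodes > 1 and n_per_ch % episodes == 0:
        sweep = n_per_ch // episodes
        boundaries = [sweep * k for k in range(1, episodes)]

    return Recording(
        data=data,
        fs=fs,
        channel_labels=labels,
        units=units,
        source_path=path,
        sweep_boundaries=boundaries,
    )


def write_abf(path: str, rec: Recording) -> None:
    """Write a Recording as a gap-free float32 ABF1 file (fixture writer)."""
    n_ch, n_samp = rec.data.shape
    if n_ch > 16:
        raise ValueError("ABF1 supports at most 16 channels")
    hdr = bytearray(_ABF1_HEADER_LEN)
    hdr[0:4] = b"ABF "
    struct.pack_into("<f", hdr, 4, 1.83)
    struct.pack_into("<h", hdr, 8, 3)  # gap-free
    struct.pack_into("<i", hdr, 10, n_ch * n_samp)
    struct.pack_into("<i", hdr, 16, 1)
    struct.pack_into("<i", hdr, 40, _ABF1_HEADER_LEN // _ABF1_BLOCK)
    struct.pack_into("<h", hdr, 100, 1)  # float32
    struct.pack_into("<h", hdr, 120, n_ch)
    struct.pack_into("<f", hdr, 122, 1e6 / (rec.fs * n_ch))
    struct.pack_into("<f", hdr, 244, 10.0)
    struct.pack_into("<i", hdr, 252, 32768)
    for i in range(n_ch):
        struct.pack_into("<h", hdr, _OFF_SAMPLING_SEQ + 2 * i, i)
        name = rec.channel_labels[i][:10].ljust(10).encode("ascii", "replace")
        hdr[_OFF_CHANNEL_NAME + 10 * i : _OFF_CHANNEL_NAME + 10 * (i + 1)] = name
        unit = rec.units[i][:8].ljust(8).encode("ascii", "replace")
        hdr[_OFF_UNITS + 8 * i : _OFF_UNITS + 8 * (i + 1)] = unit
        for off in (_OFF_PROG_GAIN, _OFF_INSTR_SCALE, _OFF_SIGNAL_GAIN):
            struct.pack_into("<f", hdr, off + 4 * i, 1.0)
    interleaved = np.ascontiguousarray(rec.data.T, dtype="<f4")
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(interleaved.tobytes())


def write_edf(path: str, rec: Recording) -> None:
    """Write a Recording as an EDF file (16-bit quantized, 1 s records).

    Trailing samples that do not fill a whole 1 s data record are dropped,
    as EDF stores an integer number of records.
    """
    data = rec.data
    n_ch = data.shape[0]
    spr = int(round(rec.fs))
    if abs(spr - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = data.shape[1] // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = data[:, : n_rec * spr]

    pmin = data.min(axis=1).astype(float)
    pmax = data.max(axis=1).astype(float)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    def fld(value, width) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    hdr = fld(0, 8) + fld("X X X X", 80) + fld("Startdate 01-JAN-2020 X X X", 80)
    hdr += fld("01.01.20", 8) + fld("00.00.00", 8)
    hdr += fld(256 + 256 * n_ch, 8) + fld("", 44)
    hdr += fld(n_rec, 8) + fld(1, 8) + fld(n_ch, 4)
    hdr += b"".join(fld(l, 16) for l in rec.channel_labels)
    hdr += b"".join(fld("", 80) for _ in range(n_ch))
    hdr += b"".join(fld(u, 8) for u in rec.units)
    hdr += b"".join(fld(f"{v:.4g}"[:8], 8) for v in pmin)
    hdr += b"".join(fld(f"{v:.4g}"[:8], 8) for v in pmax)
    hdr += fld(dmin, 8) * n_ch + fld(dmax, 8) * n_ch
    hdr += b"".join(fld("", 80) for _ in range(n_ch))
    hdr += fld(spr, 8) * n_ch
    hdr += b"".join(fld("", 32) for _ in range(n_ch))

    # re-read the rounded physical limits so the digitization matches the header
    pmin = np.array([float(f"{v:.4g}"[:8]) for v in pmin])
    pmax = np.array([float(f"{v:.4g}"[:8]) for v in pmax])
    scale = (pmax - pmin) / (dmax - dmin)
    dig = np.round((data - pmin[:, None]) / scale[:, None] + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(dig[c, r * spr : (r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# resampling


def resample(rec: Recording, target_fs: float) -> Recording:
    """Downsample with an anti-aliasing low-pass (cutoff 0.4 x target_fs).

    Polyphase resampling handles non-integer ratios.  Upsampling is out of
    contract: ``target_fs`` must not exceed ``rec.fs``.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs > rec.fs:
        raise ValueError(
            f"target_fs={target_fs} exceeds recording fs={rec.fs}; "
            "upsampling is not supported"
        )
    if abs(target_fs - rec.fs) < 1e-12:
        return replace(rec, data=rec.data.copy())

    # zero-phase anti-alias filter, then polyphase rate change
    sos = sps.butter(8, 0.4 * target_fs, btype="low", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(filtered, ratio.numerator, ratio.denominator, axis=1)
    n_expect = int(round(rec.n_samples * target_fs / rec.fs))
    out = out[:, :n_expect]
    boundaries = [int(round(b * target_fs / rec.fs)) for b in rec.sweep_boundaries]
    return replace(rec, data=out, fs=float(target_fs), sweep_boundaries=boundaries)
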