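"""Session I/O, preprocessing and framing for multichannel EEG.

An :class:`EegRecord` holds one recording session as a channels x samples
matrix with its sampling rate and channel labels (the classic six-electrode
montage C3, C4, P3, P4, O1, O2 of the 10-20 system by default).  Sessions
are notch-filtered against mains interference and then cut into short
overlapping :class:`Frame` windows -- the unit on which decomposition,
feature extraction and classification operate.  The default geometry is
1-second frames advanced by 0.5 s (50% overlap), i.e. 250 samples per frame
at the 250 Hz sampling rate typical of mental-task recordings.

Amplitude units are carried opaquely: none of the downstream features
require a calibrated microvolt scale, so no unit conversion is attempted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

DEFAULT_CHANNELS = ("C3", "C4", "P3", "P4", "O1", "O2")


@dataclasses.dataclass
class EegRecord:
    """One EEG session: a channels x samples matrix plus metadata.

    Parameters
    ----------
    signal
        2-D array, shape ``(n_channels, n_samples)``.  Amplitude units are
        opaque (whatever the source file carried).
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        Unique channel names in row order.
    task
        Class label of the session (e.g. one of R, M, L, C, B), or any
        string; ``None`` for unlabelled data.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    task: str | None = None
    subject_id: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        self.channel_labels = tuple(self.channel_labels)
        n_ch = self.signal.shape[0]
        if n_ch < 2:
            raise ValueError("an EEG record needs at least 2 channels")
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"{n_ch} channels but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.n_samples / self.fs


@dataclasses.dataclass
class Frame:
    """One fixed-length analysis window of a session (all channels)."""

    signal: np.ndarray  # channels x N
    fs: float
    channel_labels: tuple[str, ...]
    task: str | None = None
    session_id: str | None = None
    frame_index: int = 0
    start_sample: int = 0

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_signal_rates(path: Path) -> list[float]:
    """Per-signal sampling rates from an EDF header (annotations excluded).

    The EDF header is plain ASCII with fixed-width fields, so the rates can
    be taken directly from it; the actual samples are read through mne.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        record_dur = float(header[244:252].decode("ascii").strip() or 1.0)
        ns = int(header[252:256].decode("ascii").strip())
        sig_header = fh.read(ns * 256)
    labels = [
        sig_header[i * 16:(i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    n_samps = [
        int(sig_header[off + i * 8: off + (i + 1) * 8].decode("ascii").strip())
        for i in range(ns)
    ]
    return [
        n / record_dur
        for lab, n in zip(labels, n_samps)
        if "EDF Annotations" not in lab
    ]


def read_edf(path: str | Path, task: str | None = None) -> EegRecord:
    """Read an EDF/EDF+ file into an :class:`EegRecord`.

    Channel order and labels are preserved from the file.  Files whose
    signals are stored at different sampling rates are rejected rather than
    silently resampled.  Amplitudes are returned in the file's physical
    units (microvolt-labelled channels stay in microvolts).
    """
    import mne

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    rates = _edf_signal_rates(path)
    if len(set(rates)) > 1:
        raise ValueError(
            f"{path}: mixed per-channel sampling rates {sorted(set(rates))}; "
            "resampling is not performed -- provide a single-rate file"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    # mne rescales dimensioned channels to SI units; undo the scaling so the
    # caller sees the file's own physical units.
    orig_units = getattr(raw, "_orig_units", {}) or {}
    scale_back = {"µV": 1e6, "uV": 1e6, "mV": 1e3, "V": 1.0}
    for idx, name in enumerate(raw.ch_names):
        unit = orig_units.get(name)
        if unit in scale_back:
            data[idx] *= scale_back[unit]
    if data.shape[0] < 2:
        raise ValueError(f"{path}: fewer than 2 signals")
    return EegRecord(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        task=task,
        session_id=path.stem,
    )


def write_edf(
    record: EegRecord,
    path: str | Path,
    physical_range: tuple[float, float] | None = None,
    physical_dim: str = "uV",
) -> Path:
    """Write a record as a minimal EDF file (16-bit samples, 1-s records).

    The session length must be a whole number of seconds and ``fs`` an
    integer so the samples tile into one-second data records.  Amplitudes
    are linearly quantized onto the 16-bit digital range over
    ``physical_range`` (the data's own min-max span when omitted); passing
    ``physical_range=(-32768, 32767)`` with integer-valued data makes the
    mapping exact.
    """
    path = Path(path)
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_ch, n_samp = record.signal.shape
    if n_samp % fs_i != 0:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_records = n_samp // fs_i

    if physical_range is None:
        lo = float(np.min(record.signal))
        hi = float(np.max(record.signal))
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
    else:
        lo, hi = map(float, physical_range)
    dmin, dmax = -32768, 32767
    gain = (hi - lo) / (dmax - dmin)
    digital = np.clip(np.round((record.signal - lo) / gain) + dmin, dmin, dmax)
    digital = digital.astype("<i2")

    def field(text: str, width: int) -> bytes:
        s = text[:width].ljust(width)
        return s.encode("ascii")

    header = b"".join([
        field("0", 8),
        field(record.subject_id or "X", 80),
        field(record.session_id or "X", 80),
        field("01.01.00", 8),
        field("00.00.00", 8),
        field(str(256 * (1 + n_ch)), 8),
        field("", 44),
        field(str(n_records), 8),
        field("1", 8),
        field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(field(lab, 16) for lab in record.channel_labels),
        b"".join(field("", 80) for _ in range(n_ch)),
        b"".join(field(physical_dim, 8) for _ in range(n_ch)),
        b"".join(field(f"{lo:.8g}"[:8], 8) for _ in range(n_ch)),
        b"".join(field(f"{hi:.8g}"[:8], 8) for _ in range(n_ch)),
        b"".join(field(str(dmin), 8) for _ in range(n_ch)),
        b"".join(field(str(dmax), 8) for _ in range(n_ch)),
        b"".join(field("", 80) for _ in range(n_ch)),
        b"".join(field(str(fs_i), 8) for _ in range(n_ch)),
        b"".join(field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            block = digital[:, r * fs_i:(r + 1) * fs_i]
            fh.write(block.tobytes())
    return path


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def read_delimited(
    path: str | Path,
    fs: float,
    labels: Sequence[str] | None = None,
    orientation: str = "rows",
    delimiter: str | None = None,
    task: str | None = None,
) -> EegRecord:
    """Read a rectangular numeric table as an EEG session.

    ``orientation`` declares whether channels run along ``"rows"`` or
    ``"columns"``; the matrix is coerced to channels x samples either way.
    Non-numeric cells and ragged rows are rejected.
    """
    path = Path(path)
    if orientation not in ("rows", "columns"):
        raise ValueError("orientation must be 'rows' or 'columns'")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, header=None, sep=delimiter, skipinitialspace=True)
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells in table")
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing or non-numeric cells in table")
    matrix = values if orientation == "rows" else values.T
    n_ch = matrix.shape[0]
    if labels is None:
        labels = DEFAULT_CHANNELS if n_ch == len(DEFAULT_CHANNELS) else tuple(
            f"ch{i}" for i in range(n_ch)
        )
    return EegRecord(
        signal=matrix,
        fs=fs,
        channel_labels=tuple(labels),
        task=task,
        session_id=path.stem,
    )


def write_delimited(record: EegRecord, path: str | Path) -> Path:
    """Write channels-as-rows CSV (no header); inverse of ``read_delimited``."""
    path = Path(path)
    np.savetxt(path, record.signal, delimiter=",", fmt="%.10g")
    return path


# ---------------------------------------------------------------------------
# Preprocessing and framing
# ---------------------------------------------------------------------------

def notch_filter(record: EegRecord, f0_hz: float = 60.0, q: float = 30.0) -> EegRecord:
    """Zero-phase IIR notch at ``f0_hz`` (mains interference removal).

    A second-order notch of quality factor ``q`` is applied forward and
    backward (``filtfilt``) to every channel, so the waveform stays aligned
    with the input.  Applied to the whole session before framing.
    """
    if not 0 < f0_hz < record.fs / 2:
        raise ValueError(
            f"notch frequency {f0_hz} Hz must lie in (0, fs/2={record.fs / 2})"
        )
    b, a = sps.iirnotch(f0_hz, q, fs=record.fs)
    filtered = sps.filtfilt(b, a, record.signal, axis=1)
    return dataclasses.replace(record, signal=filtered)


def segment_frames(
    record: EegRecord,
    frame_seconds: float = 1.0,
    shift_seconds: float = 0.5,
) -> list[Frame]:
    """Cut a session into overlapping fixed-length frames.

    Frames are ``round(frame_seconds * fs)`` samples long and start every
    ``round(shift_seconds * fs)`` samples; an incomplete tail window is
    dropped, never padded.  Each frame inherits the session's task label.
    """
    n = int(round(frame_seconds * record.fs))
    shift = int(round(shift_seconds * record.fs))
    if n < 1 or shift < 1:
        raise ValueError("frame and shift must each span at least one sample")
    if n > record.n_samples:
        raise ValueError(
            f"frame of {n} samples longer than record of {record.n_samples}"
        )
    n_frames = (record.n_samples - n) // shift + 1
    frames = []
    for k in range(n_frames):
        start = k * shift
        frames.append(
            Frame(
                signal=record.signal[:, start:start + n].copy(),
                fs=record.fs,
                channel_labels=record.channel_labels,
                task=record.task,
                session_id=record.session_id,
                frame_index=k,
                start_sample=start,
            )
        )
    return frames


def expected_frame_count(n_samples: int, fs: float, frame_seconds: float = 1.0,
                         shift_seconds: float = 0.5) -> int:
    """Closed-form frame count: floor((S - N) / shift) + 1."""
    n = int(round(frame_seconds * fs))
    shift = int(round(shift_seconds * fs))
    if n_samples < n:
        return 0
    return (n_samples - n) // shift + 1


def frames_to_long(frames: Sequence[Frame]) -> pd.DataFrame:
    """Long-format export: one row per (session, frame, channel, sample)."""
    parts = []
    for fr in frames:
        for ci, ch in enumerate(fr.channel_labels):
            parts.append(pd.DataFrame({
                "session": fr.session_id,
                "frame": fr.frame_index,
                "channel": ch,
                "sample": np.arange(fr.n_samples),
                "value": fr.signal[ci],
            }))
    return pd.concat(parts, ignore_index=True)
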