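"""Recordings, labels and windowing for 10-channel facial sEMG.

A recording is a fixed layout of ten working electrodes placed over facial
action units (FACS AUs); each recording carries a posed expression label,
an intensity level (1-5, letters A-E), a subject id and an acquisition
batch/session id.  Channels CH6, CH8 and CH10 sit at the corners of the
mouth and dominate during happiness.

Two interchange formats are supported:

* a delimited text dialect (UTF-8 CSV, ``#key=value`` metadata header,
  columns CH1..CH10) with bit-exact float round-trip;
* EDF (European Data Format), 16-bit quantized, as a secondary format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

# ---------------------------------------------------------------------------
# Constants: label vocabulary and electrode layout

#: The seven prototypical expressions, in fixed encoding order.
EXPRESSIONS: tuple[str, ...] = (
    "contempt", "surprise", "sadness", "happiness", "anger", "disgust", "fear",
)

#: FACS intensity letters, A = minimal (1) .. E = maximal (5).
INTENSITY_LETTERS: str = "ABCDE"

#: Action unit recorded by each working electrode, CH1..CH10 in order.
CHANNEL_AUS: tuple[str, ...] = (
    "AU1", "AU2", "AU4", "AU9", "AU10", "AU26", "AU12", "AU23", "AU17", "AU15",
)

N_CHANNELS: int = 10

#: 1-based channels at the corners of the mouth (maximal during happiness).
MOUTH_CORNER_CHANNELS: tuple[int, ...] = (6, 8, 10)

DEFAULT_FS: float = 1000.0
DEFAULT_WINDOW: int = 200
DEFAULT_HOP: int = 50


class ChannelCountError(ValueError):
    """A file or array does not carry exactly 10 working channels."""


class FormatError(ValueError):
    """Metadata of a recording file could not be parsed."""


class EmptyInputError(ValueError):
    """A signal is shorter than one analysis window."""


# ---------------------------------------------------------------------------
# Labels


def intensity_from_letter(letter: str) -> int:
    """Map a FACS intensity letter A-E to the integer level 1-5."""
    letter = letter.strip().upper()
    if len(letter) != 1 or letter not in INTENSITY_LETTERS:
        raise ValueError(f"intensity letter must be one of A-E, got {letter!r}")
    return INTENSITY_LETTERS.index(letter) + 1


def intensity_to_letter(level: int) -> str:
    """Map an intensity level 1-5 to its FACS letter A-E."""
    if not 1 <= int(level) <= 5:
        raise ValueError(f"intensity level must be in [1, 5], got {level!r}")
    return INTENSITY_LETTERS[int(level) - 1]


@dataclass(frozen=True)
class ExpressionLabel:
    """A posed expression (one of seven) at an intensity level 1-5."""

    expression: str
    intensity: int

    def __post_init__(self) -> None:
        if self.expression not in EXPRESSIONS:
            raise ValueError(
                f"unknown expression {self.expression!r}; "
                f"expected one of {EXPRESSIONS}"
            )
        if not isinstance(self.intensity, (int, np.integer)) or not 1 <= self.intensity <= 5:
            raise ValueError(f"intensity must be an integer in [1, 5], got {self.intensity!r}")

    @property
    def intensity_letter(self) -> str:
        return intensity_to_letter(self.intensity)

    @classmethod
    def from_letter(cls, expression: str, letter: str) -> "ExpressionLabel":
        return cls(expression, intensity_from_letter(letter))


# ---------------------------------------------------------------------------
# Recording and Frame


@dataclass
class Recording:
    """A labelled 10-channel sEMG time series.

    ``signals`` has shape (10, T) in microvolts; ``channel_map`` lists the
    action unit recorded by each channel, in CH1..CH10 order.
    """

    signals: np.ndarray
    fs: float = DEFAULT_FS
    label: ExpressionLabel | None = None
    subject_id: str = "S1"
    batch_id: str = "B1"
    channel_map: tuple[str, ...] = CHANNEL_AUS

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != N_CHANNELS:
            raise ChannelCountError(
                f"signals must have shape (10, T), got {self.signals.shape}"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_map) != N_CHANNELS or len(set(self.channel_map)) != N_CHANNELS:
            raise ValueError("channel_map must contain 10 unique AU tags")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Frame:
    """One fixed-length analysis window of a recording (10 x N samples)."""

    window: np.ndarray
    start_index: int
    label: ExpressionLabel | None = None

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.ndim != 2 or self.window.shape[0] != N_CHANNELS:
            raise ChannelCountError(
                f"frame window must have shape (10, N), got {self.window.shape}"
            )


def segment_windows(
    rec: Recording, window: int = DEFAULT_WINDOW, hop: int = DEFAULT_HOP
) -> list[Frame]:
    """Deterministic sliding-window segmentation of a recording.

    With the defaults (window N=200 samples, hop 50 at 1000 Hz) frames are
    produced at 20 per second with 75% overlap.  Frame *i* starts at
    ``i * hop``; the number of frames is ``floor((T - window) / hop) + 1``.
    All frames inherit the recording's label.
    """
    if window < 1 or hop < 1:
        raise ValueError("window and hop must be >= 1")
    T = rec.n_samples
    if T < window:
        raise EmptyInputError(f"recording has {T} samples, shorter than window {window}")
    n = (T - window) // hop + 1
    return [
        Frame(rec.signals[:, i * hop : i * hop + window], i * hop, rec.label)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Delimited dialect

_META_KEYS = ("fs", "expression", "intensity", "subject_id", "batch_id")


def write_recording(rec: Recording, path: str | Path, format: str = "delimited") -> Path:
    """Write a recording; the delimited dialect round-trips bit-exactly."""
    path = Path(path)
    if format == "delimited":
        _write_delimited(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_recording(path: str | Path, format: str = "delimited") -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if format == "delimited":
        return _read_delimited(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


def _write_delimited(rec: Recording, path: Path) -> None:
    lines = [
        f"#fs={rec.fs!r}",
        f"#expression={rec.label.expression if rec.label else ''}",
        f"#intensity={rec.label.intensity if rec.label else ''}",
        f"#subject_id={rec.subject_id}",
        f"#batch_id={rec.batch_id}",
        ",".join(f"CH{i + 1}" for i in range(N_CHANNELS)),
    ]
    # repr() of a python float round-trips exactly through float().
    cols = rec.signals.T
    lines.extend(",".join(repr(float(v)) for v in row) for row in cols)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_delimited(path: Path) -> Recording:
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    header: list[str] | None = None
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise FormatError(f"bad metadata line {line!r}")
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif header is None:
            header = [c.strip() for c in line.split(",")]
        else:
            data_lines.append(line)
    if header is None:
        raise FormatError(f"{path}: no column header found")
    if len(header) != N_CHANNELS:
        raise ChannelCountError(
            f"{path}: expected {N_CHANNELS} channel columns, found {len(header)}"
        )
    try:
        fs = float(meta["fs"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing or invalid fs metadata") from exc
    rows = []
    for line in data_lines:
        values = line.split(",")
        if len(values) != N_CHANNELS:
            raise ChannelCountError(
                f"{path}: data row has {len(values)} columns, expected {N_CHANNELS}"
            )
        rows.append([float(v) for v in values])
    signals = np.array(rows, dtype=float).T
    label = None
    if meta.get("expression"):
        try:
            label = ExpressionLabel(meta["expression"], int(meta["intensity"]))
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: invalid label metadata") from exc
    return Recording(
        signals=signals,
        fs=fs,
        label=label,
        subject_id=meta.get("subject_id", "S1"),
        batch_id=meta.get("batch_id", "B1"),
    )


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit, one data record.
#
# The header is plain ASCII with fixed-width fields; samples are little-endian
# int16 mapped linearly between the per-channel physical min/max.  Label and
# batch metadata travel in the standard 80-char patient/recording id fields.


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF field {s!r} exceeds {width} characters")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int) -> str:
    """Format a float into a fixed-width EDF numeric field."""
    for fmt in (f"{x:.10g}", f"{x:.6g}", f"{x:.3g}"):
        if len(fmt) <= width:
            return fmt
    raise FormatError(f"cannot fit {x} into {width} chars")


def _write_edf(rec: Recording, path: Path) -> None:
    T = rec.n_samples
    duration = T / rec.fs
    patient = rec.subject_id or "X"
    if rec.label is not None:
        recording_id = (
            f"expression={rec.label.expression} intensity={rec.label.intensity} "
            f"batch={rec.batch_id}"
        )
    else:
        recording_id = f"batch={rec.batch_id}"

    phys_min = rec.signals.min(axis=1)
    phys_max = rec.signals.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((rec.signals - phys_min[:, None]) / scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    ns = N_CHANNELS
    header_bytes = 256 + 256 * ns
    buf = bytearray()
    buf += _ascii_field("0", 8)                       # version
    buf += _ascii_field(patient, 80)                  # patient id
    buf += _ascii_field(recording_id, 80)             # recording id
    buf += _ascii_field("01.01.00", 8)                # start date (placeholder)
    buf += _ascii_field("00.00.00", 8)                # start time
    buf += _ascii_field(header_bytes, 8)
    buf += _ascii_field("", 44)                       # reserved
    buf += _ascii_field(1, 8)                         # number of data records
    buf += _ascii_field(_fmt_float(duration, 8), 8)   # record duration (s)
    buf += _ascii_field(ns, 4)
    for i in range(ns):
        buf += _ascii_field(f"CH{i + 1} {rec.channel_map[i]}", 16)
    for _ in range(ns):
        buf += _ascii_field("AgCl electrode", 80)     # transducer
    for _ in range(ns):
        buf += _ascii_field("uV", 8)                  # physical dimension
    for i in range(ns):
        buf += _ascii_field(_fmt_float(float(phys_min[i]), 8), 8)
    for i in range(ns):
        buf += _ascii_field(_fmt_float(float(phys_max[i]), 8), 8)
    for _ in range(ns):
        buf += _ascii_field(dig_min, 8)
    for _ in range(ns):
        buf += _ascii_field(dig_max, 8)
    for _ in range(ns):
        buf += _ascii_field("", 80)                   # prefiltering
    for _ in range(ns):
        buf += _ascii_field(T, 8)                     # samples per record
    for _ in range(ns):
        buf += _ascii_field("", 32)                   # reserved
    assert len(buf) == header_bytes
    buf += digital.tobytes()                          # channel-sequential record
    path.write_bytes(bytes(buf))


def _read_edf(path: Path) -> Recording:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header")

    def sfield(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    patient = sfield(8, 80)
    recording_id = sfield(88, 80)
    n_records = int(sfield(236, 8))
    duration = float(sfield(244, 8))
    ns = int(sfield(252, 4))
    if ns != N_CHANNELS:
        raise ChannelCountError(f"{path}: EDF declares {ns} signals, expected {N_CHANNELS}")
    off = 256
    labels = [sfield(off + 16 * i, 16) for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns  # skip transducer + physical dimension
    phys_min = np.array([float(sfield(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    phys_max = np.array([float(sfield(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    dig_min = np.array([int(sfield(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    dig_max = np.array([int(sfield(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns + 80 * ns
    spr = [int(sfield(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns + 32 * ns
    if len(set(spr)) != 1:
        raise FormatError(f"{path}: heterogeneous samples-per-record unsupported")
    T_rec = spr[0]
    data = np.frombuffer(raw[off:], dtype="<i2")
    if data.size != n_records * ns * T_rec:
        raise FormatError(f"{path}: data section size mismatch")
    data = data.reshape(n_records, ns, T_rec)
    digital = np.concatenate([data[r] for r in range(n_records)], axis=1).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    signals = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    if duration <= 0:
        raise FormatError(f"{path}: nonpositive record duration")
    fs = T_rec / duration

    meta = dict(re.findall(r"(\w+)=(\S+)", recording_id))
    label = None
    if "expression" in meta:
        label = ExpressionLabel(meta["expression"], int(meta["intensity"]))
    channel_map = tuple(lbl.split()[-1] if " " in lbl else lbl for lbl in labels)
    return Recording(
        signals=signals,
        fs=fs,
        label=label,
        subject_id=patient,
        batch_id=meta.get("batch", "B1"),
        channel_map=channel_map,
    )
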