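"""Minimal EDF (European Data Format) reader/writer for Recording objects.

Implements the plain EDF spec (Kemp et al. 1992): a 256-byte fixed header,
256 bytes per signal, then little-endian 16-bit data records.  One data
record spans one second, so each channel stores ``fs`` samples per record
and channels may have different rates (EEG/EMG at 500 Hz, ACT at 200 Hz).

Only what this package needs is supported: continuous recordings, channels
named EEG / EMG / ACT, integer sampling rates.  Values round-trip to within
one quantization step of the channel's physical range.
"""

from __future__ import annotations

import datetime as _dt
import math
import os
from dataclasses import dataclass

import numpy as np

from .recording import Recording

__all__ = ["read_edf", "write_edf", "EdfFormatError"]

_HDR = 256  # bytes, fixed header and per-signal block


class EdfFormatError(ValueError):
    """Raised when a file is not a readable EDF with the expected channels."""


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    # shortest exact-ish ascii representation that fits the field
    for fmt in (f"{value:g}", f"{value:.{max(width - 8, 1)}g}"):
        if len(fmt) <= width:
            return _pad(fmt, width)
    raise ValueError(f"cannot encode {value} in {width} chars")


@dataclass
class _Channel:
    label: str
    fs: int
    data: np.ndarray


def write_edf(rec: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as EDF with channels EEG, EMG and ACT."""
    for name in ("eeg_fs", "emg_fs", "activity_fs"):
        fs = getattr(rec, name)
        if fs != int(fs):
            raise EdfFormatError(f"EDF writer requires integer {name}, got {fs}")
    n_records = int(math.floor(rec.duration_s))
    if n_records < 1:
        raise EdfFormatError("recording shorter than one 1-s data record")

    channels = [
        _Channel("EEG", int(rec.eeg_fs), rec.eeg),
        _Channel("EMG", int(rec.emg_fs), rec.emg),
        _Channel("ACT", int(rec.activity_fs), rec.activity),
    ]

    # physical range: symmetric, padded 1% so extremes stay in digital range
    phys: list[tuple[float, float]] = []
    digitized: list[np.ndarray] = []
    for ch in channels:
        x = ch.data[: n_records * ch.fs]
        lim = float(np.max(np.abs(x))) if x.size else 0.0
        lim = max(lim * 1.01, 1e-6)
        lo, hi = -lim, lim
        scale = 65535 / (hi - lo)
        d = np.clip(np.round((x - lo) * scale) - 32768, -32768, 32767)
        phys.append((lo, hi))
        digitized.append(d.astype("<i2"))

    ns = len(channels)
    start = _dt.datetime(2000, 1, 1) + _dt.timedelta(hours=rec.start_clock_h)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))  # version
        fh.write(_pad(f"subject {rec.subject_id}", 80))
        fh.write(_pad(f"group {rec.group_label or 'none'}", 80))
        fh.write(_pad(start.strftime("%d.%m.%y"), 8))
        fh.write(_pad(start.strftime("%H.%M.%S"), 8))
        fh.write(_pad(str(_HDR * (1 + ns)), 8))
        fh.write(_pad("", 44))  # reserved
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))  # record duration, seconds
        fh.write(_pad(str(ns), 4))

        fh.write(b"".join(_pad(c.label, 16) for c in channels))
        fh.write(b"".join(_pad("telemetry", 80) for _ in channels))
        units = ["uV", "uV", "counts"]
        fh.write(b"".join(_pad(u, 8) for u in units))
        fh.write(b"".join(_num(p[0], 8) for p in phys))
        fh.write(b"".join(_num(p[1], 8) for p in phys))
        fh.write(b"".join(_pad("-32768", 8) for _ in channels))
        fh.write(b"".join(_pad("32767", 8) for _ in channels))
        fh.write(b"".join(_pad("", 80) for _ in channels))  # prefiltering
        fh.write(b"".join(_pad(str(c.fs), 8) for c in channels))
        fh.write(b"".join(_pad("", 32) for _ in channels))  # reserved

        for r in range(n_records):
            for ch, d in zip(channels, digitized):
                fh.write(d[r * ch.fs : (r + 1) * ch.fs].tobytes())


def _read_field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


def read_edf(path: str | os.PathLike) -> Recording:
    """Read an EDF file into a Recording.

    The file must declare EEG and EMG channels; ACT is optional (an all-zero
    activity trace at 200 Hz is substituted when absent).
    """
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise EdfFormatError(f"{path}: truncated or empty EDF header")
        try:
            n_records = int(_read_field(head, 236, 8))
            record_dur = float(_read_field(head, 244, 8))
            ns = int(_read_field(head, 252, 4))
        except ValueError as exc:
            raise EdfFormatError(f"{path}: malformed EDF header") from exc
        time_str = _read_field(head, 176, 8)
        try:
            hh, mm, ss = (int(p) for p in time_str.split("."))
            start_clock_h = hh + mm / 60 + ss / 3600
        except ValueError:
            start_clock_h = 0.0

        sig = fh.read(_HDR * ns)
        if len(sig) < _HDR * ns:
            raise EdfFormatError(f"{path}: truncated signal headers")

        # per-signal blocks in field order
        off = 0
        labels = [_read_field(sig, off + i * 16, 16) for i in range(ns)]
        off += 16 * ns + 80 * ns + 8 * ns  # skip transducer, units
        phys_min = [float(_read_field(sig, off + i * 8, 8)) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(_read_field(sig, off + i * 8, 8)) for i in range(ns)]
        off += 8 * ns
        dig_min = [int(_read_field(sig, off + i * 8, 8)) for i in range(ns)]
        off += 8 * ns
        dig_max = [int(_read_field(sig, off + i * 8, 8)) for i in range(ns)]
        off += 8 * ns + 80 * ns  # skip prefiltering
        nsamp = [int(_read_field(sig, off + i * 8, 8)) for i in range(ns)]

        rec_len = sum(nsamp)
        raw = np.frombuffer(fh.read(2 * rec_len * n_records), dtype="<i2")
        if raw.size < rec_len * n_records:
            raise EdfFormatError(f"{path}: data records truncated")
        raw = raw.reshape(n_records, rec_len)

    traces: dict[str, tuple[np.ndarray, float]] = {}
    pos = 0
    for i in range(ns):
        block = raw[:, pos : pos + nsamp[i]].reshape(-1).astype(np.float64)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        physical = (block - dig_min[i]) * gain + phys_min[i]
        traces[labels[i].upper()] = (physical, nsamp[i] / record_dur)
        pos += nsamp[i]

    for required in ("EEG", "EMG"):
        if required not in traces:
            raise EdfFormatError(f"{path}: missing required channel {required}")
    eeg, eeg_fs = traces["EEG"]
    emg, emg_fs = traces["EMG"]
    if "ACT" in traces:
        act, act_fs = traces["ACT"]
    else:
        act_fs = 200.0
        act = np.zeros(int(round(n_records * record_dur * act_fs)))

    hdr_subject = _read_field(head, 8, 80)
    subject = hdr_subject.split(" ", 1)[1] if " " in hdr_subject else hdr_subject
    hdr_group = _read_field(head, 88, 80)
    group = hdr_group.split(" ", 1)[1] if " " in hdr_group else ""
    if group == "none":
        group = ""

    return Recording(
        eeg=eeg,
        emg=emg,
        activity=act,
        eeg_fs=eeg_fs,
        emg_fs=emg_fs,
        activity_fs=act_fs,
        start_clock_h=start_clock_h % 24.0,
        subject_id=subject or "subject",
        group_label=group,
    )
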