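"""Minimal EDF/EDF+ reader and writer for multichannel PSG recordings.

EDF stores 16-bit samples with per-channel physical scaling and allows each
channel its own samples-per-record count, i.e. its own native sampling rate.
General-purpose readers built on a uniform-rate container (such as MNE's
``RawEDF``) resample low-rate channels up to the fastest channel on load,
which silently discards the native rates this package's preprocessing is
required to honor. This module therefore round-trips the format directly;
its output is cross-checked against ``mne.io.read_raw_edf`` on uniform-rate
files in the test suite.

Only the features the package writes are supported on read: one data-record
duration for the whole file, 16-bit little-endian samples, physical scaling
from the header. Signals whose digital range is degenerate are returned
as zeros.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class EdfSignal:
    label: str
    data: np.ndarray  # float, physical units
    rate: float  # Hz


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii")[:width]
    return raw.ljust(width)


def write_edf(path: str | Path, signals: list[EdfSignal],
              start: datetime.datetime | None = None,
              patient_id: str = "X",
              record_seconds: float = 1.0) -> None:
    """Write signals to an EDF file, one data record per ``record_seconds``.

    Every signal's ``rate * record_seconds`` must be a whole number of
    samples, and all signals must span the same duration.
    """
    if not signals:
        raise ValueError("no signals to write")
    start = start or datetime.datetime(2000, 1, 1, 0, 0, 0)
    durations = {len(s.data) / s.rate for s in signals}
    if len({round(d, 6) for d in durations}) != 1:
        raise ValueError("signals have unequal durations")
    duration = durations.pop()
    n_records = int(round(duration / record_seconds))
    spr = []
    for s in signals:
        n = s.rate * record_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"rate {s.rate} Hz not commensurate with {record_seconds}-s records"
            )
        spr.append(int(round(n)))

    phys_min, phys_max, scaled = [], [], []
    for s in signals:
        lo = float(np.min(s.data)) if len(s.data) else -1.0
        hi = float(np.max(s.data)) if len(s.data) else 1.0
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig = (s.data - lo) / (hi - lo) * (_DIG_MAX - _DIG_MIN) + _DIG_MIN
        scaled.append(np.clip(np.round(dig), _DIG_MIN, _DIG_MAX).astype("<i2"))

    ns = len(signals)
    hdr = b""
    hdr += _field("0", 8)  # version
    hdr += _field(patient_id, 80)
    hdr += _field("Startdate X X X X", 80)
    hdr += _field(start.strftime("%d.%m.%y"), 8)
    hdr += _field(start.strftime("%H.%M.%S"), 8)
    hdr += _field(str(256 * (1 + ns)), 8)
    hdr += _field("EDF+C", 44)
    hdr += _field(str(n_records), 8)
    hdr += _field(f"{record_seconds:g}", 8)
    hdr += _field(str(ns), 4)
    hdr += b"".join(_field(s.label, 16) for s in signals)
    hdr += b"".join(_field("", 80) for _ in signals)  # transducer
    hdr += b"".join(_field("uV", 8) for _ in signals)
    hdr += b"".join(_field(f"{lo:.6g}"[:8], 8) for lo in phys_min)
    hdr += b"".join(_field(f"{hi:.6g}"[:8], 8) for hi in phys_max)
    hdr += b"".join(_field(str(_DIG_MIN), 8) for _ in signals)
    hdr += b"".join(_field(str(_DIG_MAX), 8) for _ in signals)
    hdr += b"".join(_field("", 80) for _ in signals)  # prefiltering
    hdr += b"".join(_field(str(n), 8) for n in spr)
    hdr += b"".join(_field("", 32) for _ in signals)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            for sig, n in zip(scaled, spr):
                fh.write(sig[rec * n : (rec + 1) * n].tobytes())


def read_edf(path: str | Path) -> tuple[list[EdfSignal], datetime.datetime]:
    """Read an EDF file written by :func:`write_edf` (or compatible)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")

    def txt(lo, hi):
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    ns = int(txt(252, 256))
    n_records = int(txt(236, 244))
    record_seconds = float(txt(244, 252))
    date_s, time_s = txt(168, 176), txt(176, 184)
    try:
        start = datetime.datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = datetime.datetime(2000, 1, 1)

    off = 256

    def block(width):
        nonlocal off
        vals = [raw[off + i * width : off + (i + 1) * width].decode("ascii", errors="replace").strip()
                for i in range(ns)]
        off += ns * width
        return vals

    labels = block(16)
    block(80)  # transducer
    block(8)  # dimension
    pmin = [float(v) for v in block(8)]
    pmax = [float(v) for v in block(8)]
    dmin = [int(v) for v in block(8)]
    dmax = [int(v) for v in block(8)]
    block(80)  # prefiltering
    spr = [int(v) for v in block(8)]
    block(32)

    header_bytes = 256 * (1 + ns)
    data = np.frombuffer(raw[header_bytes:], dtype="<i2")
    rec_len = sum(spr)
    if len(data) < n_records * rec_len:
        raise ValueError(f"{path}: data section shorter than header declares")
    data = data[: n_records * rec_len].reshape(n_records, rec_len)

    signals = []
    col = 0
    for i in range(ns):
        dig = data[:, col : col + spr[i]].reshape(-1).astype(np.float64)
        col += spr[i]
        drange = dmax[i] - dmin[i]
        if drange <= 0:
            phys = np.zeros_like(dig)
        else:
            phys = pmin[i] + (dig - dmin[i]) * (pmax[i] - pmin[i]) / drange
        signals.append(EdfSignal(labels[i], phys, spr[i] / record_seconds))
    return signals, start
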