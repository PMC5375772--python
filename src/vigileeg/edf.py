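"""Minimal EDF (European Data Format) reader and writer.

Covers the subset of EDF this package produces and consumes: uniform-rate
signals, one-second data records, 16-bit samples with linear physical
(µV) scaling. The format is a fixed-layout ASCII header (256 bytes plus
256 per signal) followed by little-endian int16 data records, signal-major
within each record.

Round trips are exact to the 16-bit quantisation step of the declared
physical range.
"""

from __future__ import annotations

import datetime as _dt
from typing import List, Optional, Sequence, Tuple

import numpy as np

_HDR = 256
_SIG_HDR = 256


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path,
    data: np.ndarray,
    fs: int,
    channel_labels: Sequence[str],
    physical_dim: str = "uV",
    patient: str = "X",
    recording_id: str = "vigileeg",
    start: Optional[_dt.datetime] = None,
) -> None:
    """Write (n_channels, n_samples) µV data as 16-bit EDF.

    Data are truncated to whole one-second records. Each channel gets a
    symmetric physical range covering its extremes; digital range is the
    full int16 span.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ns = len(channel_labels)
    if data.shape[0] != ns:
        raise ValueError("one label per channel required")
    n_records = data.shape[1] // fs
    if n_records < 1:
        raise ValueError("need at least one full second of data")
    data = data[:, : n_records * fs]
    start = start or _dt.datetime(2000, 1, 1)

    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _field("0", 8),
        _field(patient, 80),
        _field(recording_id, 80),
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(str(_HDR + ns * _SIG_HDR), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),                      # record duration: 1 s
        _field(str(ns), 4),
    ])

    header += b"".join([
        sig_fields_w(channel_labels, 16),
        sig_fields_const("", 80, ns),
        sig_fields_const(physical_dim, 8, ns),
        b"".join(_field(_num(-phys_max[i]), 8) for i in range(ns)),
        b"".join(_field(_num(phys_max[i]), 8) for i in range(ns)),
        sig_fields_const(str(dig_min), 8, ns),
        sig_fields_const(str(dig_max), 8, ns),
        sig_fields_const("HP:3Hz LP:100Hz", 80, ns),
        sig_fields_const(str(fs), 8, ns),
        sig_fields_const("", 32, ns),
    ])

    # physical -> digital, per channel
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(
        np.rint((data + phys_max[:, None]) * scale[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(chunk.tobytes())


def sig_fields_w(values: Sequence[str], width: int) -> bytes:
    return b"".join(_field(v, width) for v in values)


def sig_fields_const(value: str, width: int, ns: int) -> bytes:
    return b"".join(_field(value, width) for _ in range(ns))


def _num(x: float) -> str:
    s = f"{x:.6g}"
    return s[:8]


def read_edf(path) -> Tuple[np.ndarray, int, List[str], dict]:
    """Read a uniform-rate EDF file.

    Returns (data µV array of shape (n_channels, n_samples), fs,
    channel labels, header metadata dict). Requires all signals to share one
    sampling rate and a one-second-compatible record duration.
    """
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise ValueError("truncated EDF header")

        def txt(b: bytes) -> str:
            return b.decode("ascii", "replace").strip()

        n_records = int(txt(head[236:244]))
        record_dur = float(txt(head[244:252]))
        ns = int(txt(head[252:256]))
        if ns <= 0 or record_dur <= 0:
            raise ValueError("malformed EDF header")

        sig_head = fh.read(ns * _SIG_HDR)

        # per-signal columns are stored field-major
        off = 0
        labels = [txt(sig_head[off + i * 16 : off + (i + 1) * 16]) for i in range(ns)]
        off += 16 * ns + 80 * ns            # skip transducer
        phys_dim = [txt(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        phys_min = [float(txt(sig_head[off + i * 8 : off + (i + 1) * 8])) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(txt(sig_head[off + i * 8 : off + (i + 1) * 8])) for i in range(ns)]
        off += 8 * ns
        dig_min = [int(txt(sig_head[off + i * 8 : off + (i + 1) * 8])) for i in range(ns)]
        off += 8 * ns
        dig_max = [int(txt(sig_head[off + i * 8 : off + (i + 1) * 8])) for i in range(ns)]
        off += 8 * ns + 80 * ns             # skip prefiltering
        spr = [int(txt(sig_head[off + i * 8 : off + (i + 1) * 8])) for i in range(ns)]

        rates = {s / record_dur for s in spr}
        if len(rates) != 1:
            raise ValueError("mixed sampling rates not supported")
        fs = rates.pop()
        if fs <= 0 or abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"unsupported sampling rate {fs}")
        fs = int(round(fs))

        for dim in phys_dim:
            if dim not in ("uV", "µV", ""):
                raise ValueError(
                    f"expected µV physical dimension, got {dim!r}"
                )

        raw = np.frombuffer(fh.read(), dtype="<i2")

    expected = n_records * sum(spr)
    if len(raw) < expected:
        raise ValueError("truncated EDF data")
    raw = raw[:expected]

    data = np.empty((ns, n_records * spr[0]))
    per_rec = sum(spr)
    for i in range(ns):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        # gather signal i across records
        sig_i = np.concatenate([
            raw[r * per_rec + sum(spr[:i]) : r * per_rec + sum(spr[: i + 1])]
            for r in range(n_records)
        ]).astype(float)
        data[i] = (sig_i - dig_min[i]) * gain + phys_min[i]

    meta = {"n_records": n_records, "record_duration": record_dur}
    return data, fs, labels, meta
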