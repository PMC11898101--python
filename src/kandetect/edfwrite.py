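"""Minimal EDF+ writer for synthetic fixtures.

Writes continuous EDF+ ("EDF+C") files: 16-bit samples with per-channel
physical scaling, 1-second data records, and a TAL annotation channel
carrying the seizure intervals.  Only what the synthetic generator needs is
implemented; reading is done with ``mne.io.read_raw_edf``, which serves as an
independent check that the files are well-formed.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "write_annotations_csv"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width} bytes")
    return b.ljust(width)


def _num8(v: float) -> str:
    """Shortest decimal rendering of ``v`` that fits an 8-byte header field."""
    for prec in range(7, -1, -1):
        s = f"{v:.{prec}f}".rstrip("0").rstrip(".") if prec else f"{v:.0f}"
        if len(s) <= 8:
            return s
    raise ValueError(f"physical range value {v} does not fit an EDF header field")


def _tal(onset: float, duration: float | None = None, text: str = "") -> bytes:
    s = f"+{onset:.3f}".rstrip("0").rstrip(".")
    if duration is not None:
        d = f"{duration:.3f}".rstrip("0").rstrip(".")
        s += f"\x15{d}"
    s += f"\x14{text}\x14\x00"
    return s.encode("ascii")


def write_edf(rec, path) -> None:
    """Write an :class:`~kandetect.preprocess.EEGRecording` as EDF+C.

    The recording is zero-padded to a whole number of seconds; annotations
    are stored as TALs ("seizure" descriptions) in the record containing
    their onset, with millisecond precision.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = int(math.ceil(rec.n_samples / fs))
    n_ch = rec.n_channels

    sig = np.zeros((n_ch, n_records * fs))
    sig[:, : rec.n_samples] = rec.signals

    # physical scaling per channel (guard against flat channels); the range is
    # rounded outward so the header's decimal rendering is exact
    pmin = sig.min(axis=1)
    pmax = sig.max(axis=1)
    small = np.maximum(np.abs(pmin), np.abs(pmax)) < 9999
    pmin = np.where(small, np.floor(pmin * 1000) / 1000, np.floor(pmin))
    pmax = np.where(small, np.ceil(pmax * 1000) / 1000, np.ceil(pmax))
    flat = (pmax - pmin) <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    digital = np.round(
        (sig - pmin[:, None]) / (pmax - pmin)[:, None] * (_DIG_MAX - _DIG_MIN) + _DIG_MIN
    ).astype("<i2")

    # TALs per record: timestamp first, then annotations with onset in-record
    tals: list[bytes] = []
    for r in range(n_records):
        chunk = _tal(float(r))
        for onset, offset, label in rec.annotations:
            if r <= onset < r + 1:
                chunk += _tal(onset, offset - onset, str(label))
        tals.append(chunk)
    ann_bytes = max(64, max(len(t) for t in tals))
    ann_samples = (ann_bytes + 1) // 2 + 1  # 2 bytes per 'sample', slack for padding

    labels = [f"EEG {name}" for name in rec.channel_names] + ["EDF Annotations"]
    ns = n_ch + 1
    header = b""
    header += _field("0", 8)
    header += _field("X X X X", 80)
    header += _field("Startdate 01-JAN-2026 X X X", 80)
    header += _field("01.01.26", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (ns + 1)), 8)
    header += _field("EDF+C", 44)
    header += _field(str(n_records), 8)
    header += _field("1", 8)
    header += _field(str(ns), 4)

    def per_signal(values: list[str], width: int) -> bytes:
        return b"".join(_field(v, width) for v in values)

    header += per_signal(labels, 16)
    header += per_signal([""] * ns, 80)  # transducer
    header += per_signal(["uV"] * n_ch + [""], 8)  # physical dimension
    header += per_signal([_num8(v) for v in pmin] + ["-1"], 8)
    header += per_signal([_num8(v) for v in pmax] + ["1"], 8)
    header += per_signal([str(_DIG_MIN)] * ns, 8)
    header += per_signal([str(_DIG_MAX)] * ns, 8)
    header += per_signal([""] * ns, 80)  # prefiltering
    header += per_signal([str(fs)] * n_ch + [str(ann_samples)], 8)
    header += per_signal([""] * ns, 32)  # reserved

    with open(Path(path), "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            fh.write(tals[r].ljust(2 * ann_samples, b"\x00"))


def write_annotations_csv(annotations, path) -> None:
    """Sidecar CSV with columns onset_s, offset_s, label."""
    lines = ["onset_s,offset_s,label"]
    for onset, offset, label in annotations:
        lines.append(f"{onset:.3f},{offset:.3f},{label}")
    Path(path).write_text("\n".join(lines) + "\n")
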