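"""Minimal EDF (European Data Format) writer.

Writes 16-bit EDF files with one data record per second and physical units
of microvolts — sufficient for round-tripping synthetic polysomnography
through standard readers (e.g. ``mne.io.read_raw_edf``).  The sample rate
must be an integer so each record holds a whole number of samples.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np

__all__ = ["write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    channels: dict[str, np.ndarray],
    sample_rate: float,
    start: datetime | None = None,
    patient_id: str = "X X X X",
) -> Path:
    """Write ``channels`` (label -> uV series) to an EDF file.

    Signals are truncated to a whole number of 1-s records.  Each channel is
    scaled to the 16-bit digital range using a symmetric physical range, so
    quantization error is at most ``max|x| / 32767``.
    """
    path = Path(path)
    fs = int(round(sample_rate))
    if abs(fs - sample_rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    if not channels:
        raise ValueError("no channels to write")
    labels = list(channels)
    n_samples = min(len(channels[lb]) for lb in labels)
    n_records = n_samples // fs
    if n_records < 1:
        raise ValueError("signal shorter than one 1-s data record")
    start = start or datetime(2000, 1, 1, 23, 0, 0)

    phys_ranges = {}
    digital = {}
    for lb in labels:
        x = np.asarray(channels[lb], float)[: n_records * fs]
        amp = max(float(np.max(np.abs(x))), 1e-6)
        phys_ranges[lb] = amp
        digital[lb] = np.clip(
            np.round(x / amp * _DIG_MAX), _DIG_MIN, _DIG_MAX
        ).astype("<i2")

    ns = len(labels)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field("Startdate X X X X", 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    sig_fields = [
        ("label", 16, labels),
        ("transducer", 80, [""] * ns),
        ("dim", 8, ["uV"] * ns),
        ("phys_min", 8, [f"{-phys_ranges[lb]:.1f}" for lb in labels]),
        ("phys_max", 8, [f"{phys_ranges[lb]:.1f}" for lb in labels]),
        ("dig_min", 8, [str(_DIG_MIN)] * ns),
        ("dig_max", 8, [str(_DIG_MAX)] * ns),
        ("prefilter", 80, [""] * ns),
        ("n_per_record", 8, [str(fs)] * ns),
        ("reserved", 32, [""] * ns),
    ]
    for _, width, values in sig_fields:
        header += b"".join(_field(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for lb in labels:
                fh.write(digital[lb][rec * fs : (rec + 1) * fs].tobytes())
    return path
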