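"""Minimal EDF (European Data Format) writing for synthetic recordings.

Writes standard 16-bit EDF with per-channel physical scaling and 1 s data
records, which any EDF reader (e.g. MNE-Python) can open.  Annotations are
deliberately kept out of the EDF container and written as a CSV sidecar by
the CLI, since EDF+ annotation support varies widely across readers.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .synthetic import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numerics to fit the fixed-width ASCII field
        s = f"{float(value):.{max(width - 7, 1)}g}" if not isinstance(value, str) else s[:width]
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path, *, records_per_block_s: float = 1.0) -> Path:
    """Write ``recording`` (microvolts) to ``path`` as 16-bit EDF.

    The signal is truncated to a whole number of data records.  Physical
    min/max are set per channel from the data (symmetric), so quantization
    error is bounded by (2 * max|x|) / 65535 per channel.
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs * records_per_block_s))
    if abs(spr - fs * records_per_block_s) > 1e-9:
        raise ValueError("sampling_rate * record duration must be an integer")
    n_ch, n_samp = recording.signal.shape
    n_records = n_samp // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")

    sig = recording.signal[:, : n_records * spr]
    phys_max = np.maximum(np.abs(sig).max(axis=1), 1e-3)
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(
        np.round((sig - phys_min[:, None]) * scale[:, None]) + _DIG_MIN,
        _DIG_MIN,
        _DIG_MAX,
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(recording.patient_id, 80),
            _field("synthetic EEG", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(256 + 256 * n_ch, 8),
            _field("", 44),
            _field(n_records, 8),
            _field(f"{records_per_block_s:g}", 8),
            _field(n_ch, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_field(f"EEG {ch}", 16) for ch in recording.channel_labels),
            b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(_field(_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_field(_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(spr, 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # records: per record, each channel's spr samples contiguously
        blocks = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())
    return path
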