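"""Minimal EDF (European Data Format) interchange layer.

Reading goes through MNE's EDF reader. Writing uses a small purpose-built
16-bit EDF writer: it emits a single data record holding the whole signal,
with per-channel physical scaling, which is sufficient for fixtures and for
exporting simulated recordings. Amplitudes are quantized to the 16-bit
digital range, so a round trip is exact only to the per-channel resolution
(physical range / 65535).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .eeg import Recording
from .errors import FormatError, ValidationError


def _fit8(value: float) -> str:
    """Format a float into at most 8 ASCII characters (EDF numeric field)."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise FormatError(f"cannot represent {value} in an 8-character EDF field")


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording (microvolts) as a plain 16-bit EDF file."""
    path = Path(path)
    data = np.asarray(rec.samples, dtype=float)
    n_ch, n_samp = data.shape
    record_duration = n_samp / rec.fs

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs <= pmins
    pmaxs = np.where(flat, pmins + 1.0, pmaxs)
    dmin, dmax = -32768, 32767

    header = b""
    header += _field("0", 8)  # version
    header += _field("X X X X", 80)  # patient id (anonymous)
    header += _field("Startdate X saegbls", 80)  # recording id
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (n_ch + 1)), 8)
    header += _field("", 44)
    header += _field("1", 8)  # one data record
    header += _field(_fit8(record_duration), 8)
    header += _field(str(n_ch), 4)

    def per_channel(fn, width):
        return b"".join(_field(fn(i), width) for i in range(n_ch))

    header += per_channel(lambda i: rec.channel_names[i], 16)
    header += per_channel(lambda i: "", 80)  # transducer
    header += per_channel(lambda i: "uV", 8)
    header += per_channel(lambda i: _fit8(pmins[i]), 8)
    header += per_channel(lambda i: _fit8(pmaxs[i]), 8)
    header += per_channel(lambda i: str(dmin), 8)
    header += per_channel(lambda i: str(dmax), 8)
    header += per_channel(lambda i: "", 80)  # prefiltering
    header += per_channel(lambda i: str(n_samp), 8)
    header += per_channel(lambda i: "", 32)

    # header fields are parsed back, so scale with the stored (possibly
    # truncated) physical limits rather than the exact data extrema
    pmins_h = np.array([float(_fit8(v)) for v in pmins])
    pmaxs_h = np.array([float(_fit8(v)) for v in pmaxs])
    gain = (dmax - dmin) / (pmaxs_h - pmins_h)
    digital = np.rint((data - pmins_h[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())  # channel-sequential within the record


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via MNE and return samples in microvolts."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE scales EEG-like channels to volts
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        annotations=[],
    )
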