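"""EEG segment containers and EDF / catalog input-output.

Recordings travel as :class:`EegSegment` (channels x samples, µV).  Files are
European Data Format (EDF): reading goes through :func:`mne.io.read_raw_edf`;
writing uses a minimal 16-bit EDF writer implemented here, sufficient for
fixed-rate multichannel signals with whole-second duration.  Segment catalogs
are CSV files with columns ``file_path, start_s, duration_s, label``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    BoundsError,
    ChannelError,
    ConfigurationError,
    RateMismatchError,
    SizeError,
)

logger = logging.getLogger("epitensor")

#: inter-ictal / pre-ictal class labels
INTERICTAL, PREICTAL = 1, 2


@dataclass
class EegSegment:
    """A channels x samples block of EEG with its sampling rate.

    ``data`` is in microvolts.  ``label`` is 1 (inter-ictal), 2 (pre-ictal)
    or ``None``; ``band`` tags which frequency band the data represent.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    label: int | None = None
    band: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("segment data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if self.label is not None and self.label not in (INTERICTAL, PREICTAL):
            raise ValueError("label must be 1 (inter-ictal) or 2 (pre-ictal)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, band: str | None = None) -> "EegSegment":
        return replace(self, data=data, band=self.band if band is None else band)


@dataclass(frozen=True)
class SegmentRecord:
    """One catalog row: where a labeled segment lives inside an EDF file."""

    file_path: str
    channel_names: tuple[str, ...]
    start_s: float
    duration_s: float
    label: int

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.label not in (INTERICTAL, PREICTAL):
            raise ValueError("label must be 1 or 2")


# ---------------------------------------------------------------------------
# EDF writing (16-bit, one-second data records)
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _format_phys(v: float) -> str:
    """Format a physical min/max into <= 8 ASCII characters."""
    for fmt in (".6g", ".5g", ".4g", ".3g", ".2g"):
        s = format(float(v), fmt)
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {v} into an EDF header field")


def write_edf(segment: EegSegment, path: str | Path) -> Path:
    """Write ``segment`` (µV) to ``path`` as a 16-bit EDF file.

    The segment must contain a whole number of seconds at an integer
    sampling rate (data records are one second long).  Values are scaled
    per channel to the full 16-bit digital range, so the quantization step
    is ``(max - min) / 65535`` per channel.
    """
    path = Path(path)
    data = segment.data
    if not np.isfinite(data).all():
        raise ValueError("segment contains non-finite samples")
    fs = segment.fs
    if fs <= 0 or fs != int(fs):
        raise SizeError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(fs)  # samples per one-second record
    if segment.n_samples % spr != 0:
        raise SizeError("EDF writer requires a whole number of seconds of data")
    n_records = segment.n_samples // spr
    if n_records < 1:
        raise SizeError("segment shorter than one EDF data record (1 s)")
    n_sig = segment.n_channels

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    pmin_s = [_format_phys(v) for v in phys_min]
    pmax_s = [_format_phys(v) for v in phys_max]
    # quantize against the header values actually written
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])
    pmax = np.where(pmax <= pmin, pmin + 1.0, pmax)
    cal = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.rint((data - pmin[:, None]) / cal[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate 01-JAN-2000 X X X", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + n_sig), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(n_sig, 4),
        ]
    )
    sig_fields = [
        (16, [f"EEG {name}" for name in segment.channel_names]),
        (80, [""] * n_sig),
        (8, ["uV"] * n_sig),
        (8, pmin_s),
        (8, pmax_s),
        (8, [str(_DIG_MIN)] * n_sig),
        (8, [str(_DIG_MAX)] * n_sig),
        (80, [""] * n_sig),
        (8, [str(spr)] * n_sig),
        (32, [""] * n_sig),
    ]
    sig_header = b"".join(
        _ascii_field(v, width) for width, values in sig_fields for v in values
    )
    # records: for each second, each channel's samples contiguously
    records = digital.reshape(n_sig, n_records, spr).transpose(1, 0, 2)
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(sig_header)
            fh.write(np.ascontiguousarray(records).tobytes())
    except OSError as exc:
        raise OSError(f"cannot write EDF file {path}: {exc}") from exc
    logger.info("wrote EDF %s: %d ch x %d s at %d Hz", path, n_sig, n_records, spr)
    return path


# ---------------------------------------------------------------------------
# EDF reading (via mne)
# ---------------------------------------------------------------------------


def read_segment(record: SegmentRecord, fs: float | None = None) -> EegSegment:
    """Read one catalog record from its EDF file.

    Returns the channels in ``record.channel_names`` order, trimmed to
    ``[start_s, start_s + duration_s)``, in µV.  Raises
    :class:`ChannelError` for a missing channel, :class:`RateMismatchError`
    when ``fs`` is given and differs from the file's rate, and
    :class:`BoundsError` when the requested range runs past the recording.
    """
    import mne

    raw = mne.io.read_raw_edf(record.file_path, preload=False, verbose="error")
    file_fs = float(raw.info["sfreq"])
    if fs is not None and abs(file_fs - fs) > 1e-9:
        raise RateMismatchError(
            f"{record.file_path}: sampling rate {file_fs} Hz, expected {fs} Hz"
        )
    # the writer prefixes labels with "EEG "; accept either form
    available = {name: name for name in raw.ch_names}
    available.update({name.removeprefix("EEG ").strip(): name for name in raw.ch_names})
    try:
        picks = [available[name] for name in record.channel_names]
    except KeyError as exc:
        raise ChannelError(
            f"{record.file_path}: channel {exc.args[0]!r} not in file"
        ) from None
    start = int(round(record.start_s * file_fs))
    stop = start + int(round(record.duration_s * file_fs))
    if start < 0 or stop > raw.n_times:
        raise BoundsError(
            f"{record.file_path}: samples [{start}, {stop}) outside recording "
            f"of {raw.n_times} samples"
        )
    data = raw.get_data(picks=picks, start=start, stop=stop, units="uV")
    return EegSegment(
        data=data,
        fs=file_fs,
        channel_names=tuple(record.channel_names),
        label=record.label,
    )


# ---------------------------------------------------------------------------
# Catalogs
# ---------------------------------------------------------------------------


def write_catalog(records: list[SegmentRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "file_path": [r.file_path for r in records],
            "start_s": [r.start_s for r in records],
            "duration_s": [r.duration_s for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, index=False)
    return path


def read_catalog(path: str | Path, channel_names: tuple[str, ...]) -> list[SegmentRecord]:
    """Load a catalog CSV; every record gets the configured channel list."""
    df = pd.read_csv(path)
    required = {"file_path", "start_s", "duration_s", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"catalog {path} missing columns {sorted(missing)}")
    return [
        SegmentRecord(
            file_path=str(row.file_path),
            channel_names=tuple(channel_names),
            start_s=float(row.start_s),
            duration_s=float(row.duration_s),
            label=int(row.label),
        )
        for row in df.itertuples()
    ]
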