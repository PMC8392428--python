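"""Synthetic multichannel EEG with controllable inter-channel coupling.

Each segment is a linear mixture of a few band-limited latent oscillators
plus independent channel noise:

    x_c(t) = kappa(t) * sum_s m[c, s] * source_s(t) + noise_sd * eta_c(t)

Every source is a unit-variance sinusoid at its band center (random phase)
plus narrowband filtered noise around it, so frequency-band filtering
isolates distinct sources.  The mixing weights ``m`` are drawn once per
segment; the coupling gain ``kappa(t)`` equals ``coupling_strength`` and,
when ``drift_rate`` is nonzero, drifts linearly in time (clipped to [0, 1])
— the pre-ictal class is modeled as strong coupling that drifts, the
inter-ictal class as weak stationary coupling.  Amplitudes are scaled to a
±100 µV range before EDF writing so 16-bit quantization behaves as for
real scalp EEG.

None of this is physiologically realistic beyond band placement and
coupling structure; it exists so every pipeline stage is testable without
clinical recordings.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import DEFAULT_CHANNELS, SizeError
from .edf import EegSegment, SegmentRecord, write_catalog, write_edf

logger = logging.getLogger("epitensor")


@dataclass(frozen=True)
class CouplingSpec:
    """Statistical structure of one segment class.

    ``band_centers`` places one latent oscillator per listed frequency;
    ``coupling_strength`` in [0, 1] scales the shared-source mixture;
    ``drift_rate`` (per second) moves the coupling gain linearly over the
    segment; ``noise_sd`` scales the independent per-channel noise.
    """

    n_channels: int = 23
    fs: float = 256.0
    n_sources: int = 5
    band_centers: tuple[float, ...] = (2.0, 6.0, 11.0, 22.0, 45.0)
    coupling_strength: float = 0.5
    drift_rate: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.band_centers) != self.n_sources:
            raise ValueError("need one band center per source")
        if any(not 0 < f < self.fs / 2 for f in self.band_centers):
            raise ValueError("band centers must lie in (0, fs/2)")


def _narrowband_noise(rng, n: int, fs: float, center: float) -> np.ndarray:
    """White noise FFT-filtered to ±max(1 Hz, 15% of center) around center."""
    half_bw = max(1.0, 0.15 * center)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = (freqs >= center - half_bw) & (freqs <= center + half_bw)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=n)


def _sources(rng, spec: CouplingSpec, n: int) -> np.ndarray:
    """n_sources x n matrix of unit-variance band-limited oscillators."""
    t = np.arange(n) / spec.fs
    out = np.empty((spec.n_sources, n))
    for s, f in enumerate(spec.band_centers):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.sin(2.0 * np.pi * f * t + phase)
        noise = _narrowband_noise(rng, n, spec.fs, f)
        src = wave + 0.5 * noise
        out[s] = src / src.std()
    return out


def generate_segment(
    spec: CouplingSpec, duration_s: float, label: int | None = None
) -> EegSegment:
    """One labeled segment of ``duration_s`` seconds under ``spec``.

    Deterministic given the spec (including its seed).  Raises
    :class:`SizeError` for durations under one 8-s analysis window.
    """
    if duration_s < 8.0:
        raise SizeError("segment must cover at least one 8-s window")
    n = int(round(duration_s * spec.fs))
    rng = np.random.default_rng(spec.seed)
    sources = _sources(rng, spec, n)
    # nonnegative unit-norm mixing rows around uniform loading: coupling is
    # broad (every channel loads positively on every source, with modest
    # per-segment jitter) and the shared-signal variance per channel is
    # kappa^2 exactly, so coupling_strength means the same thing in every
    # segment and the coupled subnetwork is not a per-segment lottery
    mixing = np.clip(
        1.0 + 0.3 * rng.standard_normal((spec.n_channels, spec.n_sources)),
        0.1,
        None,
    )
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    t = np.arange(n) / spec.fs
    kappa = np.clip(spec.coupling_strength + spec.drift_rate * t, 0.0, 1.0)
    shared = mixing @ sources
    noise = rng.standard_normal((spec.n_channels, n))
    data = kappa[None, :] * shared + spec.noise_sd * noise
    data *= 100.0 / np.abs(data).max()  # ±100 µV before EDF quantization
    names = (
        DEFAULT_CHANNELS
        if spec.n_channels == len(DEFAULT_CHANNELS)
        else tuple(f"CH{i:02d}" for i in range(1, spec.n_channels + 1))
    )
    return EegSegment(data=data, fs=spec.fs, channel_names=names, label=label)


def generate_catalog(
    n_per_class: int,
    spec_inter: CouplingSpec,
    spec_pre: CouplingSpec,
    duration_s: float,
    out_dir: str | Path,
    master_seed: int = 0,
) -> list[SegmentRecord]:
    """Write a balanced catalog of EDF segments and its catalog CSV.

    Produces ``n_per_class`` inter-ictal (label 1) then ``n_per_class``
    pre-ictal (label 2) recordings; each segment's seed derives
    deterministically from ``master_seed``.  Returns the catalog records
    (also written to ``out_dir/catalog.csv``).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[SegmentRecord] = []
    jobs = [(spec_inter, 1, i) for i in range(n_per_class)] + [
        (spec_pre, 2, i) for i in range(n_per_class)
    ]
    for k, (spec, label, i) in enumerate(jobs):
        seg_seed = (master_seed * 100003 + k * 9973 + 17) % (2**31)
        seg = generate_segment(
            dataclasses.replace(spec, seed=seg_seed), duration_s, label
        )
        path = out_dir / f"segment_{k:03d}_label{label}.edf"
        write_edf(seg, path)
        records.append(
            SegmentRecord(
                file_path=str(path),
                channel_names=seg.channel_names,
                start_s=0.0,
                duration_s=duration_s,
                label=label,
            )
        )
    write_catalog(records, out_dir / "catalog.csv")
    logger.info(
        "wrote %d synthetic segments (%.0f s each) to %s",
        len(records),
        duration_s,
        out_dir,
    )
    return records
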