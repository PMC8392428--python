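"""Frequency-band splitting with a Fourier-transform (bin-zeroing) filter.

Each channel is taken to the frequency domain with an FFT, every bin whose
frequency lies outside the band is zeroed, and the signal is transformed
back.  This brick-wall filter has exactly zero phase distortion and removes
energy only (Parseval), at the cost of edge ringing — acceptable here
because downstream features are windowed correlations, not waveforms.

Shared band edges (e.g. 15 Hz between alpha and beta) are assigned to the
lower band: bands are half-open ``[f_lo, f_hi)`` except the topmost (gamma),
which is closed above, so the five bands partition 0.5-60 Hz without double
counting.  The DC bin is excluded from every filtered band.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import BANDS, BandDefinition, ConfigurationError
from .edf import EegSegment

logger = logging.getLogger("epitensor")


def fft_bandpass(segment: EegSegment, band: BandDefinition) -> EegSegment:
    """Band-limit every channel of ``segment`` to ``band`` by FFT bin zeroing.

    ``raw`` returns the segment unchanged (a copy).  Raises
    :class:`ConfigurationError` when ``f_hi`` exceeds the Nyquist frequency.
    """
    if band.is_raw:
        return segment.with_data(segment.data.copy(), band="raw")
    if segment.n_samples < 2:
        raise ConfigurationError("segment must have at least 2 samples")
    if band.f_hi > segment.fs / 2:
        raise ConfigurationError(
            f"band {band.name}: f_hi={band.f_hi} Hz exceeds Nyquist "
            f"{segment.fs / 2} Hz"
        )
    n = segment.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / segment.fs)
    if band.closed_upper:
        keep = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    else:
        keep = (freqs >= band.f_lo) & (freqs < band.f_hi)
    spectrum = np.fft.rfft(segment.data, axis=1)
    spectrum[:, ~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=n, axis=1)
    return segment.with_data(filtered, band=band.name)


def split_bands(segment: EegSegment) -> dict[str, EegSegment]:
    """Return the five filtered bands plus the unfiltered signal.

    Keys: ``raw, delta, theta, alpha_band, beta, gamma``.
    """
    out = {name: fft_bandpass(segment, band) for name, band in BANDS.items()}
    logger.info(
        "split %d-channel segment (%.1f s) into %d bands",
        segment.n_channels,
        segment.duration_s,
        len(out),
    )
    return out
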