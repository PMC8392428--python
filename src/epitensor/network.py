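"""Functional brain networks from windowed, thresholded Pearson correlation.

A band-limited segment is cut into semi-overlapping windows (8 s long,
4-s step by default).  Each window yields a channels x channels Pearson
correlation matrix, which is binarized against a statistical significance
threshold

    Th = 1 - (1 - alpha)^(1 / (L - 1))

where ``alpha`` is the confidence level and ``L`` the number of disjoint
window sections of the recording.  The result is one symmetric binary
adjacency matrix (zero diagonal) per window: a functional brain network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, SizeError
from .edf import EegSegment

logger = logging.getLogger("epitensor")


@dataclass(frozen=True)
class Window:
    """One sliding-window slice of a segment."""

    data: np.ndarray  # channels x samples
    index: int
    start_s: float


def sliding_windows(
    segment: EegSegment, window_s: float = 8.0, step_s: float = 4.0
) -> list[Window]:
    """Cut ``segment`` into windows of ``window_s`` at ``step_s`` steps.

    Windows start at 0, step_s, 2*step_s, ...; trailing samples that do not
    fill a whole window are dropped.  Raises :class:`SizeError` when the
    segment is shorter than one window.
    """
    w = int(round(window_s * segment.fs))
    s = int(round(step_s * segment.fs))
    n = segment.n_samples
    if n < w:
        raise SizeError(
            f"segment of {n} samples shorter than one {w}-sample window"
        )
    count = (n - w) // s + 1
    return [
        Window(
            data=segment.data[:, i * s : i * s + w],
            index=i,
            start_s=i * step_s,
        )
        for i in range(count)
    ]


def correlation_matrix(window: Window) -> np.ndarray:
    """Pearson correlation between all channel pairs of one window.

    Zero-variance (flat) channels get correlation 0 with every other
    channel instead of raising, so artifact-flat channels simply become
    isolated nodes; the diagonal is 1 throughout.
    """
    data = window.data
    sd = data.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.info(
            "window %d: %d zero-variance channel(s); correlations set to 0",
            window.index,
            int(flat.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def significance_threshold(alpha: float = 0.95, L: int = 337) -> float:
    """Significance threshold ``Th = 1 - (1 - alpha)^(1/(L-1))``."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if L < 2:
        raise ConfigurationError("L must be an integer >= 2")
    return 1.0 - (1.0 - alpha) ** (1.0 / (L - 1))


def binarize(corr: np.ndarray, th: float, rule: str = "abs") -> np.ndarray:
    """Threshold a correlation matrix into a binary adjacency matrix.

    With ``rule="abs"`` (default) an edge is present when ``|r| > th``, so
    strong negative coupling also counts as a connection; ``rule="signed"``
    keeps the literal ``r > th``.  The diagonal is forced to zero.
    """
    corr = np.asarray(corr, dtype=float)
    if not 0 < th < 1:
        raise ConfigurationError("threshold must lie in (0, 1)")
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.abs(corr - corr.T).max() > 1e-9:
        raise ValueError("correlation matrix is not symmetric")
    if rule == "abs":
        adj = (np.abs(corr) > th).astype(np.int8)
    elif rule == "signed":
        adj = (corr > th).astype(np.int8)
    else:
        raise ConfigurationError("rule must be 'abs' or 'signed'")
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)  # symmetric by construction for both rules
    validate_adjacency(adj)
    return adj


def validate_adjacency(adj: np.ndarray) -> None:
    """Assert the adjacency-matrix invariants (binary, symmetric, hollow)."""
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency matrix must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency matrix must have a zero diagonal")
    if not np.isin(adj, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")


def adjacency_series(
    segment: EegSegment,
    window_s: float = 8.0,
    step_s: float = 4.0,
    alpha: float = 0.95,
    L: int = 337,
    rule: str = "abs",
) -> list[np.ndarray]:
    """Windows -> correlation -> binarization for a whole segment."""
    th = significance_threshold(alpha, L)
    windows = sliding_windows(segment, window_s, step_s)
    series = [binarize(correlation_matrix(w), th, rule) for w in windows]
    logger.info(
        "segment (band=%s, label=%s): %d windows -> %d networks at Th=%.4f",
        segment.band,
        segment.label,
        len(windows),
        len(series),
        th,
    )
    return series
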