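"""Baseline node metrics of binary networks: degree and clustering coefficient.

These are the per-node features the tensor-decomposition features are
compared against.  For node i of a binary adjacency matrix ``a``:

    D_i = sum_j a_ij                         (degree)
    C_i = 2 E_i / (k_i (k_i - 1))            (clustering coefficient)

with k_i = D_i and E_i the number of edges among i's neighbors.  Nodes
with k_i <= 1 get C_i = 0 (the formula is undefined there).
"""

from __future__ import annotations

import numpy as np

from .network import validate_adjacency


def degree(adj: np.ndarray) -> np.ndarray:
    """Per-node neighbor count (length-J float vector)."""
    validate_adjacency(adj)
    return adj.sum(axis=1).astype(float)


def clustering(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering coefficient, in [0, 1].

    E_i is half the i-th diagonal entry of A^3 (closed triangles through i).
    """
    validate_adjacency(adj)
    a = adj.astype(float)
    k = a.sum(axis=1)
    triangles2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 * E_i
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles2 / denom, 0.0)
    return c


def metric_features(adj_series: list[np.ndarray], metric: str) -> np.ndarray:
    """One length-J node-metric row per window, rows aligned with windows.

    ``metric`` is ``"degree"`` or ``"clustering"``.
    """
    if not adj_series:
        raise ValueError("adjacency series is empty")
    fn = {"degree": degree, "clustering": clustering}.get(metric)
    if fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    return np.vstack([fn(a) for a in adj_series])
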