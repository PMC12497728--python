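"""Repertoire diversity and clonality indices.

All three indices operate on abundance vectors at any unit level (gene,
clonotype, or lineage): the Shannon index (natural log), the Gini index in its
mean-absolute-difference form, and the cumulative frequency of the top-N most
abundant units.
"""

from __future__ import annotations

import numpy as np


def shannon_index(freqs) -> float:
    """Shannon entropy −Σ p_i ln p_i in nats, with 0·ln 0 ≡ 0.

    ``freqs`` must be non-negative and sum to 1 (±1e-6).
    """
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def gini_index(values) -> float:
    """Gini index of an abundance vector: Σ_i Σ_j |x_i − x_j| / (2 n Σ x).

    0 for perfect equality, approaching 1 for extreme concentration.
    Scale-invariant and permutation-invariant.
    """
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("values must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Gini undefined for an all-zero vector")
    # Sorted-form identity for the pairwise absolute-difference sum:
    # ΣΣ|xi−xj| = 2 Σ_k (2k − n − 1) x_(k), avoiding the O(n²) double loop.
    xs = np.sort(x)
    n = len(xs)
    ranks = np.arange(1, n + 1)
    pairwise = 2.0 * np.sum((2 * ranks - n - 1) * xs)
    return float(pairwise / (2.0 * n * total))


def top_n_cumulative(freqs, n: int = 100) -> float:
    """Cumulative frequency of the ``n`` most abundant units (1.0 if fewer)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.asarray(freqs, dtype=float)
    if len(p) <= n:
        return float(p.sum())
    top = np.partition(p, len(p) - n)[len(p) - n:]
    return float(top.sum())
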