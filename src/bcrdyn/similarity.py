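"""Between-sample similarity: Morisita–Horn, lineage overlap, gene-usage correlation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import spearman


def align_counts(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Align two labelled count vectors on the union of labels (absent -> 0)."""
    union = a.index.union(b.index)
    return (
        a.reindex(union, fill_value=0).to_numpy(dtype=float),
        b.reindex(union, fill_value=0).to_numpy(dtype=float),
    )


def morisita_horn(a, b) -> float:
    """Morisita–Horn similarity CH = 2 Σ x_i y_i / ((Σx²/X² + Σy²/Y²) · X · Y).

    Accepts labelled pandas Series (aligned on the label union) or already
    aligned arrays.  1 for identical composition, 0 for disjoint supports;
    invariant to proportional scaling of either vector.
    """
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        x, y = align_counts(a, b)
    else:
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        if x.shape != y.shape:
            raise ValueError("unlabelled vectors must be pre-aligned to equal length")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("Morisita–Horn undefined when either total is zero")
    num = 2.0 * np.dot(x, y)
    den = (np.dot(x, x) / X**2 + np.dot(y, y) / Y**2) * X * Y
    return float(num / den)


def timepoint_overlap(a: set, b: set, method: str = "overlap") -> float:
    """Overlap between two lineage-ID sets.

    ``overlap`` (default) is the overlap coefficient |A∩B| / min(|A|, |B|),
    robust to large size asymmetry between lineage pools; ``jaccard`` is
    |A∩B| / |A∪B|.
    """
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap undefined for an empty lineage set")
    inter = len(a & b)
    if method == "overlap":
        return inter / min(len(a), len(b))
    if method == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown method {method!r}")


def gene_usage_correlation(a: pd.Series, b: pd.Series) -> float:
    """Spearman rank correlation of two gene-usage vectors on their label union.

    Returns NaN (undefined) when either aligned vector is constant.
    """
    x, y = align_counts(a, b)
    return spearman(x, y).statistic
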