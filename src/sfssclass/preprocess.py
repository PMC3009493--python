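"""Expression preprocessing: log transform, low-expression filtering and
per-feature standardization.

Two filtering conventions are supported through one operation,
:func:`filter_min_expression`: keep a miRNA if its log2 expression
reaches a cutoff in at least ``min_count`` samples. ``min_count=1`` with
cutoff 7.25 discards features that never exceed the cutoff in any
sample; ``min_count=ceil(0.10 * n)`` with cutoff 8 keeps features
expressed in at least 10% of samples.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional

import numpy as np

from .datatypes import ExpressionMatrix

__all__ = [
    "log2_transform",
    "filter_min_expression",
    "min_count_fraction",
    "feature_stats",
    "standardize_features",
]


def log2_transform(m: ExpressionMatrix, floor: float = 1.0, *, force: bool = False) -> ExpressionMatrix:
    """Return ``log2(max(x, floor))`` of a raw-scale matrix.

    ``floor`` clamps values from below before the log so non-positive
    intensities stay defined; ``floor=1`` maps them to 0 on the log2
    scale. Applying to an already-log2 matrix is an error unless
    ``force`` is given.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if m.scale == "log2" and not force:
        raise ValueError("matrix is already on the log2 scale (pass force=True to re-apply)")
    vals = np.log2(np.maximum(m.values, floor))
    return replace(m, values=vals, scale="log2", standardized=False)


def min_count_fraction(n_samples: int, fraction: float) -> int:
    """Smallest integer count covering at least the given fraction of samples
    ("at least 10% of the cell lines" -> ``ceil(0.10 * n)``)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return max(1, math.ceil(fraction * n_samples))


def filter_min_expression(
    m: ExpressionMatrix, cutoff: float, min_count: int = 1
) -> ExpressionMatrix:
    """Keep features whose log2 expression is >= cutoff in >= min_count samples.

    The comparison is inclusive; sample set and retained-feature order
    are unchanged. Raises if every feature would be removed.
    """
    if m.scale != "log2":
        raise ValueError("filter_min_expression expects a log2-scale matrix")
    if not 1 <= min_count <= m.n_samples:
        raise ValueError(f"min_count must be in [1, {m.n_samples}]")
    exceed = (m.values >= cutoff).sum(axis=1)
    keep = exceed >= min_count
    if not keep.any():
        raise ValueError("empty matrix after filtering: no feature reaches the cutoff")
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return m.subset(features=kept_ids)


def feature_stats(m: ExpressionMatrix, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (mean, sd) across samples; sd uses the n-1 denominator."""
    means = m.values.mean(axis=1)
    sds = m.values.std(axis=1, ddof=ddof)
    return means, sds


def standardize_features(
    m: ExpressionMatrix,
    stats: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> ExpressionMatrix:
    """Centre every feature to mean 0 and scale to sd 1 (sample sd, n-1).

    When ``stats`` is given (means, sds fit on training data) those are
    applied instead of refitting, so held-out samples are transformed
    without leaking their own statistics.
    """
    if stats is None:
        means, sds = feature_stats(m)
        zero = np.isclose(sds, 0.0)
        if zero.any():
            bad = [f for f, z in zip(m.feature_ids, zero) if z]
            raise ValueError(f"zero-variance features cannot be standardized: {bad[:10]}")
    else:
        means, sds = (np.asarray(a, dtype=float) for a in stats)
        if means.shape != (m.n_features,) or sds.shape != (m.n_features,):
            raise ValueError("stats shape does not match feature count")
        if np.any(sds <= 0):
            raise ValueError("stats contain non-positive sds")
    vals = (m.values - means[:, None]) / sds[:, None]
    return replace(m, values=vals, standardized=True)
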