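"""Bespoke statistical utilities used across the pipeline.

Outlier removal by z-score, Cohen's d with conventional magnitude
categories, Benjamini-Hochberg multiplicity adjustment, and success-rate
inflation of a required sample size.  Model fitting itself (mixed models,
marginal means) is left to general statistics packages; this module only
prepares and post-processes their inputs and outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectSize",
    "zscore_filter",
    "cohens_d",
    "bh_adjust",
    "adjust_sample_size",
]

#: |z| beyond which an observation is discarded (two-sided 0.001 level).
ZSCORE_LIMIT = 3.29

#: Conventional |d| edges: small at 0.2, medium at 0.5, large at >= 0.8.
EFFECT_SIZE_EDGES = (0.2, 0.5, 0.8)


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d (pooled-SD convention) and its magnitude category."""

    d: float
    category: str
    pooling: str = "pooled_sd"


def zscore_filter(
    values, limit: float = ZSCORE_LIMIT
) -> tuple[np.ndarray, np.ndarray]:
    """Remove observations with |z| strictly greater than ``limit``.

    z-scores use the mean and SD (ddof=1) of the full sample and the rule
    is applied in a single pass: the filter is not re-iterated on the
    surviving values.  A zero-SD sample removes nothing.

    Returns
    -------
    kept : ndarray
        Values with |z| <= limit, original order preserved.
    removed : ndarray of int
        Indices (into the input) of the discarded observations.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample")
    if x.size < 2:
        raise ValueError("need at least 2 values to compute z-scores")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy(), np.empty(0, dtype=int)
    z = (x - x.mean()) / sd
    removed = np.flatnonzero(np.abs(z) > limit)
    kept = np.delete(x, removed)
    return kept, removed


def cohens_d(group_a, group_b) -> EffectSize:
    """Cohen's d between two samples with the pooled-SD denominator.

    d = (mean_a - mean_b) / s_p with s_p^2 the (n-1)-weighted average of
    the two sample variances.  The category follows the conventional
    edges on |d| (small 0.2, medium 0.5, large >= 0.8); |d| below the
    small edge is labelled "negligible".
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return EffectSize(d=0.0, category="negligible")
        raise ZeroDivisionError("pooled SD is zero but means differ")
    d = (a.mean() - b.mean()) / math.sqrt(pooled_var)
    small, medium, large = EFFECT_SIZE_EDGES
    mag = abs(d)
    if mag >= large:
        category = "large"
    elif mag >= medium:
        category = "medium"
    elif mag >= small:
        category = "small"
    else:
        category = "negligible"
    return EffectSize(d=d, category=category)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the input ranks and bounded by 1; invariant (up to
    reordering) under permutation of the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_sample_size(n_required: int, success_rate: float) -> int:
    """Inflate a required sample size for an anticipated success rate.

    With only a fraction ``success_rate`` of enrolled subjects expected
    to complete the protocol, ceil(n / rate) must be enrolled to retain
    ``n_required`` completers in expectation.
    """
    if not 0 < success_rate <= 1:
        raise ValueError("success_rate must be in (0, 1]")
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    return math.ceil(n_required / success_rate)
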