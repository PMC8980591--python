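"""Paired comparison arithmetic for the two-model (cavity vs. substitute) design.

Percent differences are always taken with the no-cavity model as reference.
The Wilcoxon matched-pairs signed-rank test uses the large-sample normal
approximation without continuity or tie correction, which at N = 6 with all
differences of one sign yields p = 0.028 (the exact-distribution value would
be 0.031); an exact mode is available for small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "percent_difference",
    "wilcoxon_signed_rank",
    "summarize",
    "PairedComparison",
    "compare_rois",
]


def percent_difference(th_value: float, nth_value: float) -> float:
    """100 * (th - nth) / nth, with the no-cavity (NTH) value as reference."""
    if nth_value == 0:
        raise ValueError("reference (NTH) value must be nonzero")
    return 100.0 * (th_value - nth_value) / nth_value


def wilcoxon_signed_rank(th_values, nth_values, exact: bool = False):
    """Wilcoxon matched-pairs signed-rank test on paired samples.

    Returns ``(W_plus, z, p)`` where ``W_plus`` is the sum of ranks of
    positive differences (th - nth), ``z`` the standard normal deviate
    ``(W_plus - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)`` without continuity or
    tie correction, and ``p`` the two-sided tail probability.  Zero
    differences are dropped with a warning.  With ``exact=True`` (n <= 12)
    the p-value comes from full enumeration of the 2^n sign assignments and
    ``z`` is still reported from the approximation.
    """
    th = np.asarray(th_values, dtype=float)
    nth = np.asarray(nth_values, dtype=float)
    if th.shape != nth.shape or th.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = th - nth
    if np.any(d == 0):
        warnings.warn("dropping zero differences from signed-rank test")
        d = d[d != 0]
    n = d.size
    if n < 4:
        raise ValueError("need at least 4 nonzero pairs for the signed-rank test")
    ranks = rankdata(np.abs(d))  # average ranks on ties
    W_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (W_plus - mean) / sd
    if exact:
        if n > 12:
            raise ValueError("exact mode supported only for n <= 12")
        stats = [float(np.dot(signs, ranks)) for signs in product((0, 1), repeat=n)]
        stats = np.array(stats)
        # two-sided: as or more extreme in distance from the mean
        p = float(np.mean(np.abs(stats - mean) >= abs(W_plus - mean) - 1e-12))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return W_plus, float(z), min(p, 1.0)


def summarize(values):
    """Median, Q1 (25th) and Q3 (75th) percentile by linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if v.size < 2:
        return float(v[0]), float(v[0]), float(v[0])
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    return float(med), float(q1), float(q3)


@dataclass
class PairedComparison:
    """Per-ROI paired comparison of one metric across the simulated cases."""

    roi: str
    metric: str
    th_values: np.ndarray
    nth_values: np.ndarray
    percent_differences: np.ndarray
    median: float
    q1: float
    q3: float
    W_plus: float
    z: float
    p: float


def compare_rois(th_table, nth_table, metric: str) -> list[PairedComparison]:
    """Build per-ROI paired comparisons from {roi: [per-case values]} tables."""
    out = []
    for roi in th_table:
        th = np.asarray(th_table[roi], dtype=float)
        nth = np.asarray(nth_table[roi], dtype=float)
        pdiff = np.array([percent_difference(a, b) for a, b in zip(th, nth)])
        med, q1, q3 = summarize(pdiff)
        W, z, p = wilcoxon_signed_rank(th, nth)
        out.append(PairedComparison(roi, metric, th, nth, pdiff,
                                    med, q1, q3, W, z, p))
    return out
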