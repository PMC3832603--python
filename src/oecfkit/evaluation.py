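"""Method-comparison statistics: SSE and the Wilcoxon signed-rank test.

The Wilcoxon statistic is W = min(W+, W-) over the signed ranks of the
non-zero paired differences (midranks for ties, zero differences dropped
and counted). The exact two-sided p-value enumerates all 2^n sign
assignments; the normal approximation applies a tie-corrected variance and
a continuity correction. SSE values are in squared input units (the
source table labels them in the unsquared unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DataError

__all__ = ["ComparisonResult", "sse", "wilcoxon_signed_rank", "compare_methods"]

EXACT_MAX_AUTO = 12   # auto mode switches exact -> normal above this n
EXACT_MAX_HARD = 24   # enumeration refuses beyond 2^24 assignments


@dataclass
class ComparisonResult:
    sse_biexp: float
    sse_bezier: float
    wilcoxon_W: float
    p_value: float
    n_pairs: int
    n_zero_diffs: int

    def as_dict(self) -> dict:
        return {
            "sse_biexp": self.sse_biexp,
            "sse_bezier": self.sse_bezier,
            "wilcoxon_W": self.wilcoxon_W,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "n_zero_diffs": self.n_zero_diffs,
        }


def sse(measured, recovered) -> float:
    """Sum of squared differences between two equal-length sequences."""
    m = np.asarray(measured, dtype=float)
    r = np.asarray(recovered, dtype=float)
    if m.shape != r.shape or m.ndim != 1 or m.size < 1:
        raise ValueError("inputs must be equal-length 1-D with >= 1 element")
    return float(np.sum((m - r) ** 2))


def _exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(min(W+, W-) <= w_obs) under the sign-flip null, by enumeration."""
    n = ranks.size
    total = ranks.sum()
    # Enumerate W+ for all 2^n assignments by bit tricks.
    w_plus = np.zeros(1)
    for r in ranks:
        w_plus = np.concatenate([w_plus, w_plus + r])
    w_min = np.minimum(w_plus, total - w_plus)
    return float(np.mean(w_min <= w_obs + 1e-12))


def wilcoxon_signed_rank(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    Returns (W, p) with W = min(W+, W-). Zero differences are dropped;
    ties get midranks. ``mode`` is "exact" (full sign-assignment
    enumeration), "normal_approx" (tie-corrected variance, continuity
    correction) or "auto" (exact for n <= 12).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DataError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if mode == "auto":
        mode = "exact" if n <= EXACT_MAX_AUTO else "normal_approx"
    if mode == "exact":
        if n > EXACT_MAX_HARD:
            raise ValueError(
                f"exact enumeration limited to n <= {EXACT_MAX_HARD}"
            )
        return w, _exact_p(ranks, w)
    if mode == "normal_approx":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(counts**3 - counts)) / 48.0
        if var <= 0:
            raise DataError("zero variance after tie correction")
        z = (w - mu + 0.5) / np.sqrt(var)  # continuity correction; w <= mu
        p = min(1.0, 2.0 * float(norm.cdf(z)))
        return w, p
    raise ValueError(f"unknown mode {mode!r}")


def compare_methods(
    measured, recovered_biexp, recovered_bezier, mode: str = "auto"
) -> ComparisonResult:
    """SSE of each method against the measurement, plus the paired test."""
    m = np.asarray(measured, dtype=float)
    rb = np.asarray(recovered_biexp, dtype=float)
    rz = np.asarray(recovered_bezier, dtype=float)
    d = rb - rz
    n_zero = int(np.sum(d == 0))
    w, p = wilcoxon_signed_rank(rb, rz, mode=mode)
    return ComparisonResult(
        sse_biexp=sse(m, rb),
        sse_bezier=sse(m, rz),
        wilcoxon_W=w,
        p_value=p,
        n_pairs=int(m.size - n_zero),
        n_zero_diffs=n_zero,
    )
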