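"""Penalized change-point detection for piecewise-constant genomic tracks.

A PELT-style exact search with an L2 (within-segment sum of squares) cost.
The cost is divided by a robust noise-variance estimate (median absolute
deviation of first differences) so that one penalty scale works for both the
VAF-deviation track (binomial noise) and the depth-ratio copy-number track
(Poisson noise); the penalty is ``beta * log(n)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_noise_variance", "pelt_l2", "segment_indices", "merge_segments"]


def estimate_noise_variance(values: np.ndarray) -> float:
    """Robust noise variance from first differences.

    ``Var(x[i+1] - x[i]) = 2 sigma^2`` for iid noise around a piecewise
    constant mean; the MAD is insensitive to the few jump differences.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    diffs = np.diff(values)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sigma = mad / (0.67448975 * np.sqrt(2.0))
    return float(sigma * sigma)


def pelt_l2(
    values: np.ndarray,
    penalty: float,
    min_size: int = 2,
    noise_var: float | None = None,
) -> list[int]:
    """Exact penalized segmentation; returns interior change points as indices.

    A change point ``t`` means segments ``[.., t)`` and ``[t, ..)``. The L2
    cost of each segment is divided by ``noise_var`` (estimated robustly when
    not given) before the ``penalty`` is applied.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_size:
        return []
    if noise_var is None:
        noise_var = estimate_noise_variance(x)
    noise_var = max(noise_var, 1e-12)

    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    candidates = np.array([0], dtype=int)
    for t in range(min_size, n + 1):
        usable = candidates[t - candidates >= min_size]
        # residual sum of squares of x[s:t] around its mean, noise-scaled
        sums = cs[t] - cs[usable]
        costs = ((cs2[t] - cs2[usable]) - sums * sums / (t - usable)) / noise_var
        totals = f[usable] + costs + penalty
        best = int(np.argmin(totals))
        f[t] = totals[best]
        prev[t] = usable[best]
        # PELT pruning: a candidate whose cost already exceeds f[t] can never win
        keep_usable = usable[f[usable] + costs <= f[t]]
        pending = candidates[t - candidates < min_size]
        candidates = np.concatenate(
            [keep_usable, pending, [t - min_size + 1]]
        )

    breakpoints: list[int] = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            breakpoints.append(s)
        t = s
    return sorted(breakpoints)


def segment_indices(
    values: np.ndarray,
    beta: float = 3.0,
    min_size: int = 2,
    merge_tol: float | None = None,
) -> list[tuple[int, int]]:
    """Segment a series into half-open index ranges covering ``[0, n)``.

    Penalty is ``beta * log(n)``. When ``merge_tol`` is given, adjacent
    segments whose means differ by less than it are joined.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return []
    penalty = beta * np.log(max(n, 2))
    bkps = pelt_l2(x, penalty=penalty, min_size=min_size)
    bounds = [0, *bkps, n]
    segments = list(zip(bounds[:-1], bounds[1:]))
    if merge_tol is not None:
        segments = merge_segments(x, segments, merge_tol)
    return segments


def merge_segments(
    values: np.ndarray, segments: list[tuple[int, int]], tol: float
) -> list[tuple[int, int]]:
    """Join adjacent segments whose means differ by less than ``tol``."""
    if not segments:
        return []
    x = np.asarray(values, dtype=float)
    merged = [segments[0]]
    for start, end in segments[1:]:
        pstart, pend = merged[-1]
        if abs(x[start:end].mean() - x[pstart:pend].mean()) < tol:
            merged[-1] = (pstart, end)
        else:
            merged.append((start, end))
    return merged
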