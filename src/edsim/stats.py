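"""Simulation output analysis.

Warm-up truncation by the moving-average (Welch) method, batch-means
confidence intervals for one long steady-state run, utilization from
activity logs, and Welch two-sample t-tests between model variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "BatchCI",
    "ComparisonResult",
    "batch_means",
    "compare",
    "replication_ci",
    "utilization",
    "welch_warmup",
]


@dataclass(frozen=True)
class BatchCI:
    """A batched-mean estimate with a 95% confidence half-width."""

    mean: float
    half_width: float
    n_batches: int
    batch_size: int
    confidence: float = 0.95

    @property
    def lo(self) -> float:
        return self.mean - self.half_width

    @property
    def hi(self) -> float:
        return self.mean + self.half_width


@dataclass(frozen=True)
class ComparisonResult:
    difference: float
    sd: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def welch_warmup(
    values: Sequence[float], window: int, rel_tol: float = 0.05
) -> int | None:
    """Truncation index by moving-average stabilization.

    Computes the trailing moving average of ``values`` with the given
    window and returns the first index after which the moving average stays
    within ``rel_tol`` (relative) of its terminal level for the remainder of
    the series.  Returns ``None`` if the series never stabilizes.
    """
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size <= 2 * window:
        raise ValueError("series too short for the chosen window")
    kernel = np.full(window, 1.0 / window)
    ma = np.convolve(x, kernel, mode="valid")  # trailing MA, index i covers x[i:i+window]
    terminal = ma[-max(1, ma.size // 10):].mean()
    scale = abs(terminal) if terminal != 0 else 1.0
    inside = np.abs(ma - terminal) <= rel_tol * scale
    # first index from which every subsequent MA stays inside the band
    bad = np.nonzero(~inside)[0]
    if bad.size == 0:
        return 0
    first_ok = bad[-1] + 1
    if first_ok >= ma.size:
        return None
    # translate from MA index to series index (end of the averaging window)
    return int(first_ok + window - 1)


def batch_means(
    values: Sequence[float], min_batches: int = 20, max_batches: int = 40
) -> BatchCI:
    """Batch-means 95% CI for the steady-state mean of one long run.

    The post-warm-up series is cut into batches whose size doubles until the
    lag-1 autocorrelation of the batch means is statistically negligible
    (|r1| below the two-sided 5% bound 1.96/sqrt(m)) or fewer than
    ``min_batches`` batches remain; the last screening that still leaves at
    least ``min_batches`` batches is used.  The point estimate equals the
    plain sample mean of the included observations; batching changes only
    the variance estimate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 * min_batches:
        raise ValueError(
            f"need at least {2 * min_batches} observations for {min_batches} batches, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        return BatchCI(float(x[0]) if x.size else 0.0, 0.0, x.size, 1)

    batch_size = max(1, x.size // max_batches)
    while True:
        m = x.size // batch_size
        if m < min_batches:
            m = min_batches
            batch_size = x.size // m
        used = m * batch_size
        means = x[:used].reshape(m, batch_size).mean(axis=1)
        r1 = _lag1_autocorr(means)
        if abs(r1) <= 1.96 / math.sqrt(m) or x.size // (2 * batch_size) < min_batches:
            break
        batch_size *= 2

    grand = float(x[:used].mean())
    s = means.std(ddof=1)
    hw = float(sps.t.ppf(0.975, m - 1) * s / math.sqrt(m))
    return BatchCI(grand, hw, m, batch_size)


def _lag1_autocorr(x: np.ndarray) -> float:
    if x.size < 3:
        return 0.0
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        return 0.0
    return float(d[:-1] @ d[1:]) / denom


def replication_ci(values: Sequence[float]) -> BatchCI:
    """t-based 95% CI across independent replication means."""
    x = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if x.size < 2:
        raise ValueError("confidence interval undefined for fewer than 2 replications")
    s = x.std(ddof=1)
    hw = float(sps.t.ppf(0.975, x.size - 1) * s / math.sqrt(x.size))
    return BatchCI(float(x.mean()), hw, int(x.size), 1)


def utilization(
    intervals: Sequence[tuple[object, float, float]] | Sequence[tuple[float, float]],
    scheduled_time: float,
    start: float = 0.0,
    busy_states: frozenset | None = None,
) -> float:
    """Fraction of scheduled time spent on patient-related activity.

    ``intervals`` are ``(state, start, end)`` activity-log rows (or bare
    ``(start, end)`` busy intervals).  Overlapping busy intervals violate the
    single-agent contract and raise.  The result is invariant to log
    granularity: splitting an interval in two changes nothing.
    """
    if scheduled_time <= 0:
        raise ValueError("scheduled_time must be positive")
    end = start + scheduled_time
    busy: list[tuple[float, float]] = []
    for row in intervals:
        if len(row) == 3:
            state, a, b = row  # type: ignore[misc]
            if busy_states is not None:
                if state not in busy_states:
                    continue
            elif getattr(state, "value", state) in ("idle", "awaiting_consult"):
                continue
        else:
            a, b = row  # type: ignore[misc]
        a2, b2 = max(float(a), start), min(float(b), end)
        if b2 > a2:
            busy.append((a2, b2))
    busy.sort()
    total = 0.0
    last_end = -math.inf
    for a, b in busy:
        if a < last_end - 1e-9:
            raise ValueError(f"overlapping activity intervals at t={a:.6g}")
        total += b - max(a, last_end)
        last_end = max(last_end, b)
    return total / scheduled_time


def compare(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> ComparisonResult:
    """Welch two-sample t-test on independent batch/replication means.

    Reports the mean difference ``b - a``, its standard error, the p-value
    and significance at ``alpha``.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need at least 2 observations on each side")
    diff = float(xb.mean() - xa.mean())
    sd = float(math.sqrt(xa.var(ddof=1) / xa.size + xb.var(ddof=1) / xb.size))
    if sd == 0.0:
        return ComparisonResult(diff, 0.0, 1.0 if diff == 0 else 0.0, diff != 0, alpha)
    t_res = sps.ttest_ind(xb, xa, equal_var=False)
    p = float(t_res.pvalue)
    return ComparisonResult(diff, sd, p, p < alpha, alpha)
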