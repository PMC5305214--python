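"""Change-point idealization of bleaching traces.

Two idealizers are provided:

``idealize_cp``
    Parameter-free change-point analysis: recursive binary segmentation
    with a generalized log-likelihood-ratio (LLR) test in which each
    segment carries its own Gaussian variance.  The test threshold is
    calibrated by Monte Carlo (``calibrate_threshold``) so that on a
    constant-mean trace the probability of reporting *any* change point
    equals ``1 - confidence`` (5% per trace at the default 95% level).
    Segment-local variances accommodate shot-noise-like scaling of the
    variance with intensity, which a bleaching trace exhibits.

``idealize_kv``
    The constant-variance baseline: greedy binary segmentation in which a
    split is accepted whenever it lowers the Bayes Information Criterion
    of a global piecewise-constant-mean, single-variance Gaussian model,
    BIC = n log(RSS/n) + (k + 2) log(n) for k change points, so each
    extra step costs log(n).  Steps may fall anywhere, including next to
    the trace ends (one-frame levels are admissible because the variance
    is shared globally).  On pure-noise traces this criterion grossly
    over-segments, which is exactly why it serves here only as a
    comparison baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import IntensityTrace, Idealization

__all__ = [
    "CriticalValueTable",
    "calibrate_threshold",
    "idealize_cp",
    "idealize_kv",
    "detection_stats",
    "max_llr_split",
]

# Shortest level the CP test can produce: the variance of a one-frame
# level is undefined, so splits leave at least 2 frames on each side.
MIN_LEVEL = 2

_VAR_FLOOR = 1e-300


def _segment_stats(x: np.ndarray) -> tuple[float, float]:
    """MLE mean and variance (ddof=0) of a segment."""
    m = float(np.mean(x))
    v = float(np.mean((x - m) ** 2))
    return m, v


def max_llr_split(x: np.ndarray) -> tuple[int, float]:
    """Best single change point of a segment under the generalized LLR.

    For each admissible split ``c`` (left part ``x[:c]``, right part
    ``x[c:]``, both at least ``MIN_LEVEL`` frames) the statistic is

        LLR(c) = (n/2) log v  - (c/2) log v_L - ((n-c)/2) log v_R

    with MLE variances estimated separately on the whole segment and on
    each part.  Returns ``(c*, LLR(c*))`` with ties broken toward the
    earliest frame.  Requires ``len(x) >= 2 * MIN_LEVEL``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * MIN_LEVEL:
        raise ValueError(f"segment too short to split (need >= {2 * MIN_LEVEL} frames)")
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    tot1, tot2 = s1[-1], s2[-1]
    c = np.arange(MIN_LEVEL, n - MIN_LEVEL + 1)  # split indices
    nl = c.astype(float)
    nr = n - nl
    sl1 = s1[c - 1]
    sl2 = s2[c - 1]
    vl = np.maximum(sl2 / nl - (sl1 / nl) ** 2, _VAR_FLOOR)
    vr = np.maximum((tot2 - sl2) / nr - ((tot1 - sl1) / nr) ** 2, _VAR_FLOOR)
    v = max(tot2 / n - (tot1 / n) ** 2, _VAR_FLOOR)
    llr = 0.5 * (n * np.log(v) - nl * np.log(vl) - nr * np.log(vr))
    i = int(np.argmax(llr))
    return int(c[i]), float(llr[i])


def _max_llr_batch(X: np.ndarray) -> np.ndarray:
    """Max LLR over splits for each row of a (m, n) batch (no argmax)."""
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    s1 = np.cumsum(X, axis=1)
    s2 = np.cumsum(X * X, axis=1)
    tot1 = s1[:, -1:]
    tot2 = s2[:, -1:]
    c = np.arange(MIN_LEVEL, n - MIN_LEVEL + 1)
    nl = c.astype(float)
    nr = n - nl
    sl1 = s1[:, c - 1]
    sl2 = s2[:, c - 1]
    vl = np.maximum(sl2 / nl - (sl1 / nl) ** 2, _VAR_FLOOR)
    vr = np.maximum((tot2 - sl2) / nr - ((tot1 - sl1) / nr) ** 2, _VAR_FLOOR)
    v = np.maximum(tot2 / n - (tot1 / n) ** 2, _VAR_FLOOR)
    llr = 0.5 * (n * np.log(v) - nl * np.log(vl) - nr * np.log(vr))
    return llr.max(axis=1)


@dataclass
class CriticalValueTable:
    """Monte-Carlo critical values of the max-LLR statistic vs segment length.

    ``critical_values[i]`` is the ``confidence`` quantile of the maximal
    single-change-point LLR on i.i.d. Gaussian segments of length
    ``lengths[i]``; intermediate lengths are interpolated on a log-length
    scale, and lengths outside the table are clamped to its ends.
    """

    lengths: np.ndarray
    critical_values: np.ndarray
    confidence: float = 0.95
    n_sim: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.critical_values = np.asarray(self.critical_values, dtype=float)
        if self.lengths.size != self.critical_values.size:
            raise ValueError("lengths and critical values differ in size")

    def threshold(self, length: int) -> float:
        return float(
            np.interp(
                np.log(length), np.log(self.lengths), self.critical_values
            )
        )


def _default_length_grid(n_frames: int) -> np.ndarray:
    grid = [4, 5, 6, 8, 10, 12, 16, 20, 26, 34, 44, 58, 75, 96, 120]
    grid = [g for g in grid if g < n_frames] + [n_frames]
    return np.array(sorted(set(grid)), dtype=int)


def calibrate_threshold(
    n_frames: int,
    confidence: float = 0.95,
    n_sim: int = 10_000,
    seed: int = 0,
    lengths: np.ndarray | None = None,
) -> CriticalValueTable:
    """Monte-Carlo calibration of the CP split test.

    For each segment length, draw ``n_sim`` i.i.d. standard-normal
    segments (the statistic is location/scale invariant so the null is
    fully general), compute the maximal split LLR of each, and record the
    ``confidence`` quantile.  The root test on a full trace then rejects
    a constant-mean trace with probability ``1 - confidence``, making the
    per-trace false-positive rate the calibrated quantity.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if n_sim < 1_000:
        raise ValueError("n_sim too small to estimate the quantile reliably")
    if n_sim * (1 - confidence) < 20:
        raise ValueError("n_sim too small for the requested confidence quantile")
    if lengths is None:
        lengths = _default_length_grid(n_frames)
    lengths = np.asarray(lengths, dtype=int)
    if lengths.min() < 2 * MIN_LEVEL:
        raise ValueError(f"lengths must be >= {2 * MIN_LEVEL}")
    rng = np.random.default_rng(seed)
    crit = np.empty(lengths.size)
    for i, length in enumerate(lengths):
        stats = _max_llr_batch(rng.standard_normal((n_sim, int(length))))
        crit[i] = np.quantile(stats, confidence)
    return CriticalValueTable(
        lengths=lengths,
        critical_values=crit,
        confidence=confidence,
        n_sim=n_sim,
        seed=seed,
    )


def _as_values(trace) -> np.ndarray:
    if isinstance(trace, IntensityTrace):
        return trace.values
    return np.asarray(trace, dtype=float)


def _single_level(x: np.ndarray) -> Idealization:
    m, v = _segment_stats(x)
    return Idealization(
        change_points=np.array([], dtype=int),
        level_means=np.array([m]),
        level_variances=np.array([v]),
        level_durations=np.array([x.size]),
    )


def _levels_from_breaks(x: np.ndarray, breaks: list[int]) -> Idealization:
    breaks = sorted(breaks)
    bounds = [0] + breaks + [x.size]
    means, variances, durations = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        m, v = _segment_stats(x[a:b])
        means.append(m)
        variances.append(v)
        durations.append(b - a)
    return Idealization(
        change_points=np.array(breaks, dtype=int),
        level_means=np.array(means),
        level_variances=np.array(variances),
        level_durations=np.array(durations, dtype=int),
    )


def idealize_cp(trace, table: CriticalValueTable) -> Idealization:
    """Recursive binary segmentation with per-length calibrated thresholds.

    On each segment the best split (``max_llr_split``) is accepted iff its
    LLR exceeds the table's critical value for that segment's length;
    accepted splits recurse into both children.  Traces shorter than
    ``2 * MIN_LEVEL`` frames yield a single-level idealization with a
    warning.
    """
    x = _as_values(trace)
    if x.size < 2 * MIN_LEVEL:
        warnings.warn("trace too short for change-point analysis; single level")
        return _single_level(x)

    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * MIN_LEVEL:
            return
        c, llr = max_llr_split(x[lo:hi])
        if llr > table.threshold(n):
            breaks.append(lo + c)
            recurse(lo, lo + c)
            recurse(lo + c, hi)

    recurse(0, x.size)
    return _levels_from_breaks(x, breaks)


def _best_rss_split(x: np.ndarray, min_level: int = 1) -> tuple[int, float]:
    """Split minimizing the two-segment residual sum of squares."""
    n = x.size
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    c = np.arange(min_level, n - min_level + 1)
    nl = c.astype(float)
    nr = n - nl
    sl1 = s1[c - 1]
    rss = (s2[c - 1] - sl1**2 / nl) + (s2[-1] - s2[c - 1] - (s1[-1] - sl1) ** 2 / nr)
    i = int(np.argmin(rss))
    return int(c[i]), float(rss[i])


def idealize_kv(trace) -> Idealization:
    """Greedy BIC-guided segmentation under a global constant variance.

    Model: piecewise-constant means with one shared Gaussian variance;
    BIC = n log(RSS/n) + (k + 2) log(n), one extra parameter per change
    point.  At each iteration the single split (anywhere, in any current
    segment) that most reduces the global RSS is proposed and accepted
    iff the BIC drops; the recursion stops at the first rejection.
    """
    x = _as_values(trace)
    n = x.size
    if n < 2 * MIN_LEVEL:
        warnings.warn("trace too short for change-point analysis; single level")
        return _single_level(x)

    penalty = np.log(n)
    breaks: list[int] = []

    def seg_rss(lo: int, hi: int) -> float:
        seg = x[lo:hi]
        return float(np.sum((seg - seg.mean()) ** 2))

    segments = {(0, n): None}

    def best_for(lo: int, hi: int):
        if hi - lo < 2:
            return None
        c, rss_after = _best_rss_split(x[lo:hi])
        return lo + c, seg_rss(lo, hi) - rss_after

    for key in list(segments):
        segments[key] = best_for(*key)

    rss_total = seg_rss(0, n)
    while True:
        candidates = [(v[1], k, v[0]) for k, v in segments.items() if v is not None]
        if not candidates:
            break
        gain, (lo, hi), split = max(candidates, key=lambda t: t[0])
        rss_new = max(rss_total - gain, _VAR_FLOOR)
        if n * np.log(rss_total / rss_new) <= penalty:
            break
        breaks.append(split)
        rss_total = rss_new
        del segments[(lo, hi)]
        for child in ((lo, split), (split, hi)):
            segments[child] = best_for(*child)

    return _levels_from_breaks(x, breaks)


def detection_stats(
    idealize,
    traces,
    true_change_points,
    tol: int = 2,
) -> dict:
    """Efficiency and false-positive summary of a detector on labelled traces.

    Parameters
    ----------
    idealize
        Callable mapping a trace to an :class:`Idealization`.
    traces
        Iterable of traces (arrays or :class:`IntensityTrace`).
    true_change_points
        Per-trace sequences of true change-point frames (empty for null
        traces).  A true step counts as detected when some detected change
        point lies within ``tol`` frames of it.

    Returns
    -------
    dict with ``efficiency`` (fraction of true steps detected),
    ``type1_rate`` (fraction of null traces with >= 1 detection) and
    ``state_counts`` (histogram of detected level counts, as a dict).
    """
    n_true = 0
    n_hit = 0
    n_null = 0
    n_null_fp = 0
    state_counts: dict[int, int] = {}
    for trace, truth in zip(traces, true_change_points):
        ideal = idealize(trace)
        detected = ideal.change_points
        state_counts[ideal.n_levels] = state_counts.get(ideal.n_levels, 0) + 1
        truth = np.asarray(truth, dtype=int)
        if truth.size == 0:
            n_null += 1
            if detected.size > 0:
                n_null_fp += 1
            continue
        n_true += truth.size
        for t in truth:
            if detected.size and np.min(np.abs(detected - t)) <= tol:
                n_hit += 1
    return {
        "efficiency": n_hit / n_true if n_true else float("nan"),
        "type1_rate": n_null_fp / n_null if n_null else float("nan"),
        "state_counts": state_counts,
    }
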