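"""Latency estimation from phase transfer functions.

The cumulative phase lag of the response grows linearly with pulse rate
wherever a single generator dominates; its slope gives the group delay
``tau_ms = slope / (2 pi) * 1000`` (slope in rad/Hz).  Two estimators are
provided:

* **piecewise regression** — exhaustive partition of the significant rates
  into up to 5 contiguous linear segments (>= 3 rates each) minimizing total
  SSE, followed by fusion of adjacent segments whose slopes do not differ
  (slope-equality t-test on the combined regression, p > 0.05);
* **3-point running group delay** — the slope of each set of three
  consecutive rates, assigned to the middle rate and linearly interpolated
  to a 1-pps grid.

Both respect a maximum rate gap and a monotonicity tolerance (phase
decreases between adjacent rates no more negative than -pi/20), and delays
below 1 ms are excluded from downstream synchrony analysis.  The maximum
synchrony rate of a putative generator is the highest pulse rate whose group
delay is at least that generator's nominal minimum latency (CN 1, SOC 2,
IC 4, TC 8, CTX 12 ms).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectral_analysis import TransferFunction

__all__ = [
    "PhaseCurve",
    "PhaseSegment",
    "GroupDelayConfig",
    "DelaySeries",
    "GENERATOR_MIN_LATENCY_MS",
    "unwrap_phase",
    "phase_curve_from_tf",
    "monotonic_mask",
    "slopes_differ",
    "piecewise_fit",
    "running_group_delay_3pt",
    "segments_to_series",
    "max_sync_rates",
    "high_rate_group_delay",
]

#: nominal minimum latency attributed to each putative generator (ms)
GENERATOR_MIN_LATENCY_MS = {"CN": 1.0, "SOC": 2.0, "IC": 4.0, "TC": 8.0, "CTX": 12.0}


@dataclass(frozen=True)
class GroupDelayConfig:
    n_segments: int = 5  # 4 when <= 20 significant rates
    few_rates_threshold: int = 20
    min_points_per_segment: int = 3
    max_gap_pps: float = 60.0  # 80 when < 20 significant rates
    max_gap_few_pps: float = 80.0
    monotonic_tol_rad: float = -np.pi / 20.0
    fuse_p: float = 0.05
    min_delay_ms: float = 1.0

    def segments_for(self, n_rates: int) -> int:
        return 4 if n_rates <= self.few_rates_threshold else self.n_segments

    def gap_for(self, n_rates: int) -> float:
        return self.max_gap_few_pps if n_rates < 20 else self.max_gap_pps


@dataclass
class PhaseCurve:
    """Cumulative (unwrapped) phase lag in rad over ascending rates (pps)."""

    rates_pps: np.ndarray
    phase_rad: np.ndarray
    channel: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.rates_pps) <= 0):
            raise ValueError("rates must be strictly ascending")
        if not np.all(np.isfinite(self.phase_rad)):
            raise ValueError("phases must be finite")


def unwrap_phase(rates_pps, wrapped_phase_rad, channel: int = 0) -> PhaseCurve:
    """Accumulate phase lags across increasing rates, adding 2 pi wherever
    adjacent phases differ by more than pi (after correction every successive
    difference lies in (-pi, pi]; the first value is unchanged)."""
    rates = np.asarray(rates_pps, dtype=float)
    if rates.size < 2:
        raise ValueError("need >= 2 rates to unwrap")
    return PhaseCurve(rates, np.unwrap(np.asarray(wrapped_phase_rad, dtype=float)), channel)


def phase_curve_from_tf(tf: TransferFunction) -> PhaseCurve:
    """Cumulative phase *lag* over the significant rates of a transfer
    function.  Spectral phases decrease with latency, so the lag is the
    unwrapped negative phase and group delays come out positive."""
    rates, phase = tf.significant_subset()
    return unwrap_phase(rates, -np.asarray(phase), tf.channel)


def monotonic_mask(curve: PhaseCurve, cfg: GroupDelayConfig | None = None):
    """Maximal admissible runs of the curve: within a run every successive
    phase difference is >= the monotonicity tolerance and every rate gap is
    <= the maximum gap.  Returns a list of ``slice`` objects."""
    cfg = cfg or GroupDelayConfig()
    n = curve.rates_pps.size
    gap = cfg.gap_for(n)
    ok = (np.diff(curve.phase_rad) >= cfg.monotonic_tol_rad) & (
        np.diff(curve.rates_pps) <= gap
    )
    runs = []
    start = 0
    for i, good in enumerate(ok):
        if not good:
            runs.append(slice(start, i + 1))
            start = i + 1
    runs.append(slice(start, n))
    runs = [r for r in runs if r.stop - r.start >= cfg.min_points_per_segment]
    if not runs:
        warnings.warn("no admissible run of >= 3 rates")
    return runs


def _linfit(x, y):
    """Least-squares line fit; returns (slope, intercept, sse)."""
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(res[0]) if res.size else float(np.sum((y - A @ coef) ** 2))
    return float(coef[0]), float(coef[1]), sse


def slopes_differ(x1, y1, x2, y2, alpha: float = 0.05) -> tuple[bool, float]:
    """Two-segment slope-equality test (the rate x segment interaction of the
    combined regression, equivalently the classic two-slope t-test with
    pooled residual variance).  Returns ``(differ, p_value)``."""
    b1, _, sse1 = _linfit(x1, y1)
    b2, _, sse2 = _linfit(x2, y2)
    if abs(b1 - b2) <= 1e-9 * max(1.0, abs(b1), abs(b2)):
        return False, 1.0  # numerically equal slopes
    n1, n2 = len(x1), len(x2)
    df = n1 + n2 - 4
    if df <= 0:
        return False, 1.0
    s2 = (sse1 + sse2) / df
    sxx1 = float(np.sum((x1 - np.mean(x1)) ** 2))
    sxx2 = float(np.sum((x2 - np.mean(x2)) ** 2))
    if s2 == 0.0:
        # noiseless data: slopes differ iff they are not numerically equal
        differ = abs(b1 - b2) > 1e-9 * max(1.0, abs(b1), abs(b2))
        return differ, 0.0 if differ else 1.0
    se = math.sqrt(s2 * (1.0 / sxx1 + 1.0 / sxx2))
    t = (b1 - b2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return p < alpha, float(p)


@dataclass
class PhaseSegment:
    index: slice  # into the curve arrays
    rate_range_pps: tuple[float, float]
    slope_rad_per_hz: float
    intercept_rad: float
    n_points: int
    sse: float

    @property
    def tau_ms(self) -> float:
        return self.slope_rad_per_hz / (2.0 * np.pi) * 1e3


def _make_segment(curve: PhaseCurve, i0: int, i1: int) -> PhaseSegment:
    x = curve.rates_pps[i0:i1]
    y = curve.phase_rad[i0:i1]
    b, a, sse = _linfit(x, y)
    return PhaseSegment(
        index=slice(i0, i1),
        rate_range_pps=(float(x[0]), float(x[-1])),
        slope_rad_per_hz=b,
        intercept_rad=a,
        n_points=i1 - i0,
        sse=sse,
    )


def piecewise_fit(
    curve: PhaseCurve, cfg: GroupDelayConfig | None = None
) -> list[PhaseSegment]:
    """Optimal contiguous partition of the admissible curve into linear
    segments, then fusion of adjacent same-run segments with equal slopes.

    The partition into ``cfg.segments_for(n)`` segments (>= 3 points each,
    never straddling an inadmissible step or over-wide gap) minimizing the
    total SSE is found by dynamic programming — equivalent to exhaustive
    enumeration of all valid partitions.  If the admissible runs force more
    (or allow fewer) segments than requested, the count is adjusted and the
    result flagged via a warning.
    """
    cfg = cfg or GroupDelayConfig()
    runs = monotonic_mask(curve, cfg)
    if not runs:
        return []
    n = curve.rates_pps.size
    run_id = np.full(n, -1)
    for ri, r in enumerate(runs):
        run_id[r] = ri
    valid = run_id >= 0
    mpts = cfg.min_points_per_segment

    # feasible segment count range given the runs
    max_segs = sum((r.stop - r.start) // mpts for r in runs)
    min_segs = len(runs)
    want = cfg.segments_for(n)
    n_seg = min(max(want, min_segs), max_segs)
    if n_seg != want:
        warnings.warn(f"using {n_seg} segments (requested {want}) given admissible runs")

    # segment cost: SSE of the line fit, or inf if invalid
    INF = np.inf
    cost = np.full((n, n + 1), INF)  # cost[i][j] for segment [i, j)
    for r in runs:
        for i in range(r.start, r.stop - mpts + 1):
            x = curve.rates_pps
            y = curve.phase_rad
            for j in range(i + mpts, r.stop + 1):
                _, _, sse = _linfit(x[i:j], y[i:j])
                cost[i, j] = sse

    # DP over number of segments; segments must tile all valid points of the
    # runs in order (invalid points are skipped between runs)
    order = [i for r in runs for i in range(r.start, r.stop)]
    pos_of = {i: p for p, i in enumerate(order)}
    starts = [r.start for r in runs]
    ends = {r.stop for r in runs}
    best = {}  # (seg_count, end_index) -> (total_sse, prev_key, (i, j))

    def successors(j):
        """Next segment start after position j (same run or next run)."""
        if j in ends:
            nxt = [s for s in starts if s > j - 1 and run_id[s] > (run_id[j - 1] if j > 0 else -1)]
            return min(nxt) if nxt else None
        return j

    best[(0, runs[0].start)] = (0.0, None, None)
    frontier = {(0, runs[0].start)}
    final = None
    for _ in range(n_seg):
        new = {}
        for key in frontier:
            s, i = key
            if i >= n:  # all points consumed; nothing to extend
                continue
            base = best[key][0]
            r = runs[run_id[i]]
            for j in range(i + mpts, r.stop + 1):
                if not np.isfinite(cost[i, j]):
                    continue
                total = base + cost[i, j]
                nxt = successors(j)
                nk = (s + 1, nxt if nxt is not None else n)
                if nk not in best or total < best[nk][0] - 1e-15:
                    best[nk] = (total, key, (i, j))
                    new[nk] = True
        frontier = set(new)
    goal = (n_seg, n)
    if goal not in best:
        # fall back: best full tiling with any feasible count
        cands = [k for k in best if k[1] == n and k[0] >= 1]
        if not cands:
            warnings.warn("piecewise fit infeasible; fitting one line per run")
            return [_make_segment(curve, r.start, r.stop) for r in runs]
        goal = min(cands, key=lambda k: best[k][0])
        warnings.warn(f"used {goal[0]} segments; {n_seg} infeasible")
    segs = []
    key = goal
    while best[key][1] is not None:
        _, prev, ij = best[key]
        segs.append(ij)
        key = prev
    segs.reverse()
    segments = [_make_segment(curve, i, j) for i, j in segs]

    # fusion: adjacent same-run segments with statistically equal slopes
    changed = True
    while changed:
        changed = False
        for k in range(len(segments) - 1):
            a, b = segments[k], segments[k + 1]
            if run_id[a.index.stop - 1] != run_id[b.index.start]:
                continue
            x1, y1 = curve.rates_pps[a.index], curve.phase_rad[a.index]
            x2, y2 = curve.rates_pps[b.index], curve.phase_rad[b.index]
            differ, _ = slopes_differ(x1, y1, x2, y2, cfg.fuse_p)
            if not differ:
                segments[k : k + 2] = [_make_segment(curve, a.index.start, b.index.stop)]
                changed = True
                break
    return segments


@dataclass
class DelaySeries:
    """Group delays sampled over pulse rates (1-pps grid for the running
    method; per-significant-rate for piecewise segments)."""

    rates_pps: np.ndarray
    tau_ms: np.ndarray
    method: str
    #: pre-interpolation window-center rates/delays (running method only)
    centers_pps: np.ndarray | None = None
    center_tau_ms: np.ndarray | None = None

    def drop_short(self, min_delay_ms: float = 1.0) -> "DelaySeries":
        m = self.tau_ms >= min_delay_ms
        return DelaySeries(self.rates_pps[m], self.tau_ms[m], self.method)


def running_group_delay_3pt(
    curve: PhaseCurve, cfg: GroupDelayConfig | None = None, interp_pps: float = 1.0
) -> DelaySeries:
    """Slopes of successive 3-rate windows, assigned to the window's center
    rate and linearly interpolated to a 1-pps grid.  Windows straddling an
    inadmissible step or over-wide gap are skipped; negative delays are
    discarded (like sub-1-ms delays, they are artifact-suspect)."""
    cfg = cfg or GroupDelayConfig()
    runs = monotonic_mask(curve, cfg)
    centers, taus = [], []
    for r in runs:
        for i in range(r.start + 1, r.stop - 1):
            x = curve.rates_pps[i - 1 : i + 2]
            y = curve.phase_rad[i - 1 : i + 2]
            b, _, _ = _linfit(x, y)
            tau = b / (2.0 * np.pi) * 1e3
            if tau < 0:
                continue
            centers.append(curve.rates_pps[i])
            taus.append(tau)
    if not centers:
        return DelaySeries(np.array([]), np.array([]), "running3")
    centers = np.array(centers)
    taus = np.array(taus)
    grid = np.arange(math.ceil(centers[0]), math.floor(centers[-1]) + 1, interp_pps)
    return DelaySeries(grid, np.interp(grid, centers, taus), "running3", centers, taus)


def segments_to_series(curve: PhaseCurve, segments: list[PhaseSegment]) -> DelaySeries:
    """Per-rate delays implied by piecewise segments (each significant rate in
    a segment's range takes that segment's group delay)."""
    rates, taus = [], []
    for s in segments:
        for r in curve.rates_pps[s.index]:
            rates.append(r)
            taus.append(s.tau_ms)
    return DelaySeries(np.array(rates), np.array(taus), "piecewise")


def max_sync_rates(
    series: DelaySeries,
    min_latencies_ms: dict[str, float] | None = None,
    min_delay_ms: float = 1.0,
) -> dict[str, float]:
    """Maximum synchrony rate per putative generator.

    Delays below ``min_delay_ms`` are excluded first; each generator's value
    is the highest rate whose delay is at least that generator's minimum
    latency (NaN when no rate qualifies).  By construction the rates are
    non-increasing from CN to CTX.
    """
    lat = min_latencies_ms or GENERATOR_MIN_LATENCY_MS
    kept = series.drop_short(min_delay_ms)
    out = {}
    if kept.rates_pps.size == 0:
        warnings.warn("no delays >= 1 ms; all maximum synchrony rates undefined")
        return {g: math.nan for g in lat}
    for gen, ms in lat.items():
        q = kept.rates_pps[kept.tau_ms >= ms]
        out[gen] = float(q.max()) if q.size else math.nan
    return out


def high_rate_group_delay(tf: TransferFunction, min_rate_pps: float = 500.0) -> float:
    """Group delay from a single line fit to the cumulative phase of the
    significant rates above ``min_rate_pps`` (used by the blanking-length
    evaluation, where residual artifact dominates the top rates).  NaN when
    fewer than 2 such rates are significant."""
    rates, phase = tf.significant_subset()
    m = rates > min_rate_pps
    if m.sum() < 2:
        return math.nan
    curve = unwrap_phase(rates[m], -np.asarray(phase)[m])
    b, _, _ = _linfit(curve.rates_pps, curve.phase_rad)
    return b / (2.0 * np.pi) * 1e3
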