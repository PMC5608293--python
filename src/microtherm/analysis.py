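"""Trace analytics: ramp segmentation, OLS heating-rate fits, duty cycle,
plateau stability, replicate aggregation, and the closed-form calibration
inverse.

The calibration inverse is the keystone linking the published observations
to the plant model.  At a bang-bang plateau the lobe alternates between a
net on-rate ``h - L0`` and an off-rate ``L0``, so the relay on-fraction is
``D = L0 / h`` where ``h`` is the gross rate of the interval feeding the
plateau from below.  Given the observed net slopes ``s_i = h_i - L0`` and
the observed duty ``D`` at the reference plateau (anchored on ``s_2``, the
40-42 °C interval that feeds the 42 °C plateau), this inverts in closed
form::

    L0  = D * s_2 / (1 - D)
    h_i = s_i + L0

With the published values (s = 3.375, 0.291, 0.136 °C/s; D = 0.205) this
gives L0 = 0.0750 °C/s and h = (3.450, 0.366, 0.211) °C/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from . import plant as plt
from .runner import RelayLog, Trace

__all__ = [
    "SegmentFit",
    "TraceSegment",
    "Segmentation",
    "DutyReport",
    "PlateauStats",
    "AggregateSeries",
    "AnalysisError",
    "SetpointNotReachedError",
    "segment_trace",
    "fit_segment",
    "duty_cycle",
    "plateau_stats",
    "time_to_setpoint",
    "aggregate_traces",
    "calibrate_from_observations",
]


class AnalysisError(ValueError):
    """Invalid analysis input."""


class SetpointNotReachedError(AnalysisError):
    """The trace never reaches the requested temperature."""


@dataclass(frozen=True)
class SegmentFit:
    """OLS fit of one ramp segment: T = intercept + slope * t."""

    t_low: float
    t_high: float
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    p_value: float = math.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise AnalysisError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.n_points < 2:
            raise AnalysisError("a segment fit needs at least 2 points")


@dataclass(frozen=True)
class TraceSegment:
    """Rows of a trace belonging to one ramp between two breakpoints."""

    t_low: float
    t_high: float
    times: np.ndarray
    temps: np.ndarray
    complete: bool = True

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Segmentation:
    """Ramp segments plus a flag for breakpoints that were never reached."""

    segments: tuple[TraceSegment, ...]
    truncated: bool = False


@dataclass(frozen=True)
class DutyReport:
    """Relay on-time fraction over a window."""

    window: tuple[float, float]
    on_fraction: float
    n_cycles: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.on_fraction <= 1.0:
            raise AnalysisError(f"on_fraction out of [0, 1]: {self.on_fraction}")


@dataclass(frozen=True)
class PlateauStats:
    """Stability of a held plateau: mean, SD, and the worst excursion
    beyond the hysteresis band ``[setpoint - band, setpoint]``."""

    mean: float
    sd: float
    max_excursion: float


@dataclass(frozen=True)
class AggregateSeries:
    """Across-replicate mean and sample SD on a common time grid."""

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int


def segment_trace(trace: Trace, breakpoints, crossing_tol: float = 0.01) -> Segmentation:
    """Split a trace into ramp segments between consecutive breakpoints.

    Segment ``k`` spans the rows from the first row at or above
    ``breakpoints[k]`` following the last excursion below it, up to (but
    excluding) the first row at or above ``breakpoints[k+1] - crossing_tol``
    — i.e. the rising ramp into the next breakpoint, excluding any dwell
    plateau spent holding ``breakpoints[k]``.  On a monotone trace this
    reduces to the plain first-crossing half-open rule.  Segmentation
    operates on the filtered channel (the controller's own view of the
    temperature).

    ``crossing_tol`` (default one 0.01 °C quantization step) makes crossing
    detection robust on decimated traces: a controller that switches off at
    the setpoint keeps the plateau a hair below it, and the brief peaks that
    do touch it fall between recorded rows.

    If a breakpoint is never reached, the last segment is returned open
    (rows to the end of the trace, ``complete=False``) and the segmentation
    is flagged ``truncated``.
    """
    bps = [float(b) for b in breakpoints]
    if len(bps) < 2 or any(b <= a for a, b in zip(bps, bps[1:])):
        raise AnalysisError("breakpoints must be strictly increasing, length >= 2")
    if crossing_tol < 0:
        raise AnalysisError("crossing_tol must be >= 0")
    if len(trace) == 0:
        raise AnalysisError("empty trace")
    filt = trace.t1_filt
    segments: list[TraceSegment] = []
    truncated = False
    for a, b in zip(bps, bps[1:]):
        above_b = np.nonzero(filt >= b - crossing_tol)[0]
        end = int(above_b[0]) if len(above_b) else len(filt)
        below_a = np.nonzero(filt[:end] < a)[0]
        if len(below_a):
            start = int(below_a[-1]) + 1
        else:
            above_a = np.nonzero(filt[:end] >= a)[0]
            start = int(above_a[0]) if len(above_a) else end
        complete = bool(len(above_b))
        segments.append(
            TraceSegment(
                t_low=a,
                t_high=b,
                times=trace.time[start:end].copy(),
                temps=filt[start:end].copy(),
                complete=complete,
            )
        )
        if not complete:
            truncated = True
            warnings.warn(
                f"breakpoint {b} °C never reached; segmentation truncated", stacklevel=2
            )
            break
    return Segmentation(segments=tuple(segments), truncated=truncated)


def fit_segment(times, temps) -> SegmentFit:
    """Ordinary least squares line fit of temperature against time.

    ``r_squared = 1 - SSR/SST``; a zero-variance response (SST = 0) is
    defined as R² = 0 with a warning.  Also reports the two-sided p-value of
    the slope's t statistic.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(temps, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise AnalysisError("times and temps must be 1-D arrays of equal length")
    if len(t) < 2:
        raise AnalysisError("need at least 2 points to fit a segment")
    if np.ptp(t) == 0:
        raise AnalysisError("all times identical; slope undefined")
    if np.ptp(y) == 0:
        warnings.warn("zero-variance response; defining R² = 0", stacklevel=2)
        return SegmentFit(
            t_low=float(y[0]), t_high=float(y[0]), slope=0.0, intercept=float(y[0]),
            r_squared=0.0, n_points=len(t), p_value=math.nan,
        )
    res = stats.linregress(t, y)
    return SegmentFit(
        t_low=float(y.min()),
        t_high=float(y.max()),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue) ** 2, 1.0),
        n_points=len(t),
        p_value=float(res.pvalue),
    )


def duty_cycle(log: RelayLog, window: tuple[float, float]) -> DutyReport:
    """Relay on-time fraction within ``window`` (boundary intervals clipped).

    The relay is taken as off before the log's first transition and as
    holding its last state afterwards, so a log ending in the ON state is
    clipped at the window end.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise AnalysisError(f"empty or inverted window {window}")
    if len(log) == 0:
        return DutyReport(window=(t0, t1), on_fraction=0.0, n_cycles=0)
    on_time = 0.0
    n_cycles = 0
    for a, b in log.on_intervals(until=t1):
        lo, hi = max(a, t0), min(b, t1)
        if hi > lo:
            on_time += hi - lo
            n_cycles += 1
    return DutyReport(window=(t0, t1), on_fraction=on_time / (t1 - t0), n_cycles=n_cycles)


def plateau_stats(
    trace: Trace, window: tuple[float, float], setpoint: float, band: float
) -> PlateauStats:
    """Mean/SD of the filtered temperature over a plateau window, plus the
    maximum excursion beyond the hysteresis band ``[setpoint - band, setpoint]``."""
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise AnalysisError(f"empty or inverted window {window}")
    mask = (trace.time >= t0) & (trace.time <= t1)
    if not np.any(mask):
        raise AnalysisError(f"no trace rows inside window {window}")
    y = trace.t1_filt[mask]
    above = y - setpoint
    below = (setpoint - band) - y
    excursion = max(0.0, float(np.max(np.maximum(above, below))))
    return PlateauStats(mean=float(y.mean()), sd=float(y.std()), max_excursion=excursion)


def time_to_setpoint(trace: Trace, setpoint: float) -> float:
    """Seconds from the first relay-on to the first filtered crossing of
    ``setpoint``; 0 if the trace already starts at or above it."""
    if len(trace) == 0:
        raise AnalysisError("empty trace")
    crossed = np.nonzero(trace.t1_filt >= setpoint)[0]
    if len(crossed) == 0:
        raise SetpointNotReachedError(f"trace never reaches {setpoint} °C")
    if crossed[0] == 0:
        return 0.0
    on = np.nonzero(trace.relay)[0]
    if len(on) == 0:
        raise AnalysisError("relay never on; ramp start undefined")
    return float(trace.time[crossed[0]] - trace.time[on[0]])


def aggregate_traces(traces, grid, channel: str = "t1_filt") -> AggregateSeries:
    """Per-time mean and sample SD (n−1 denominator) across replicate traces,
    linearly interpolated onto a common time grid."""
    grid = np.asarray(grid, dtype=float)
    traces = list(traces)
    if not traces:
        raise AnalysisError("empty trace list")
    if grid.ndim != 1 or len(grid) == 0:
        raise AnalysisError("grid must be a non-empty 1-D array")
    rows = []
    for tr in traces:
        if grid[0] < tr.time[0] - 1e-12 or grid[-1] > tr.time[-1] + 1e-12:
            raise AnalysisError(
                f"grid [{grid[0]}, {grid[-1]}] outside trace span "
                f"[{tr.time[0]}, {tr.time[-1]}]"
            )
        rows.append(np.interp(grid, tr.time, getattr(tr, channel)))
    values = np.stack(rows)
    n = len(traces)
    sd = values.std(axis=0, ddof=1) if n > 1 else np.zeros(len(grid))
    return AggregateSeries(grid=grid, mean=values.mean(axis=0), sd=sd, n=n)


def calibrate_from_observations(
    net_slopes,
    duty: float,
    breakpoints,
    anchor_index: int = 1,
    extend_last: bool = True,
    **plant_kwargs,
) -> plt.PlantParams:
    """Invert the constant-loss plant from observed slopes and duty cycle.

    ``net_slopes[i]`` is the observed ramp slope over
    ``[breakpoints[i], breakpoints[i+1])``; ``duty`` the relay on-fraction at
    the plateau fed by interval ``anchor_index`` (default: the second
    interval, whose upper breakpoint is the reference plateau).  Returns
    plant parameters with ``L0 = duty·s_a/(1−duty)`` and gross rates
    ``h_i = s_i + L0``.  With ``extend_last`` the final interval's upper
    bound is opened to +inf so small controller overshoots above the last
    breakpoint stay covered.

    ``duty = 0`` is the lossless limit (L0 = 0, h_i = s_i).
    """
    slopes = [float(s) for s in net_slopes]
    bps = [float(b) for b in breakpoints]
    if not 0.0 <= duty < 1.0:
        raise AnalysisError(f"duty must lie in [0, 1), got {duty}")
    if any(s <= 0 for s in slopes):
        raise AnalysisError("net slopes must be positive")
    if len(bps) != len(slopes) + 1:
        raise AnalysisError("need exactly len(net_slopes) + 1 breakpoints")
    if not 0 <= anchor_index < len(slopes):
        raise AnalysisError(f"anchor_index {anchor_index} out of range")
    loss = duty * slopes[anchor_index] / (1.0 - duty)
    uppers = bps[1:]
    if extend_last:
        uppers = uppers[:-1] + [math.inf]
    heat_rates = tuple(
        (lo, hi, s + loss) for lo, hi, s in zip(bps[:-1], uppers, slopes)
    )
    return plt.PlantParams(heat_rates=heat_rates, loss_rate=loss, **plant_kwargs)
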