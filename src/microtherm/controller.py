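"""The virtual-instrument control loop: moving-average filter, hysteresis
relay comparator, and the staged dwell timer.

This re-implements the LabView virtual instrument that drove the physical
rig: raw thermocouple samples are smoothed by a moving average over 10
samples, the smoothed value is compared against a 0.1 °C hysteresis band
anchored at the current stage's setpoint, and the comparison switches the
magnetron relay.  A protocol is an ordered list of stages
``(setpoint °C, dwell s)``; a stage's dwell clock starts the first time the
filtered temperature reaches the setpoint, and the controller advances to
the next stage (or completes) once the dwell has elapsed.

Band placement: the relay switches ON below ``setpoint - band_width``, OFF
at or above ``setpoint``, and holds its previous command inside the band.
Anchoring the upper limit at the setpoint makes "reaching the desired
temperature" and "switching off" coincide.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field as dc_field

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "ControllerError",
    "ProtocolCompleteError",
    "new_state",
    "filter_update",
    "decide",
    "stage_advance",
]


class ControllerError(ValueError):
    """Invalid controller configuration or input."""


class ProtocolCompleteError(ControllerError):
    """The stage machine was advanced after the protocol already completed."""


@dataclass(frozen=True)
class ControllerConfig:
    """Virtual-instrument parameters.

    ``filter_window`` raw samples per moving average (10), ``band_width`` the
    hysteresis band (0.1 °C), ``control_interval`` raw samples between relay
    decisions (one decision per full filter window by default, i.e. 1 kHz at
    10 kHz sampling), ``stages`` the ordered ``(setpoint °C, dwell s)`` list
    (reference protocol: 40/42/44 °C), and ``control_channels`` the sensor
    channels averaged into the control signal (the two target-lobe probes).
    """

    filter_window: int = 10
    band_width: float = 0.1
    control_interval: int = 10
    stages: tuple[tuple[float, float], ...] = ((40.0, 20.0), (42.0, 20.0), (44.0, 20.0))
    control_channels: tuple[str, ...] = ("T1a", "T1b")

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "stages", tuple((float(sp), float(dw)) for sp, dw in self.stages)
        )
        object.__setattr__(self, "control_channels", tuple(self.control_channels))
        if self.filter_window < 1:
            raise ControllerError("filter_window must be >= 1")
        if not self.band_width > 0:
            raise ControllerError("band_width must be positive")
        if self.control_interval < 1:
            raise ControllerError("control_interval must be >= 1")
        setpoints = [sp for sp, _ in self.stages]
        if any(b <= a for a, b in zip(setpoints, setpoints[1:])):
            raise ControllerError("stage setpoints must be strictly increasing")
        if any(dw < 0 for _, dw in self.stages):
            raise ControllerError("dwell times must be >= 0")
        if not self.control_channels:
            raise ControllerError("control_channels must be non-empty")


@dataclass
class ControllerState:
    """Mutable run-time state of the virtual instrument."""

    window: int
    buffer: deque = dc_field(default_factory=deque)
    relay_cmd: bool = False
    stage_index: int = 0
    dwell_started_at: float | None = None
    complete: bool = False


def new_state(config: ControllerConfig) -> ControllerState:
    """Fresh controller state; completes immediately for an empty stage list."""
    return ControllerState(
        window=config.filter_window,
        buffer=deque(maxlen=config.filter_window),
        complete=not config.stages,
    )


def filter_update(state: ControllerState, raw: float) -> float:
    """Push one raw sample into the moving-average buffer; return the mean.

    The buffer evicts its oldest sample beyond ``filter_window``; before the
    window first fills, the mean is over the samples seen so far.  The mean
    uses exact (compensated) summation, so it is invariant to the order of
    the buffer contents and always bounded by their min/max.
    """
    if not math.isfinite(raw):
        raise ControllerError(f"raw sample must be finite, got {raw!r}")
    state.buffer.append(float(raw))
    return math.fsum(state.buffer) / len(state.buffer)


def decide(filtered: float, setpoint: float, band_width: float, prev_cmd: bool) -> bool:
    """Hysteresis relay law.

    ON if ``filtered < setpoint - band_width``; OFF if ``filtered >= setpoint``;
    otherwise hold the previous command.  Monotone: raising ``filtered`` can
    only switch on -> off, never off -> on.
    """
    if not band_width > 0:
        raise ControllerError("band_width must be positive")
    if filtered < setpoint - band_width:
        return True
    if filtered >= setpoint:
        return False
    return prev_cmd


def stage_advance(
    state: ControllerState, filtered: float, clock: float, config: ControllerConfig
) -> str | None:
    """Advance the staged dwell machine by one observation.

    Starts the current stage's dwell clock the first time ``filtered``
    reaches the stage setpoint; once ``clock - dwell_started_at`` reaches the
    dwell duration, moves to the next stage (resetting the dwell) or marks
    the protocol complete after the last stage.

    Returns ``"dwell_started"``, ``"advanced"``, ``"complete"`` or ``None``,
    and raises :class:`ProtocolCompleteError` if called after completion.
    """
    if state.complete:
        raise ProtocolCompleteError("protocol already complete")
    setpoint, dwell = config.stages[state.stage_index]
    if state.dwell_started_at is None:
        if filtered >= setpoint:
            state.dwell_started_at = clock
            if dwell > 0:
                return "dwell_started"
            # zero dwell: fall through to advance immediately
        else:
            return None
    if clock - state.dwell_started_at >= dwell:
        state.dwell_started_at = None
        state.stage_index += 1
        if state.stage_index >= len(config.stages):
            state.complete = True
            return "complete"
        return "advanced"
    return None
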