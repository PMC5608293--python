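"""Closed-loop experiment runner and file I/O.

``run_experiment`` wires the lumped plant, the thermocouple model and the
virtual-instrument controller into a seeded simulation of one staged
heating protocol, producing a decimated :class:`Trace` and a
:class:`RelayLog` of magnetron switching events.

Timing scheme (all rates must be mutually divisible):

* the plant advances by ``sim_dt`` (default 1 ms, explicit Euler);
* sensors emit ``sample_rate_hz * sim_dt`` readings per plant step
  (zero-order hold of the current truth within a step);
* a relay decision is taken every ``control_interval`` raw samples
  (default: one decision per full filter window, 1 kHz at 10 kHz sampling);
* the trace records one row every ``1 / record_rate_hz`` (default 100 Hz).

Decision and transition timestamps are quantized to the plant step grid.
The protocol seed is fanned out into four independent per-channel random
streams (T1a, T1b, T2a, T2b), so a given seed reproduces bit-identical
traces and relay logs.
"""

from __future__ import annotations

import io
import json
import math
import tomllib
from dataclasses import dataclass, field as dc_field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import controller as ctl
from . import plant as plt
from . import sensing as sns

__all__ = [
    "REFERENCE_NET_SLOPES",
    "REFERENCE_DUTY",
    "REFERENCE_BREAKPOINTS",
    "TRACE_COLUMNS",
    "ProtocolSpec",
    "Trace",
    "RelayLog",
    "RunnerError",
    "UnreachableSetpointError",
    "ProtocolTimeoutError",
    "TraceParseError",
    "TraceHeaderError",
    "TraceMonotonicityError",
    "TraceValueError",
    "run_experiment",
    "write_trace",
    "read_trace",
    "write_relay_log",
    "read_relay_log",
    "load_config",
    "write_plant_config",
    "reference_config",
]

#: Published calibration observations of the physical rig: net ramp slopes
#: (°C/s) over 30-40 / 40-42 / 42-44 °C, plateau duty cycle, and the
#: breakpoints delimiting the rate intervals.
REFERENCE_NET_SLOPES = (3.375, 0.291, 0.136)
REFERENCE_DUTY = 0.205
REFERENCE_BREAKPOINTS = (30.0, 40.0, 42.0, 44.0)

TRACE_COLUMNS = ("time_s", "T1_raw", "T1_filt", "T2", "relay")
RELAY_COLUMNS = ("time_s", "state")


class RunnerError(ValueError):
    """Invalid protocol configuration or an impossible protocol."""


class UnreachableSetpointError(RunnerError):
    """A stage setpoint cannot be reached by the configured plant."""


class ProtocolTimeoutError(RunnerError):
    """The simulation hit the wall-time cap before the protocol completed."""


class TraceParseError(ValueError):
    """Base class for malformed trace / relay-log files."""


class TraceHeaderError(TraceParseError):
    """Missing or wrong CSV header row."""


class TraceMonotonicityError(TraceParseError):
    """Time column is not strictly increasing."""


class TraceValueError(TraceParseError):
    """Non-numeric or otherwise invalid cell values."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Experiment-level settings: initial temperatures, seed, and rates.

    ``initial_T1`` defaults to 30 °C (the exteriorised lobe cools to ~4 °C
    below body temperature during dissection and wrapping); ``initial_T2``
    to the 37 °C body baseline.  ``max_sim_time`` caps the simulated
    duration to guarantee termination.
    """

    initial_T1: float = 30.0
    initial_T2: float = 37.0
    seed: int = 0
    sim_dt: float = 1e-3
    record_rate_hz: float = 100.0
    max_sim_time: float = 300.0

    def __post_init__(self) -> None:
        if not self.sim_dt > 0:
            raise RunnerError("sim_dt must be positive")
        if not self.record_rate_hz > 0:
            raise RunnerError("record_rate_hz must be positive")
        if not self.max_sim_time > 0:
            raise RunnerError("max_sim_time must be positive")


@dataclass
class Trace:
    """Decimated closed-loop recording.

    Parallel arrays: time (s), last raw control sample (°C), filtered
    control temperature (°C), body/control temperature (°C), relay command.
    ``metadata`` carries the seed, configs and stage episode times.

    Simulated traces additionally carry ``t1_true``, the plant's ground-truth
    lobe temperature — available in memory for validation but not part of
    the serialized CSV schema (a physical rig has no such channel).
    """

    time: np.ndarray
    t1_raw: np.ndarray
    t1_filt: np.ndarray
    t2: np.ndarray
    relay: np.ndarray
    metadata: dict = dc_field(default_factory=dict)
    t1_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(self.time, dtype=float),
            np.asarray(self.t1_raw, dtype=float),
            np.asarray(self.t1_filt, dtype=float),
            np.asarray(self.t2, dtype=float),
            np.asarray(self.relay, dtype=bool),
        ]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise TraceValueError("trace series must have equal lengths")
        if n > 1 and not np.all(np.diff(arrays[0]) > 0):
            raise TraceMonotonicityError("trace time must be strictly increasing")
        self.time, self.t1_raw, self.t1_filt, self.t2, self.relay = arrays
        if self.t1_true is not None:
            truth = np.asarray(self.t1_true, dtype=float)
            if len(truth) != n:
                raise TraceValueError("t1_true length mismatch")
            self.t1_true = truth

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "T1_raw": self.t1_raw,
                "T1_filt": self.t1_filt,
                "T2": self.t2,
                "relay": self.relay.astype(int),
            }
        )


@dataclass
class RelayLog:
    """Ordered magnetron relay transitions ``(time s, new state)``.

    The relay is off before the first transition; the state after the last
    transition persists.  Times strictly increase and states alternate.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=bool)
        if len(self.times) != len(self.states):
            raise TraceValueError("relay log times/states must have equal lengths")
        if len(self.times) > 1:
            if not np.all(np.diff(self.times) > 0):
                raise TraceMonotonicityError("relay log times must be strictly increasing")
            if np.any(self.states[1:] == self.states[:-1]):
                raise TraceValueError("relay log states must alternate")

    def __len__(self) -> int:
        return len(self.times)

    def on_intervals(self, until: float = math.inf) -> list[tuple[float, float]]:
        """Closed relay-on intervals, an unterminated final ON clipped at ``until``."""
        out: list[tuple[float, float]] = []
        for i, (t, s) in enumerate(zip(self.times, self.states)):
            if s:
                end = self.times[i + 1] if i + 1 < len(self.times) else until
                out.append((float(t), float(end)))
        return out


class _RelayLogBuilder:
    """Accumulates transitions; collapses same-time toggles (sub-step pulses)."""

    def __init__(self) -> None:
        self.times: list[float] = []
        self.states: list[bool] = []

    def _current(self) -> bool:
        return self.states[-1] if self.states else False

    def set(self, time: float, state: bool) -> None:
        if state == self._current():
            return
        if self.times and self.times[-1] == time:
            self.times.pop()
            self.states.pop()
            if state == self._current():
                return
        self.times.append(time)
        self.states.append(state)

    def build(self) -> RelayLog:
        return RelayLog(np.array(self.times), np.array(self.states))


def _check_rates(protocol: ProtocolSpec, sensor: sns.SensorSpec, ctrl: ctl.ControllerConfig):
    """Validate rate divisibility; return (samples per step, record stride)."""

    def _as_int(x: float, what: str) -> int:
        n = round(x)
        if n < 1 or abs(x - n) > 1e-9:
            raise RunnerError(f"{what} must be a positive integer, got {x}")
        return n

    m = _as_int(sensor.sample_rate_hz * protocol.sim_dt, "samples per plant step")
    rec = _as_int(1.0 / (protocol.record_rate_hz * protocol.sim_dt), "plant steps per record")
    if protocol.record_rate_hz > sensor.sample_rate_hz:
        raise RunnerError("record_rate_hz must not exceed sample_rate_hz")
    if m % ctrl.control_interval and ctrl.control_interval % m:
        raise RunnerError(
            f"control_interval ({ctrl.control_interval}) and samples per step ({m}) "
            "must be divisible one way or the other"
        )
    return m, rec


def run_experiment(
    protocol: ProtocolSpec,
    plant_params: plt.PlantParams,
    sensor: sns.SensorSpec,
    ctrl_config: ctl.ControllerConfig,
) -> tuple[Trace, RelayLog]:
    """Simulate one staged closed-loop heating experiment.

    Deterministic given ``protocol.seed``.  Raises
    :class:`UnreachableSetpointError` (naming the stage) if a setpoint cannot
    be reached by the configured plant, and :class:`ProtocolTimeoutError` if
    the protocol has not completed within ``protocol.max_sim_time`` simulated
    seconds.
    """
    m, rec_every = _check_rates(protocol, sensor, ctrl_config)
    dt = protocol.sim_dt

    # feasibility: every setpoint must be reachable under continuous power
    for i, (setpoint, _) in enumerate(ctrl_config.stages):
        if setpoint <= protocol.initial_T1:
            continue
        try:
            plt.predict_ramp_time(plant_params, protocol.initial_T1, setpoint)
        except plt.PlantError as exc:
            raise UnreachableSetpointError(
                f"stage {i} (setpoint {setpoint} °C) unreachable: {exc}"
            ) from exc

    streams = {
        ch: np.random.Generator(np.random.PCG64(child))
        for ch, child in zip(sns.CHANNELS, np.random.SeedSequence(protocol.seed).spawn(4))
    }
    control_channels = ctrl_config.control_channels
    t2_channels = [ch for ch in sns.CHANNELS if ch not in control_channels]
    noiseless = sensor.noise_sd == 0 and sensor.spike_prob == 0

    state = plt.PlantState(
        time=0.0,
        T_lobe=protocol.initial_T1,
        T_body=protocol.initial_T2,
        T_water=plant_params.chamber_temp,
        relay_on=False,
    )
    cstate = ctl.new_state(ctrl_config)
    log = _RelayLogBuilder()
    rows_t, rows_raw, rows_filt, rows_t2, rows_relay = [], [], [], [], []
    rows_true: list[float] = []
    episodes: list[dict] = []
    sample_count = 0
    k = 0
    max_steps = int(round(protocol.max_sim_time / dt))

    def _sample_t2(t: float) -> float:
        vals = [float(sns.sample_values(state.T_body, sensor, streams[ch], 1)[0]) for ch in t2_channels]
        return math.fsum(vals) / len(vals)

    filtered = protocol.initial_T1
    raw_last = protocol.initial_T1
    while True:
        t = k * dt
        truth = state.T_lobe
        if noiseless:
            raw_samples = [sns.quantize(truth, sensor.resolution)] * m
        else:
            per_channel = np.stack(
                [sns.sample_values(truth, sensor, streams[ch], m) for ch in control_channels]
            )
            raw_samples = per_channel.mean(axis=0).tolist()
        for v in raw_samples:
            filtered = ctl.filter_update(cstate, v)
            raw_last = v
            sample_count += 1
            if sample_count % ctrl_config.control_interval == 0 and not cstate.complete:
                setpoint = ctrl_config.stages[cstate.stage_index][0]
                cmd = ctl.decide(filtered, setpoint, ctrl_config.band_width, cstate.relay_cmd)
                if cmd != cstate.relay_cmd:
                    log.set(t, cmd)
                    cstate.relay_cmd = cmd
                event = ctl.stage_advance(cstate, filtered, t, ctrl_config)
                if event == "dwell_started":
                    episodes.append(
                        {"stage": cstate.stage_index, "setpoint": setpoint,
                         "dwell_start": t, "stage_end": None}
                    )
                elif event in ("advanced", "complete"):
                    if episodes and episodes[-1]["stage_end"] is None:
                        episodes[-1]["stage_end"] = t
                    else:  # zero dwell: start and end coincide
                        episodes.append(
                            {"stage": cstate.stage_index - 1, "setpoint": setpoint,
                             "dwell_start": t, "stage_end": t}
                        )
        if cstate.complete and cstate.relay_cmd:
            cstate.relay_cmd = False
            log.set(t, False)
        if cstate.complete or k % rec_every == 0:
            rows_t.append(t)
            rows_raw.append(raw_last)
            rows_filt.append(filtered)
            rows_t2.append(_sample_t2(t))
            rows_relay.append(cstate.relay_cmd)
            rows_true.append(truth)
        if cstate.complete:
            break
        if k >= max_steps:
            raise ProtocolTimeoutError(
                f"protocol did not complete within {protocol.max_sim_time} s "
                f"(stuck in stage {cstate.stage_index} of {len(ctrl_config.stages)})"
            )
        state = plt.step(state, plant_params, cstate.relay_cmd, dt)
        k += 1

    metadata = {
        "seed": protocol.seed,
        "protocol": asdict(protocol),
        "sensor": asdict(sensor),
        "controller": {
            "filter_window": ctrl_config.filter_window,
            "band_width": ctrl_config.band_width,
            "control_interval": ctrl_config.control_interval,
            "stages": [list(s) for s in ctrl_config.stages],
            "control_channels": list(ctrl_config.control_channels),
        },
        "plant": {
            "heat_rates": [list(iv) for iv in plant_params.heat_rates],
            "loss_rate": plant_params.loss_rate,
            "chamber_temp": plant_params.chamber_temp,
            "body_baseline": plant_params.body_baseline,
            "body_drift": plant_params.body_drift,
        },
        "stages": episodes,
    }
    trace = Trace(
        time=np.array(rows_t),
        t1_raw=np.array(rows_raw),
        t1_filt=np.array(rows_filt),
        t2=np.array(rows_t2),
        relay=np.array(rows_relay, dtype=bool),
        metadata=metadata,
        t1_true=np.array(rows_true),
    )
    return trace, log.build()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def write_trace(path: str | Path, trace: Trace) -> None:
    """Write a trace as CSV (columns ``time_s,T1_raw,T1_filt,T2,relay``).

    Metadata is preserved in a leading ``# meta:`` comment line; values are
    printed with 6 significant digits, LF line endings, UTF-8.
    """
    path = Path(path)
    buf = io.StringIO()
    if trace.metadata:
        buf.write("# meta: " + json.dumps(trace.metadata, sort_keys=True) + "\n")
    trace.to_frame().to_csv(buf, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _read_csv(path: Path, columns: tuple[str, ...]) -> tuple[pd.DataFrame, dict]:
    text = path.read_text(encoding="utf-8")
    metadata: dict = {}
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if line.startswith("# meta:"):
                metadata = json.loads(line[len("# meta:"):])
        else:
            break
    if body_start >= len(lines):
        raise TraceHeaderError(f"{path}: no header row")
    header = [c.strip() for c in lines[body_start].split(",")]
    if header != list(columns):
        raise TraceHeaderError(
            f"{path}: expected header {','.join(columns)!r}, got {lines[body_start]!r}"
        )
    try:
        frame = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
        frame = frame.astype(float)
    except (ValueError, TypeError) as exc:
        raise TraceValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(frame.to_numpy())):
        raise TraceValueError(f"{path}: non-finite cell")
    return frame, metadata


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV written by :func:`write_trace` (or hand-built)."""
    frame, metadata = _read_csv(Path(path), TRACE_COLUMNS)
    times = frame["time_s"].to_numpy()
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise TraceMonotonicityError(f"{path}: time_s not strictly increasing")
    return Trace(
        time=times,
        t1_raw=frame["T1_raw"].to_numpy(),
        t1_filt=frame["T1_filt"].to_numpy(),
        t2=frame["T2"].to_numpy(),
        relay=frame["relay"].to_numpy().astype(bool),
        metadata=metadata,
    )


def write_relay_log(path: str | Path, log: RelayLog) -> None:
    """Write relay transitions as CSV (columns ``time_s,state``)."""
    frame = pd.DataFrame({"time_s": log.times, "state": log.states.astype(int)})
    Path(path).write_text(
        frame.to_csv(index=False, float_format=_FLOAT_FMT, lineterminator="\n"),
        encoding="utf-8",
    )


def read_relay_log(path: str | Path) -> RelayLog:
    """Read a relay-transition CSV written by :func:`write_relay_log`."""
    frame, _ = _read_csv(Path(path), RELAY_COLUMNS)
    times = frame["time_s"].to_numpy()
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise TraceMonotonicityError(f"{path}: time_s not strictly increasing")
    return RelayLog(times=times, states=frame["state"].to_numpy().astype(bool))


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def _plant_from_table(table: dict) -> plt.PlantParams:
    table = dict(table)
    magnetron = plt.MagnetronSpec(**table.pop("magnetron", {}))
    if "net_slopes" in table:
        # calibration form: observed net slopes + plateau duty cycle
        from .analysis import calibrate_from_observations

        slopes = tuple(table.pop("net_slopes"))
        duty = table.pop("duty")
        breakpoints = tuple(table.pop("breakpoints"))
        anchor = table.pop("anchor_index", 1)
        return calibrate_from_observations(
            slopes, duty, breakpoints, anchor_index=anchor, magnetron=magnetron, **table
        )
    heat_rates = tuple(tuple(iv) for iv in table.pop("heat_rates"))
    return plt.PlantParams(heat_rates=heat_rates, magnetron=magnetron, **table)


def load_config(
    path_or_text: str | Path,
) -> tuple[plt.PlantParams, sns.SensorSpec, ctl.ControllerConfig, ProtocolSpec]:
    """Load a rig configuration from a TOML file.

    The file has ``[plant]``, ``[sensor]``, ``[controller]`` and
    ``[protocol]`` sections.  The plant may be given either directly
    (``heat_rates`` + ``loss_rate``) or in calibration form (``net_slopes``,
    ``duty``, ``breakpoints``), which is inverted in closed form.
    """
    path = Path(path_or_text)
    data = tomllib.loads(path.read_text(encoding="utf-8"))
    missing = {"plant", "sensor", "controller", "protocol"} - set(data)
    if missing:
        raise RunnerError(f"{path}: missing config sections {sorted(missing)}")
    ctrl_table = dict(data["controller"])
    if "stages" in ctrl_table:
        ctrl_table["stages"] = tuple(tuple(s) for s in ctrl_table["stages"])
    return (
        _plant_from_table(data["plant"]),
        sns.SensorSpec(**data["sensor"]),
        ctl.ControllerConfig(**ctrl_table),
        ProtocolSpec(**data["protocol"]),
    )


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isinf(value):
            return "inf" if value > 0 else "-inf"
        return repr(value)
    if isinstance(value, int):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {value!r} to TOML")


def write_plant_config(path: str | Path, params: plt.PlantParams) -> None:
    """Write a ``[plant]`` TOML section for a calibrated plant."""
    lines = ["[plant]"]
    lines.append(f"heat_rates = {_toml_value([list(iv) for iv in params.heat_rates])}")
    for name in ("loss_rate", "chamber_temp", "body_baseline", "body_drift",
                 "water_mass_g", "water_power_fraction"):
        lines.append(f"{name} = {_toml_value(getattr(params, name))}")
    lines.append("")
    lines.append("[plant.magnetron]")
    for name in ("frequency_mhz", "power_w", "filament_v", "filament_a", "anode_v"):
        lines.append(f"{name} = {_toml_value(getattr(params.magnetron, name))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def reference_config() -> tuple[plt.PlantParams, sns.SensorSpec, ctl.ControllerConfig, ProtocolSpec]:
    """The reference rig: plant calibrated from the published slopes and duty.

    Noiseless sensing, 0.1 °C band, 10-sample filter window, stages
    40/42/44 °C with 20 s dwells, 1 ms plant step, 100 Hz trace recording.
    """
    from .analysis import calibrate_from_observations

    params = calibrate_from_observations(
        REFERENCE_NET_SLOPES, REFERENCE_DUTY, REFERENCE_BREAKPOINTS
    )
    return (
        params,
        sns.SensorSpec(noise_sd=0.0),
        ctl.ControllerConfig(),
        ProtocolSpec(),
    )


def packaged_reference_path():
    """Path-like handle to the packaged reference TOML config."""
    return resources.files("microtherm.data") / "reference.toml"
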