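"""Lumped-parameter thermal plant of the single-lobe microwave hyperthermia rig.

The physical system is a modified microwave oven heating the exteriorised
middle liver lobe of a rat while the rest of the animal is wrapped in a
grounded aluminium shield and a 100 ml water container absorbs most of the
magnetron output.  The plant reduces this to three thermal compartments:

``T_lobe``
    The heated target lobe.  While the magnetron relay is closed the lobe
    gains heat at a gross, temperature-interval-dependent rate ``h_i``
    (°C/s); whenever it is warmer than the oven chamber it loses heat at a
    constant rate ``L0`` (°C/s).  The observable ramp slope under continuous
    power is therefore the net rate ``h_i - L0``.
``T_body``
    The shielded animal core.  It is not microwave-heated and drifts slowly
    downward (the chamber is at room temperature), clamped at the chamber
    temperature.
``T_water``
    The water energy trap.  Passive bookkeeping of absorbed magnetron
    energy with the specific heat of water; it does not feed back on the
    lobe.

The constant-loss model (rather than Newtonian, temperature-proportional
cooling) is chosen because it makes the plateau duty cycle analytically
consistent with the ramp slopes: at a bang-bang plateau the on-fraction is
exactly ``L0 / h`` for the interval feeding the plateau from below.  Over
the narrow 30-44 °C working range the distinction is immaterial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WATER_SPECIFIC_HEAT",
    "MagnetronSpec",
    "PlantParams",
    "PlantState",
    "PlantError",
    "UncoveredIntervalError",
    "NoProgressError",
    "step",
    "predict_ramp_time",
]

#: Specific heat of water, J/(g·°C), used by the energy-trap bookkeeping.
WATER_SPECIFIC_HEAT = 4.184


class PlantError(ValueError):
    """Invalid plant parameters or an invalid plant operation."""


class UncoveredIntervalError(PlantError):
    """The lobe temperature fell outside every configured heat-rate interval."""


class NoProgressError(PlantError):
    """A requested ramp crosses an interval whose net heating rate is <= 0."""


@dataclass(frozen=True)
class MagnetronSpec:
    """Electrical metadata of the magnetron (config only, not used thermally).

    Defaults describe a commercial 2450 MHz oven tube: 1000 W output,
    4.4 V / 14 A filament, 4500 V anode.
    """

    frequency_mhz: float = 2450.0
    power_w: float = 1000.0
    filament_v: float = 4.4
    filament_a: float = 14.0
    anode_v: float = 4500.0

    def __post_init__(self) -> None:
        for name in ("frequency_mhz", "power_w", "filament_v", "filament_a", "anode_v"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise PlantError(f"MagnetronSpec.{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class PlantParams:
    """Calibrated parameters of the lumped thermal plant.

    Parameters
    ----------
    heat_rates
        Ordered, contiguous, non-overlapping temperature intervals with their
        gross relay-on heating rates: ``(lower °C, upper °C, h_i °C/s)``.
        Intervals are half-open ``[lower, upper)``; the last upper bound may
        be ``inf``.
    loss_rate
        Constant heat-loss rate ``L0`` (°C/s), active only while the lobe is
        warmer than the chamber.
    chamber_temp
        Oven chamber (room) temperature, °C.
    body_baseline
        Initial shielded-body core temperature, °C.
    body_drift
        Body temperature drift, °C/s, must be <= 0 (the shielded animal cools
        slightly; a few °C over an experiment).
    water_mass_g, water_power_fraction
        Mass of the water energy trap and the fraction of magnetron power it
        absorbs.  The default fraction 100/101 reads the power split as
        mass-proportional across ~100 g of water and ~1 g of lobe.
    """

    heat_rates: tuple[tuple[float, float, float], ...]
    loss_rate: float = 0.0
    chamber_temp: float = 20.0
    body_baseline: float = 37.0
    body_drift: float = -0.03
    water_mass_g: float = 100.0
    water_power_fraction: float = 100.0 / 101.0
    magnetron: MagnetronSpec = field(default_factory=MagnetronSpec)

    def __post_init__(self) -> None:
        if not self.heat_rates:
            raise PlantError("heat_rates must contain at least one interval")
        rates = tuple(tuple(float(x) for x in iv) for iv in self.heat_rates)
        object.__setattr__(self, "heat_rates", rates)
        if not (math.isfinite(self.loss_rate) and self.loss_rate >= 0):
            raise PlantError(f"loss_rate must satisfy L0 >= 0, got {self.loss_rate!r}")
        prev_hi = None
        for lo, hi, h in rates:
            if not hi > lo:
                raise PlantError(f"empty heat-rate interval [{lo}, {hi})")
            if prev_hi is not None and not math.isclose(lo, prev_hi, rel_tol=0, abs_tol=1e-9):
                raise PlantError(
                    f"heat-rate intervals must be contiguous and ordered: gap at {prev_hi} -> {lo}"
                )
            if not h > self.loss_rate:
                raise PlantError(
                    f"gross rate {h} °C/s on [{lo}, {hi}) does not exceed loss rate {self.loss_rate}"
                )
            prev_hi = hi
        if not 0.0 <= self.water_power_fraction <= 1.0:
            raise PlantError("water_power_fraction must lie in [0, 1]")
        if self.body_drift > 0:
            raise PlantError("body_drift must be <= 0 (the shielded body never warms)")
        if self.water_mass_g <= 0:
            raise PlantError("water_mass_g must be positive")

    @property
    def t_min(self) -> float:
        return self.heat_rates[0][0]

    @property
    def t_max(self) -> float:
        return self.heat_rates[-1][1]

    def covers(self, temp: float) -> bool:
        """Whether ``temp`` lies inside the union of heat-rate intervals."""
        return self.t_min <= temp < self.t_max

    def gross_rate(self, temp: float) -> float:
        """Gross relay-on heating rate h_i at lobe temperature ``temp``."""
        for lo, hi, h in self.heat_rates:
            if lo <= temp < hi:
                return h
        raise UncoveredIntervalError(
            f"lobe temperature {temp:.4f} °C outside covered range "
            f"[{self.t_min}, {self.t_max}) while relay on"
        )


@dataclass(frozen=True)
class PlantState:
    """Instantaneous plant state: time (s) and compartment temperatures (°C)."""

    time: float = 0.0
    T_lobe: float = 30.0
    T_body: float = 37.0
    T_water: float = 20.0
    relay_on: bool = False

    def __post_init__(self) -> None:
        for name in ("time", "T_lobe", "T_body", "T_water"):
            if not math.isfinite(getattr(self, name)):
                raise PlantError(f"PlantState.{name} must be finite")


def step(state: PlantState, params: PlantParams, relay_on: bool, dt: float) -> PlantState:
    """Advance the plant by one explicit-Euler step of length ``dt`` seconds.

    The step is exact (not just first-order) whenever the rates are constant
    across the step, which is the operating regime: rates are piecewise
    constant in ``T_lobe`` and a step rarely straddles an interval breakpoint.
    Breakpoint crossings within a step are not sub-resolved, so the
    discretisation error is bounded by one step.

    Raises
    ------
    PlantError
        For non-positive ``dt``.
    UncoveredIntervalError
        If the relay is on while ``T_lobe`` lies outside every configured
        heat-rate interval (signals a missing interval in the calibration).
    """
    if not dt > 0:
        raise PlantError(f"dt must be positive, got {dt!r}")
    T = state.T_lobe
    rate = 0.0
    if relay_on:
        rate += params.gross_rate(T)
    losing = T > params.chamber_temp
    if losing:
        rate -= params.loss_rate
    T_new = T + dt * rate
    if not relay_on and losing:
        # passive cooling at constant rate stops at the chamber temperature
        T_new = max(T_new, params.chamber_temp)
    T_body = max(state.T_body + dt * params.body_drift, params.chamber_temp)
    T_water = state.T_water
    if relay_on:
        T_water += (
            params.magnetron.power_w
            * params.water_power_fraction
            / (WATER_SPECIFIC_HEAT * params.water_mass_g)
            * dt
        )
    return PlantState(
        time=state.time + dt,
        T_lobe=T_new,
        T_body=T_body,
        T_water=T_water,
        relay_on=bool(relay_on),
    )


def predict_ramp_time(params: PlantParams, t_from: float, t_to: float) -> float:
    """Closed-form continuous-time duration of a relay-on ramp ``t_from -> t_to``.

    Sums ``span / (h_i - L0)`` over every crossed interval (the loss term is
    dropped on any portion at or below the chamber temperature, where no
    passive loss applies).  Serves as the independent oracle for simulated
    ramps: a simulated continuous-on first crossing matches this within one
    time step.
    """
    if t_to < t_from:
        raise PlantError(f"t_to ({t_to}) below t_from ({t_from})")
    if t_to == t_from:
        return 0.0
    if not (params.covers(t_from) and (params.covers(t_to) or t_to == params.t_max)):
        raise UncoveredIntervalError(
            f"ramp [{t_from}, {t_to}] not within covered range [{params.t_min}, {params.t_max}]"
        )
    total = 0.0
    for lo, hi, h in params.heat_rates:
        seg_lo = max(lo, t_from)
        seg_hi = min(hi, t_to)
        if seg_hi <= seg_lo:
            continue
        # split at the chamber temperature: below it there is no passive loss
        for a, b, net in (
            (seg_lo, min(seg_hi, params.chamber_temp), h),
            (max(seg_lo, params.chamber_temp), seg_hi, h - params.loss_rate),
        ):
            if b <= a:
                continue
            if net <= 0:
                raise NoProgressError(
                    f"no net heating on [{a}, {b}) °C (h={h}, L0={params.loss_rate})"
                )
            total += (b - a) / net
    return total
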