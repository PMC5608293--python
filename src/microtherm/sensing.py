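"""Thermocouple measurement model.

Needle-mounted J-type thermocouples read the lobe and body temperatures
through a DAQ chain whose observable behaviour is reduced to three effects:
additive Gaussian noise, rare discharge-spike artifacts (false peaks from
electrical discharges in the microwave field, eliminated in the physical rig
by common grounding but kept here to exercise the control filter), and
quantization to the 0.01 °C instrument resolution.

Channel naming follows probe placement: ``T1a``/``T1b`` in the heated target
lobe, ``T2a``/``T2b`` in the control lobe and peritoneum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CHANNELS",
    "SensorSpec",
    "Reading",
    "SensorError",
    "quantize",
    "sample",
    "sample_values",
]

#: Canonical channel identifiers: two probes in the target lobe, two controls.
CHANNELS = ("T1a", "T1b", "T2a", "T2b")


class SensorError(ValueError):
    """Invalid sensor specification or measurement input."""


@dataclass(frozen=True)
class SensorSpec:
    """Measurement-chain parameters.

    ``sample_rate_hz`` defaults to 10 kHz.  ``noise_sd`` is the per-sample
    Gaussian SD in °C (0.05 °C default for stochastic runs; set to 0 for the
    noiseless reference runs).  Spikes default off because the physical rig
    eliminated them by grounding; ``spike_amp`` is an arbitrary large artifact
    amplitude since the originals were never quantified.  ``resolution`` is
    the 0.01 °C quantization step.
    """

    sample_rate_hz: float = 10_000.0
    noise_sd: float = 0.05
    spike_prob: float = 0.0
    spike_amp: float = 5.0
    resolution: float = 0.01

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise SensorError("sample_rate_hz must be positive")
        if self.noise_sd < 0:
            raise SensorError("noise_sd must be >= 0")
        if not 0.0 <= self.spike_prob < 1.0:
            raise SensorError("spike_prob must lie in [0, 1)")
        if not self.resolution > 0:
            raise SensorError("resolution must be positive")


@dataclass(frozen=True)
class Reading:
    """A single quantized temperature reading on a named channel."""

    time: float
    channel: str
    value: float


def quantize(value: float, resolution: float) -> float:
    """Round to the nearest integer multiple of ``resolution``, half away from zero."""
    n = math.floor(abs(value) / resolution + 0.5)
    return math.copysign(n * resolution, value)


def _quantize_array(values: np.ndarray, resolution: float) -> np.ndarray:
    return np.copysign(np.floor(np.abs(values) / resolution + 0.5) * resolution, values)


def sample_values(
    truth: float, spec: SensorSpec, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw ``n`` quantized readings of a true temperature from one channel stream.

    value = quantize(truth + N(0, noise_sd) + Bernoulli(spike_prob)·spike_amp).
    Deterministic for a given generator state.
    """
    if not math.isfinite(truth):
        raise SensorError(f"true temperature must be finite, got {truth!r}")
    values = np.full(n, float(truth))
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.spike_prob > 0:
        values = values + spec.spike_amp * (rng.random(n) < spec.spike_prob)
    return _quantize_array(values, spec.resolution)


def sample(
    truth: float,
    spec: SensorSpec,
    rng: np.random.Generator,
    time: float = 0.0,
    channel: str = "T1a",
) -> Reading:
    """Take one reading of ``truth`` on ``channel`` at ``time``."""
    value = float(sample_values(truth, spec, rng, 1)[0])
    return Reading(time=time, channel=channel, value=value)
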