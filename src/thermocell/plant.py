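"""Lumped first-order thermal model of the Peltier/slide/coverslip assembly.

The heated slide is treated as a single thermal compartment: under constant
PWM drive ``u`` the temperature relaxes exponentially toward a steady state

    T_ss(u) = ambient + gain * u  (+ optional quadratic term),

with a single open-loop time constant ``tau``.  The device has no heatsink,
so it cannot cool below ambient; "cooling" is passive relaxation at u = 0.
Defaults are calibrated to two bench facts: full drive (PWM = 50) from a
25 °C room stably reaches 89 °C, giving gain = (89 - 25)/50 = 1.28 °C per
PWM unit, and passive cooling decays with tau ≈ 1.9 min.

The simulated thermistor adds Gaussian read noise and can optionally push the
reading through the calibrated resistance map and back, exercising the same
code path a real sensor readout would.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import math

import numpy as np

from .thermistor import ThermistorModel

PWM_HARD_MAX = 255


@dataclass(frozen=True)
class PlantParams:
    """Thermal plant parameters.

    Attributes
    ----------
    gain_c_per_pwm : float
        Steady-state temperature rise above ambient per PWM unit (°C).
    tau_s : float
        Open-loop relaxation time constant, seconds (114 s = 1.9 min).
    ambient_c : float
        Ambient (room / enclosure) temperature, °C.
    sensor_noise_sd_c : float
        Gaussian read-noise standard deviation of the thermistor, °C.
    process_noise_sd_c : float
        Process noise on the true temperature, °C per sqrt(second).
    quad_gain_c_per_pwm2 : float
        Optional quadratic PWM→power coefficient; zero by default.
    """

    gain_c_per_pwm: float = 1.28
    tau_s: float = 114.0
    ambient_c: float = 25.0
    sensor_noise_sd_c: float = 0.05
    process_noise_sd_c: float = 0.0
    quad_gain_c_per_pwm2: float = 0.0

    def __post_init__(self) -> None:
        if not self.gain_c_per_pwm > 0:
            raise ValueError("gain must be positive")
        if not self.tau_s > 0:
            raise ValueError("tau must be positive")
        if self.sensor_noise_sd_c < 0 or self.process_noise_sd_c < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class PlantState:
    """True plate/sample temperature at a point in simulated time."""

    time_s: float
    temperature_c: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature_c):
            raise ValueError("temperature must be finite")


def steady_state_temp(params: PlantParams, pwm: float) -> float:
    """Steady-state temperature (°C) under constant PWM drive."""
    if not 0 <= pwm <= PWM_HARD_MAX:
        raise ValueError(f"pwm must be in [0, {PWM_HARD_MAX}], got {pwm}")
    return (
        params.ambient_c
        + params.gain_c_per_pwm * pwm
        + params.quad_gain_c_per_pwm2 * pwm * pwm
    )


def step_plant(
    state: PlantState,
    params: PlantParams,
    pwm: float,
    dt_s: float,
    rng: np.random.Generator | None = None,
) -> PlantState:
    """Advance the plant by ``dt_s`` seconds under constant drive.

    Uses the exact solution of the first-order ODE,
    ``T(t+dt) = T_ss + (T(t) - T_ss) exp(-dt/tau)``, so the step size does
    not affect accuracy.  Process noise (if configured and ``rng`` given) is
    added as a Gaussian increment with sd ``process_noise_sd_c * sqrt(dt)``.
    """
    if dt_s < 0:
        raise ValueError(f"dt must be >= 0, got {dt_s}")
    if dt_s == 0:
        return state
    t_ss = steady_state_temp(params, pwm)
    temp = t_ss + (state.temperature_c - t_ss) * math.exp(-dt_s / params.tau_s)
    if params.process_noise_sd_c > 0 and rng is not None:
        temp += params.process_noise_sd_c * math.sqrt(dt_s) * rng.standard_normal()
    return PlantState(time_s=state.time_s + dt_s, temperature_c=temp)


def read_sensor(
    state: PlantState,
    params: PlantParams,
    rng: np.random.Generator | None = None,
    model: ThermistorModel | None = None,
    via_calibration: bool = False,
) -> float:
    """Simulated thermistor reading of the current plate temperature (°C).

    Adds Gaussian noise with sd ``sensor_noise_sd_c``.  With
    ``via_calibration=True`` and a :class:`ThermistorModel`, the noisy
    temperature is mapped to a resistance and back, exercising the
    calibration path the physical readout uses.
    """
    temp = state.temperature_c
    if params.sensor_noise_sd_c > 0 and rng is not None:
        temp += params.sensor_noise_sd_c * rng.standard_normal()
    if via_calibration and model is not None:
        temp = model.resistance_to_temperature(model.temperature_to_resistance(temp))
    return temp


def with_ambient(params: PlantParams, ambient_c: float) -> PlantParams:
    """Copy of ``params`` with a different ambient temperature."""
    return replace(params, ambient_c=ambient_c)
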