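"""Discrete PID temperature control and setpoint programs.

The controller reproduces the logic of the device firmware: every sample
interval (500 ms) the thermistor is read, the error e = T_setpoint - T is
formed, and a PWM command

    u = Kp e + Ki * integral(e dt) + Kd * d/dt

is computed, rounded to an integer and clamped to [0, pwm_max].  The device
caps drive at PWM = 50 (out of a possible 255) and has no active cooling, so
the lower clamp at 0 *is* the passive-cooling mode: a negative error simply
switches the heater off and the plant relaxes toward ambient.

Three firmware-faithful details:

* the proportional term acts on the *measurement* rather than on the error
  (a two-degree-of-freedom PID with setpoint weight b, default b = 0 — the
  same "proportional on measurement" mode popularized by the Arduino PID
  library).  This removes the proportional kick at setpoint steps, so a
  step is approached gently — the behavior needed so an agarose pad heats
  without melting — while the regulation bandwidth around the setpoint
  stays high enough to settle within ~2 min and reject disturbances;
* the derivative likewise acts on the measurement;
* the integral is frozen while the output saturates in the direction of the
  error (conditional integration), the standard anti-windup device.

Setpoint programs are piecewise-constant waveforms assembled from hold /
step / staircase / oscillation segments, covering the protocols used on the
bench: long holds, 2 °C staircases at 5-min dwell, and symmetric
heat/passive-cool oscillations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .plant import PlantParams, PlantState, read_sensor, step_plant
from .thermistor import ThermistorModel
from .trace import TemperatureTrace

DEFAULT_PWM_MAX = 50
DEFAULT_SAMPLE_INTERVAL_S = 0.5


class ProgramRangeError(ValueError):
    """Time queried beyond the end of a setpoint program."""


@dataclass(frozen=True)
class PIDGains:
    """PID gains in PWM units per °C, per °C·s, and per °C/s.

    The defaults are the repository's tuned "slow" gains: with the default
    plant calibration they approach a new setpoint without overshoot (the
    proportional term acts on the measurement; see ``setpoint_weight``),
    settle into a ±0.3 °C band within ~2 min, and give an emergent
    closed-loop heating constant of about 0.6 min.

    ``setpoint_weight`` (b in the two-degree-of-freedom PID literature)
    scales how much of the setpoint enters the proportional term: b = 1 is
    the textbook P-on-error controller, b = 0 (default) is proportional on
    measurement only.
    """

    kp: float = 7.0
    ki: float = 0.20
    kd: float = 0.0
    setpoint_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("PID gains must be >= 0")
        if not 0.0 <= self.setpoint_weight <= 1.0:
            raise ValueError("setpoint_weight must be in [0, 1]")


@dataclass(frozen=True)
class ControllerState:
    """Mutable-by-replacement state carried between PID samples.

    ``p_state_pwm`` is the accumulated proportional-on-measurement term,
    ``-kp (1-b) (T - T_first)`` (kept incrementally so gains may change
    mid-run).
    """

    integral_cs: float = 0.0
    p_state_pwm: float = 0.0
    previous_measurement_c: float | None = None
    last_pwm: int = 0


def pid_step(
    ctrl: ControllerState,
    gains: PIDGains,
    setpoint_c: float,
    measurement_c: float,
    dt_s: float,
    pwm_max: int = DEFAULT_PWM_MAX,
) -> tuple[int, ControllerState]:
    """One discrete PID update; returns (integer PWM command, new state)."""
    if not dt_s > 0:
        raise ValueError(f"dt must be positive, got {dt_s}")
    error = setpoint_c - measurement_c
    p_state = ctrl.p_state_pwm
    if ctrl.previous_measurement_c is None:
        derivative = 0.0
    else:
        delta = measurement_c - ctrl.previous_measurement_c
        # both P (for b < 1) and D act on the measurement, so setpoint
        # steps do not kick the output
        p_state -= gains.kp * (1.0 - gains.setpoint_weight) * delta
        derivative = -delta / dt_s
    integral = ctrl.integral_cs + error * dt_s
    raw = (
        gains.kp * gains.setpoint_weight * error
        + p_state
        + gains.ki * integral
        + gains.kd * derivative
    )
    pwm = int(math.floor(raw + 0.5))  # hardware writes integer duty, half-up
    if pwm > pwm_max:
        pwm = pwm_max
        if error > 0:
            integral = ctrl.integral_cs  # anti-windup: freeze while saturated
    elif pwm < 0:
        pwm = 0
        if error < 0:
            integral = ctrl.integral_cs
    return pwm, ControllerState(
        integral_cs=integral,
        p_state_pwm=p_state,
        previous_measurement_c=measurement_c,
        last_pwm=pwm,
    )


# ---------------------------------------------------------------------------
# Setpoint programs


@dataclass(frozen=True)
class Hold:
    """Hold ``target_c`` for ``duration_s`` seconds."""

    target_c: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("hold duration must be positive")


@dataclass(frozen=True)
class Step:
    """Step to ``target_c`` and stay there (open-ended final segment)."""

    target_c: float
    duration_s: float = math.inf


@dataclass(frozen=True)
class Staircase:
    """Stepwise ramp: start, then +increment every dwell until end (incl.)."""

    start_c: float
    increment_c: float
    dwell_s: float
    end_c: float

    def __post_init__(self) -> None:
        if not self.dwell_s > 0:
            raise ValueError("dwell must be positive")
        if self.increment_c == 0:
            raise ValueError("increment must be nonzero")
        if (self.end_c - self.start_c) * self.increment_c < 0:
            raise ValueError("end must lie in the direction of the increment")

    @property
    def levels(self) -> list[float]:
        n = int(math.floor((self.end_c - self.start_c) / self.increment_c + 1e-9)) + 1
        return [self.start_c + k * self.increment_c for k in range(n)]

    @property
    def duration_s(self) -> float:
        return len(self.levels) * self.dwell_s


@dataclass(frozen=True)
class Oscillation:
    """Square-wave cycles: high for half_period, then low for half_period."""

    low_c: float
    high_c: float
    half_period_s: float
    cycles: int

    def __post_init__(self) -> None:
        if not self.half_period_s > 0:
            raise ValueError("half period must be positive")
        if self.cycles < 1:
            raise ValueError("need at least one cycle")

    @property
    def duration_s(self) -> float:
        return 2.0 * self.half_period_s * self.cycles


Segment = Hold | Step | Staircase | Oscillation


@dataclass(frozen=True)
class SetpointProgram:
    """Ordered piecewise-constant setpoint schedule."""

    segments: tuple[Segment, ...]
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("program must contain at least one segment")
        if not self.sample_interval_s > 0:
            raise ValueError("sample interval must be positive")
        for seg in self.segments[:-1]:
            if math.isinf(seg.duration_s):
                raise ValueError("only the final segment may be open-ended")

    @property
    def duration_s(self) -> float:
        return sum(seg.duration_s for seg in self.segments)


def _segment_setpoint(seg: Segment, t_local: float) -> float:
    if isinstance(seg, (Hold, Step)):
        return seg.target_c
    if isinstance(seg, Staircase):
        idx = min(int(t_local // seg.dwell_s), len(seg.levels) - 1)
        return seg.levels[idx]
    if isinstance(seg, Oscillation):
        t_cycle = t_local % (2.0 * seg.half_period_s)
        return seg.high_c if t_cycle < seg.half_period_s else seg.low_c
    raise TypeError(f"unknown segment type {type(seg)!r}")


def evaluate_program(program: SetpointProgram, t_s: float) -> float:
    """Setpoint (°C) at time ``t_s`` from the program start."""
    if t_s < 0:
        raise ProgramRangeError(f"negative time {t_s}")
    remaining = t_s
    for seg in program.segments:
        if remaining < seg.duration_s:
            return _segment_setpoint(seg, remaining)
        remaining -= seg.duration_s
    raise ProgramRangeError(
        f"t = {t_s} s is beyond the program end ({program.duration_s} s)"
    )


def run_closed_loop(
    plant: PlantParams,
    gains: PIDGains,
    program: SetpointProgram,
    seed: int | None = None,
    duration_s: float | None = None,
    initial_temp_c: float | None = None,
    pwm_max: int = DEFAULT_PWM_MAX,
    thermistor: ThermistorModel | None = None,
    sense_via_calibration: bool = False,
) -> TemperatureTrace:
    """Simulate the full loop: sense -> PID -> drive plant, logging each sample.

    The loop starts at ``initial_temp_c`` (ambient by default) and runs for
    the program duration (or ``duration_s`` if given, required for
    open-ended programs).  The logged temperature is the *measured* one —
    what the device itself records.  A fixed ``seed`` gives a bit-identical
    trace.
    """
    if duration_s is None:
        duration_s = program.duration_s
    if math.isinf(duration_s):
        raise ValueError("open-ended program needs an explicit duration_s")
    dt = program.sample_interval_s
    n = int(round(duration_s / dt))
    rng = np.random.default_rng(seed)
    state = PlantState(
        time_s=0.0,
        temperature_c=plant.ambient_c if initial_temp_c is None else initial_temp_c,
    )
    ctrl = ControllerState()
    times = np.empty(n)
    temps = np.empty(n)
    setpoints = np.empty(n)
    pwms = np.empty(n)
    # pre-draw sensor noise so the run is fast and reproducible
    if plant.sensor_noise_sd_c > 0:
        noise = rng.normal(0.0, plant.sensor_noise_sd_c, size=n)
    else:
        noise = np.zeros(n)
    for i in range(n):
        t = i * dt
        measured = state.temperature_c + noise[i]
        if sense_via_calibration and thermistor is not None:
            measured = thermistor.resistance_to_temperature(
                thermistor.temperature_to_resistance(measured)
            )
        setpoint = evaluate_program(program, min(t, program.duration_s - 1e-9))
        pwm, ctrl = pid_step(ctrl, gains, setpoint, measured, dt, pwm_max)
        times[i] = t
        temps[i] = measured
        setpoints[i] = setpoint
        pwms[i] = pwm
        state = step_plant(state, plant, pwm, dt, rng)
    return TemperatureTrace(times, temps, setpoints, pwms)


# ---------------------------------------------------------------------------
# Waveform shorthand, e.g. "hold:37:70m", "stair:28:2:5m:46", "osc:30:37:10m:3"


def _parse_duration(token: str) -> float:
    token = token.strip().lower()
    if token.endswith("ms"):
        return float(token[:-2]) / 1000.0
    if token.endswith("h"):
        return float(token[:-1]) * 3600.0
    if token.endswith("m"):
        return float(token[:-1]) * 60.0
    if token.endswith("s"):
        return float(token[:-1])
    return float(token)


def parse_waveform(spec: str, sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S) -> SetpointProgram:
    """Parse a comma-separated waveform shorthand into a program.

    Grammar per segment: ``hold:<T>:<dur>``, ``step:<T>``,
    ``stair:<start>:<inc>:<dwell>:<end>``, ``osc:<low>:<high>:<half>:<cycles>``.
    Durations accept s/m/h suffixes (plain numbers are seconds).
    """
    segments: list[Segment] = []
    for part in spec.split(","):
        fields = [f.strip() for f in part.strip().split(":")]
        kind = fields[0].lower()
        try:
            if kind == "hold":
                segments.append(Hold(float(fields[1]), _parse_duration(fields[2])))
            elif kind == "step":
                segments.append(Step(float(fields[1])))
            elif kind == "stair":
                segments.append(
                    Staircase(
                        float(fields[1]),
                        float(fields[2]),
                        _parse_duration(fields[3]),
                        float(fields[4]),
                    )
                )
            elif kind == "osc":
                segments.append(
                    Oscillation(
                        float(fields[1]),
                        float(fields[2]),
                        _parse_duration(fields[3]),
                        int(fields[4]),
                    )
                )
            else:
                raise ValueError(f"unknown segment kind '{kind}'")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"cannot parse waveform segment '{part.strip()}': {exc}")
    return SetpointProgram(tuple(segments), sample_interval_s=sample_interval_s)
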