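"""NTC thermistor calibration with the beta (B-parameter) model.

An NTC thermistor's resistance falls roughly exponentially with temperature.
Over a modest range (here ~20-50 °C, extrapolating reasonably to 4 °C) the
relation linearizes as

    1/T = A + (1/B) * ln R,      T in Kelvin, R in kilo-ohms,

where ``B`` (Kelvin) is the classical beta parameter and ``A`` (1/K) an
intercept absorbing the reference resistance.  ``B`` is estimated from pairs
of calibration points,

    B = ln(R1 / R2) / (1/T1 - 1/T2),

and a multi-point fit averages the pairwise estimates over all unordered
pairs, then averages the implied intercepts.  This mirrors how such sensors
are calibrated in practice against a reference thermocouple.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KELVIN_OFFSET = 273.15
ABSOLUTE_ZERO_C = -KELVIN_OFFSET


class DegeneratePairError(ValueError):
    """Two calibration points at the same temperature cannot constrain B."""


class InsufficientDataError(ValueError):
    """Fewer than two usable calibration points."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One (temperature, resistance) calibration measurement.

    Parameters
    ----------
    temperature_c : float
        Temperature in degrees Celsius. Must exceed absolute zero.
    resistance_kohm : float
        Thermistor resistance in kilo-ohms. Must be positive.
    """

    temperature_c: float
    resistance_kohm: float

    def __post_init__(self) -> None:
        if not self.temperature_c > ABSOLUTE_ZERO_C:
            raise ValueError(
                f"temperature {self.temperature_c} °C is at or below absolute zero"
            )
        if not self.resistance_kohm > 0:
            raise ValueError(f"resistance must be positive, got {self.resistance_kohm}")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + KELVIN_OFFSET


@dataclass(frozen=True)
class ThermistorModel:
    """Calibrated beta model ``1/T = intercept + ln(R)/beta``.

    Attributes
    ----------
    beta_k : float
        Beta parameter in Kelvin (> 0 for an NTC device).
    intercept_per_k : float
        Intercept A of the linearized relation, in 1/K.
    """

    beta_k: float
    intercept_per_k: float

    def __post_init__(self) -> None:
        if not self.beta_k > 0:
            raise ValueError(f"beta must be positive, got {self.beta_k}")

    @property
    def reference_resistance_25c_kohm(self) -> float:
        """Model-implied resistance at 25 °C (the nominal 'R25' rating)."""
        return self.temperature_to_resistance(25.0)

    def resistance_to_temperature(self, resistance_kohm: float) -> float:
        """Invert the calibration: resistance (kΩ) -> temperature (°C)."""
        if not resistance_kohm > 0:
            raise ValueError(f"resistance must be positive, got {resistance_kohm}")
        inv_t = self.intercept_per_k + math.log(resistance_kohm) / self.beta_k
        return 1.0 / inv_t - KELVIN_OFFSET

    def temperature_to_resistance(self, temperature_c: float) -> float:
        """Evaluate the calibration: temperature (°C) -> resistance (kΩ)."""
        if not temperature_c > ABSOLUTE_ZERO_C:
            raise ValueError(
                f"temperature {temperature_c} °C is at or below absolute zero"
            )
        t_k = temperature_c + KELVIN_OFFSET
        return math.exp(self.beta_k * (1.0 / t_k - self.intercept_per_k))


def beta_from_pair(p1: CalibrationPoint, p2: CalibrationPoint) -> float:
    """Pairwise beta estimate ``ln(R1/R2) / (1/T1 - 1/T2)`` in Kelvin.

    Symmetric in its arguments; raises :class:`DegeneratePairError` when the
    two points share a temperature.
    """
    if p1.temperature_c == p2.temperature_c:
        raise DegeneratePairError(
            f"calibration points share temperature {p1.temperature_c} °C"
        )
    # differences of logs (not log of ratio): argument swap then negates both
    # numerator and denominator exactly, so the estimate is bit-symmetric
    num = math.log(p1.resistance_kohm) - math.log(p2.resistance_kohm)
    den = 1.0 / p1.temperature_k - 1.0 / p2.temperature_k
    return num / den


def fit_thermistor(points: list[CalibrationPoint]) -> ThermistorModel:
    """Fit the beta model to >= 2 calibration points.

    ``beta`` is the unweighted mean of the pairwise estimates over all
    unordered pairs with distinct temperatures; the intercept is the mean of
    ``1/T - ln(R)/beta`` over all points.
    """
    betas = []
    for p1, p2 in itertools.combinations(points, 2):
        if p1.temperature_c != p2.temperature_c:
            betas.append(beta_from_pair(p1, p2))
    if not betas:
        raise InsufficientDataError(
            "need at least two calibration points with distinct temperatures"
        )
    beta = float(np.mean(betas))
    intercepts = [
        1.0 / p.temperature_k - math.log(p.resistance_kohm) / beta for p in points
    ]
    return ThermistorModel(beta_k=beta, intercept_per_k=float(np.mean(intercepts)))


def read_calibration_csv(path: str | Path) -> list[CalibrationPoint]:
    """Read a two-column calibration table (temperature_C, resistance_kohm)."""
    df = pd.read_csv(path)
    expected = ["temperature_C", "resistance_kohm"]
    if list(df.columns) != expected:
        raise ValueError(
            f"calibration CSV must have header {expected}, got {list(df.columns)}"
        )
    return [
        CalibrationPoint(float(row.temperature_C), float(row.resistance_kohm))
        for row in df.itertuples()
    ]


def write_calibration_csv(points: list[CalibrationPoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "temperature_C": [p.temperature_c for p in points],
            "resistance_kohm": [p.resistance_kohm for p in points],
        }
    ).to_csv(path, index=False)


def adc_to_resistance(
    counts: float,
    divider_kohm: float = 100.0,
    adc_max: int = 1023,
    thermistor_on_top: bool = False,
) -> float:
    """Convert a raw ADC reading from a voltage divider to resistance (kΩ).

    The thermistor and a fixed ``divider_kohm`` resistor form a divider across
    the ADC reference; ``counts / adc_max`` is the sampled fraction at the
    midpoint.  Off by default in the simulation path; provided for users
    feeding raw microcontroller logs.
    """
    if not 0 < counts < adc_max:
        raise ValueError(f"ADC counts must lie strictly inside (0, {adc_max})")
    frac = counts / adc_max
    if thermistor_on_top:
        return divider_kohm * (1.0 - frac) / frac
    return divider_kohm * frac / (1.0 - frac)


#: The four-point bench calibration table for the device's 100 kΩ NTC sensor
#: (temperatures in °C against a reference thermocouple; resistances in kΩ).
DEFAULT_CALIBRATION_POINTS: tuple[CalibrationPoint, ...] = (
    CalibrationPoint(4.0, 274.0),
    CalibrationPoint(22.0, 114.0),
    CalibrationPoint(30.0, 81.0),
    CalibrationPoint(37.0, 60.0),
)


def default_thermistor_model() -> ThermistorModel:
    """Model fitted to :data:`DEFAULT_CALIBRATION_POINTS` (B ≈ 3950 K)."""
    return fit_thermistor(list(DEFAULT_CALIBRATION_POINTS))
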