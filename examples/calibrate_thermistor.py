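"""Fit the beta model to the bench calibration table of the 100-kΩ NTC sensor.

The four (temperature, resistance) pairs were measured against a reference
thermocouple.  The script prints the pairwise beta estimates, their mean
(the calibrated B), and sanity checks of the fitted curve.
"""

import itertools

from thermocell import beta_from_pair, fit_thermistor
from thermocell.thermistor import DEFAULT_CALIBRATION_POINTS

points = list(DEFAULT_CALIBRATION_POINTS)
print("calibration table (T degC, R kOhm):")
for p in points:
    print(f"  {p.temperature_c:5.1f}  {p.resistance_kohm:6.1f}")

print("\npairwise beta estimates (K):")
for p1, p2 in itertools.combinations(points, 2):
    print(f"  {p1.temperature_c:>4.0f}/{p2.temperature_c:<4.0f}  {beta_from_pair(p1, p2):7.0f}")

model = fit_thermistor(points)
print(f"\nmean pairwise B = {model.beta_k:.0f} K")
print(f"implied R(25 degC) = {model.reference_resistance_25c_kohm:.1f} kOhm "
      "(the sensor's nominal 100-kOhm rating)")
print(f"T(60 kOhm) = {model.resistance_to_temperature(60.0):.2f} degC "
      "(the 37 degC table entry, read back through the fit)")
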