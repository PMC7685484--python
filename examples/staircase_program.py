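"""Stepwise ramp 25 → 46 °C: first step to 28 °C, then +2 °C every 5 min.

Demonstrates the setpoint-program engine and that every intermediate target
is reached and held within a couple of minutes, so the device can trace out
near-arbitrary upshift waveforms.
"""

import numpy as np

from thermocell import PIDGains, PlantParams, parse_waveform, run_closed_loop
from thermocell.trace import equilibration_time

plant = PlantParams(ambient_c=25.0)
program = parse_waveform("stair:28:2:5m:46")
trace = run_closed_loop(plant, PIDGains(), program, seed=2)

print("level (degC)  time-to-band (min)   mean in final minute (degC)")
for k, level in enumerate(np.arange(28.0, 47.0, 2.0)):
    t0, t1 = k * 300.0, (k + 1) * 300.0
    seg = trace.slice(t0, t1)
    shifted = type(seg)(seg.time_s - t0, seg.temp_c, seg.setpoint_c, seg.pwm)
    eq = equilibration_time(shifted, level, band_c=0.3)
    final = seg.temp_c[seg.time_s >= t1 - 60.0].mean()
    eq_str = f"{eq:.2f}" if eq is not None else "  not reached"
    print(f"   {level:4.0f}          {eq_str:>6}                {final:6.2f}")
print("\nPWM stayed within the device cap:", int(trace.pwm.max()), "<= 50")
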