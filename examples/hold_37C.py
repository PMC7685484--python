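"""Maintain 37 °C for two hours of simulated time and summarize stability.

The loop starts at a 25 °C ambient, heats the stage under PID control
(sampling every 0.5 s), and logs the measured temperature.  The summary
mirrors how a maintenance run is characterized: equilibration time into a
±0.3 °C band, then mean / sd / worst deviation after the first 5 minutes.
"""

from thermocell import (
    Hold,
    PIDGains,
    PlantParams,
    SetpointProgram,
    equilibration_time,
    run_closed_loop,
    stability_stats,
)

plant = PlantParams(ambient_c=25.0)  # gain 1.28 degC/PWM, tau 1.9 min, noise 0.05 degC
trace = run_closed_loop(plant, PIDGains(), SetpointProgram((Hold(37.0, 2 * 3600.0),)), seed=1)

eq = equilibration_time(trace, 37.0, band_c=0.3)
stats = stability_stats(trace, after_s=300.0)
print(f"equilibration into +/-0.3 degC: {eq:.2f} min after the shift")
print(f"mean after 5 min:  {stats.mean_c:.3f} degC")
print(f"sd:                {stats.sd_c:.3f} degC  (sensor noise is 0.05 degC)")
print(f"worst |T - 37|:    {stats.max_abs_error_c:.3f} degC")
print(f"max 3-min-window sd: {stats.max_windowed_sd_c:.3f} degC")
print("\nA value near 37.000 with sd well under 0.2 degC means the controller")
print("holds a sample at growth temperature indefinitely without drift.")
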