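"""Division halt in a temperature-sensitive division mutant after an upshift.

Cells grow and divide at the permissive 30 °C; at t = 15 min the setpoint
steps to the nonpermissive 42 °C.  Division stops almost immediately while
elongation continues, so cells filament.  The division histogram (5-min
windows) makes the halt visible.
"""

import numpy as np

from thermocell import (
    GrowthModel,
    MovieConfig,
    PIDGains,
    PlantParams,
    parse_waveform,
    quantify_stack,
    run_closed_loop,
    simulate_movie,
)
from thermocell.simcell import FILAMENTOUS

trace = run_closed_loop(
    PlantParams(ambient_c=30.0), PIDGains(),
    parse_waveform("hold:30:15m,hold:42:15m"), seed=5, initial_temp_c=30.0,
)
model = GrowthModel(  # slower-growing ts strain, smaller division length
    rate_map=((20.0, 0.6), (30.0, 1.1), (37.0, 1.5), (45.0, 1.55)),
    division_length_mean_um=4.5,
)
config = MovieConfig(shape=(768, 768), seed=9)
movie = simulate_movie(config, model, trace, n_cells=12, phenotype=FILAMENTOUS)

result = quantify_stack(
    movie.stack.astype(np.float32) / 65535.0,
    config.pixel_size_um,
    config.frame_interval_s,
)
print("division events per 5-min window (shift to 42 degC at 15 min):")
for _, row in result.division_histogram.iterrows():
    bar = "#" * int(row.n_divisions)
    print(f"  {row.bin_start_min:4.0f}-{row.bin_end_min:4.0f} min  {int(row.n_divisions):3d} {bar}")

lengths = result.lineage_table.groupby("frame").length_um.mean()
shift_frame = int(15 * 60 / config.frame_interval_s)
print(f"\nmean cell length: {lengths.loc[shift_frame]:.1f} um at the shift, "
      f"{lengths.iloc[-1]:.1f} um at the end — cells keep elongating")
print("Divisions cluster before (or just after) the shift: inactivating the")
print("division enzyme halts cytokinesis without stopping growth.")
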