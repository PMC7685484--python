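"""Shared fixtures.

The two session-scoped synthetic movies are the expensive fixtures: a 70-min
wild-type maintenance movie at 37 °C (parameter-recovery benchmark) and a
temperature-sensitive filamentation movie with a 30→42 °C shift at 20 min.
Both are generated once and shared by the pipeline and acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

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
from thermocell.thermistor import CalibrationPoint


@pytest.fixture(scope="session")
def printed_points() -> list[CalibrationPoint]:
    """The bench calibration table of the 100-kΩ NTC thermistor."""
    return [
        CalibrationPoint(4.0, 274.0),
        CalibrationPoint(22.0, 114.0),
        CalibrationPoint(30.0, 81.0),
        CalibrationPoint(37.0, 60.0),
    ]


@pytest.fixture(scope="session")
def default_gains() -> PIDGains:
    return PIDGains()


@pytest.fixture(scope="session")
def movie_37():
    """70-min synthetic maintenance movie at 37 °C (16 founders, ~170 cells)."""
    plant = PlantParams(ambient_c=25.0)
    trace = run_closed_loop(
        plant,
        PIDGains(),
        parse_waveform("hold:37:70m"),
        seed=11,
        initial_temp_c=37.0,
    )
    config = MovieConfig(shape=(1024, 1024), seed=5, drift_per_frame_px=(0.15, 0.1))
    return simulate_movie(config, GrowthModel(), trace, n_cells=16)


@pytest.fixture(scope="session")
def quant_37(movie_37):
    """Full pipeline output for the 37 °C movie."""
    stack = movie_37.stack.astype(np.float32) / 65535.0
    return quantify_stack(
        stack,
        movie_37.config.pixel_size_um,
        movie_37.config.frame_interval_s,
    )


@pytest.fixture(scope="session")
def movie_filament():
    """Filamentation movie: permissive 30 °C, shift to 42 °C at t = 20 min."""
    plant = PlantParams(ambient_c=30.0)
    trace = run_closed_loop(
        plant,
        PIDGains(),
        parse_waveform("hold:30:20m,hold:42:25m"),
        seed=13,
        initial_temp_c=30.0,
    )
    model = GrowthModel(
        rate_map=((20.0, 0.6), (30.0, 1.1), (37.0, 1.5), (45.0, 1.55)),
        division_length_mean_um=4.5,
    )
    config = MovieConfig(shape=(1024, 1024), seed=11)
    return simulate_movie(config, model, trace, n_cells=24, phenotype=FILAMENTOUS)


@pytest.fixture(scope="session")
def quant_filament(movie_filament):
    stack = movie_filament.stack.astype(np.float32) / 65535.0
    return quantify_stack(
        stack,
        movie_filament.config.pixel_size_um,
        movie_filament.config.frame_interval_s,
    )
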