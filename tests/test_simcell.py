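"""Synthetic cell generator: physiology, colony dynamics, rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from thermocell.control import Hold, PIDGains, SetpointProgram, run_closed_loop
from thermocell.plant import PlantParams
from thermocell.simcell import (
    FILAMENTOUS,
    ROUNDING,
    SHRINKING,
    WILDTYPE,
    CellPopulation,
    CellState,
    GrowthModel,
    MovieConfig,
    advance_population,
    ground_truth_divisions,
    make_initial_population,
    relax_rate,
    render_frame,
    simulate_movie,
    target_rate,
)


def make_cell(**kw):
    defaults = dict(
        cell_id=0,
        parent_id=-1,
        length_um=3.0,
        width_um=1.0,
        orientation_rad=0.4,
        centroid_um=(25.0, 25.0),
        current_rate_per_h=1.98,
        rate_scale=1.0,
        phenotype=WILDTYPE,
        division_threshold_um=5.0,
    )
    defaults.update(kw)
    return CellState(**defaults)


class TestRateMap:
    def test_anchor_rates(self):
        model = GrowthModel()
        assert target_rate(model, 37.0) == pytest.approx(1.98)
        assert target_rate(model, 30.0) == pytest.approx(1.4)

    def test_monotone_over_domain(self):
        model = GrowthModel()
        ts = np.linspace(20.0, 45.0, 60)
        rates = [target_rate(model, t) for t in ts]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_out_of_range_clamped_with_warning(self):
        model = GrowthModel()
        with pytest.warns(UserWarning, match="clamping"):
            assert target_rate(model, 50.0) == target_rate(model, 45.0)


class TestAdaptation:
    def test_at_target_unchanged(self):
        cell = make_cell(current_rate_per_h=1.98)
        relax_rate(cell, GrowthModel(), 37.0, 30.0, 1)
        assert cell.current_rate_per_h == pytest.approx(1.98)

    def test_first_upshift_is_slow(self):
        """30→37 °C: only ~14% rate increase after the first 10 minutes."""
        cell = make_cell(current_rate_per_h=1.4)
        model = GrowthModel()
        for _ in range(20):
            relax_rate(cell, model, 37.0, 30.0, shift_count=1)
        rel_increase = (cell.current_rate_per_h - 1.4) / 1.4
        assert rel_increase == pytest.approx(0.14, abs=0.02)

    def test_repeat_upshift_reaches_target_in_7_to_8_min(self):
        cell = make_cell(current_rate_per_h=1.4)
        model = GrowthModel()
        reached = None
        for k in range(32):
            relax_rate(cell, model, 37.0, 30.0, shift_count=2)
            if reached is None and cell.current_rate_per_h >= 0.98 * 1.98:
                reached = (k + 1) * 0.5
        assert reached is not None and reached <= 8.0
        # and distinctly before the first-shift response would get there
        slow = make_cell(current_rate_per_h=1.4)
        for _ in range(16):
            relax_rate(slow, model, 37.0, 30.0, shift_count=1)
        assert slow.current_rate_per_h < 0.9 * 1.98

    def test_infinite_dt_lands_on_target(self):
        cell = make_cell(current_rate_per_h=0.5)
        relax_rate(cell, GrowthModel(), 37.0, 1e9, 2)
        assert cell.current_rate_per_h == pytest.approx(1.98)


class TestPopulationDynamics:
    def test_length_doubles_in_ln2_over_lambda(self):
        pop = CellPopulation([make_cell(division_threshold_um=1e9, current_rate_per_h=1.0)])
        rng = np.random.default_rng(0)
        n_steps = int(round(math.log(2.0) * 3600.0 / 30.0))
        for _ in range(n_steps):
            advance_population(pop, GrowthModel(), 37.0, 30.0, rng)
        length = next(iter(pop.cells.values())).length_um
        assert length / 3.0 == pytest.approx(2.0, rel=0.01)

    def test_division_conserves_total_length(self):
        pop = CellPopulation([make_cell(length_um=5.2, division_threshold_um=5.0)])
        rng = np.random.default_rng(1)
        events = advance_population(pop, GrowthModel(), 37.0, 1e-6, rng)
        assert len(events) == 1
        total = sum(c.length_um for c in pop.cells.values())
        assert total == pytest.approx(5.2, rel=1e-6)

    def test_filamentous_mode_four_fold_in_75_min(self):
        """Division-blocked cells at constant 1.1 h⁻¹ quadruple in 75 min."""
        cells = [
            make_cell(cell_id=k, centroid_um=(15.0 + 12.0 * k, 20.0),
                      phenotype=FILAMENTOUS, current_rate_per_h=1.1)
            for k in range(10)
        ]
        pop = CellPopulation(cells)
        rng = np.random.default_rng(2)
        for _ in range(150):
            advance_population(pop, GrowthModel(), 42.0, 30.0, rng)
        mean_fold = np.mean([c.length_um for c in pop.cells.values()]) / 3.0
        assert mean_fold == pytest.approx(4.0, rel=0.05)
        assert len(pop) == 10  # no divisions above the nonpermissive temperature

    def test_population_never_shrinks_without_lysis_modes(self):
        rng = np.random.default_rng(3)
        pop = make_initial_population(5, (80.0, 80.0), GrowthModel(), rng)
        sizes = [len(pop)]
        for _ in range(80):
            advance_population(pop, GrowthModel(), 37.0, 30.0, rng)
            sizes.append(len(pop))
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_rounding_mode_drives_aspect_to_one(self):
        pop = CellPopulation([make_cell(phenotype=ROUNDING, length_um=3.0)])
        rng = np.random.default_rng(4)
        for _ in range(240):
            advance_population(pop, GrowthModel(), 42.0, 30.0, rng)
        cell = next(iter(pop.cells.values()))
        assert cell.width_um / cell.length_um > 0.95

    def test_shrinking_mode_loses_area(self):
        model = GrowthModel()
        pop = CellPopulation([make_cell(phenotype=SHRINKING)])
        a0 = next(iter(pop.cells.values())).area_um2
        rng = np.random.default_rng(5)
        for _ in range(60):  # 30 min
            advance_population(pop, model, 89.0, 30.0, rng)
        a1 = next(iter(pop.cells.values())).area_um2
        expected = math.exp(-model.shrink_rate_per_h * 0.5)
        assert a1 / a0 == pytest.approx(expected, rel=0.1)

    def test_no_overlap_after_repacking(self):
        """Colony packing keeps cell spines safely separated."""
        rng = np.random.default_rng(6)
        pop = make_initial_population(4, (80.0, 80.0), GrowthModel(), rng)
        for _ in range(120):
            advance_population(pop, GrowthModel(), 37.0, 30.0, rng)
        cells = list(pop.cells.values())
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                d = math.hypot(
                    a.centroid_um[0] - b.centroid_um[0],
                    a.centroid_um[1] - b.centroid_um[1],
                )
                # centroids of touching neighbors differ by at least a width
                assert d > 0.5 * (a.width_um + b.width_um) - 1e-6


class TestGroundTruthConsistency:
    def test_log_length_derivative_equals_current_rate(self):
        """d log L/dt over a division-free interval is exactly the set rate."""
        pop = CellPopulation([make_cell(division_threshold_um=1e9, current_rate_per_h=1.7)])
        rng = np.random.default_rng(7)
        lengths = [next(iter(pop.cells.values())).length_um]
        for _ in range(10):
            advance_population(pop, GrowthModel(), 37.0, 30.0, rng)
            lengths.append(next(iter(pop.cells.values())).length_um)
        rates = np.diff(np.log(lengths)) / (30.0 / 3600.0)
        assert np.allclose(rates, 1.7, rtol=1e-9)


class TestRendering:
    def test_empty_population_is_pure_background(self):
        config = MovieConfig(shape=(128, 128), noise_sd=0.02)
        img = render_frame(CellPopulation(), config, np.random.default_rng(0))
        assert img.mean() == pytest.approx(config.background, abs=0.01)
        assert img.std() == pytest.approx(config.noise_sd, rel=0.2)

    def test_single_cell_ground_truth_mask_length(self):
        """Zero noise: segmented extent of one rendered rod matches truth to 1 px."""
        from thermocell.quant import centerline_and_dims, extract_contour, segment_frame

        pop = CellPopulation([make_cell(length_um=4.0, centroid_um=(12.8, 12.8))])
        config = MovieConfig(shape=(256, 256), noise_sd=0.0)
        img, labels = render_frame(pop, config, None, return_labels=True)
        assert labels.max() == 1
        seg = segment_frame(img)
        assert seg.max() == 1
        length, width, _ = centerline_and_dims(
            extract_contour(seg, 1), config.pixel_size_um
        )
        assert abs(length - 4.0) <= config.pixel_size_um
        assert abs(width - 1.0) <= config.pixel_size_um

    def test_drift_moves_cross_correlation_peak(self):
        from skimage.registration import phase_cross_correlation

        pop = CellPopulation(
            [make_cell(cell_id=k, centroid_um=(8.0 + 7.0 * k, 12.0)) for k in range(3)]
        )
        config = MovieConfig(shape=(256, 256), noise_sd=0.01)
        rng = np.random.default_rng(1)
        f0 = render_frame(pop, config, rng, drift_px=(0.0, 0.0))
        f1 = render_frame(pop, config, rng, drift_px=(6.0, -4.0))
        shift, _, _ = phase_cross_correlation(
            f0.astype(float), f1.astype(float), upsample_factor=1, normalization=None
        )
        assert tuple(shift) == (-6.0, 4.0)


@pytest.fixture(scope="module")
def short_trace():
    return run_closed_loop(
        PlantParams(ambient_c=25.0),
        PIDGains(),
        SetpointProgram((Hold(37.0, 900.0),)),
        seed=2,
        initial_temp_c=37.0,
    )


class TestMovie:

    def test_same_seed_identical_ground_truth(self, short_trace):
        config = MovieConfig(shape=(256, 256), seed=21)
        a = simulate_movie(config, GrowthModel(), short_trace, n_cells=3, render=False)
        b = simulate_movie(config, GrowthModel(), short_trace, n_cells=3, render=False)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_render_does_not_change_ground_truth(self, short_trace):
        config = MovieConfig(shape=(256, 256), seed=21)
        a = simulate_movie(config, GrowthModel(), short_trace, n_cells=3, render=False)
        b = simulate_movie(config, GrowthModel(), short_trace, n_cells=3, render=True)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_trace_too_short_is_error(self, short_trace):
        config = MovieConfig(shape=(256, 256), seed=21)
        with pytest.raises(ValueError, match="cover"):
            simulate_movie(
                config, GrowthModel(), short_trace, n_cells=2, duration_s=4200.0
            )

    def test_ground_truth_divisions_structure(self, short_trace):
        config = MovieConfig(shape=(256, 256), seed=3)
        movie = simulate_movie(config, GrowthModel(), short_trace, n_cells=3, render=False)
        div = ground_truth_divisions(movie.ground_truth)
        gt = movie.ground_truth
        assert gt.cell_id.nunique() == 3 + 2 * len(div)
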