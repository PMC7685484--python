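"""Quantification pipeline: registration, segmentation, geometry, tracking."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from thermocell.quant import (
    DegenerateRegionError,
    Lineage,
    bin_population,
    centerline_and_dims,
    compare_divisions_to_truth,
    contour_area,
    count_divisions,
    extract_contour,
    growth_rates,
    measure_frame,
    population_mean_rate,
    quantify_stack,
    register_stack,
    segment_frame,
    track_cells,
)
from thermocell.simcell import (
    CellPopulation,
    CellState,
    MovieConfig,
    ground_truth_divisions,
    render_frame,
)


def rod(cell_id=0, length=4.0, centroid=(12.8, 12.8), angle=0.5, rate=1.98):
    return CellState(
        cell_id=cell_id,
        parent_id=-1,
        length_um=length,
        width_um=1.0,
        orientation_rad=angle,
        centroid_um=centroid,
        current_rate_per_h=rate,
        rate_scale=1.0,
        phenotype="wildtype",
        division_threshold_um=1e9,
    )


class TestRegistration:
    def test_artificial_shifts_recovered_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.random((128, 128))
        shifts = [(0, 0), (3, -2), (-5, 7)]
        stack = np.stack([np.roll(base, s, axis=(0, 1)) for s in shifts])
        _, offsets = register_stack(stack)
        for k, (dy, dx) in enumerate(shifts):
            assert tuple(offsets[k]) == (-dy, -dx)

    def test_zero_drift_zero_offsets(self):
        pop = CellPopulation([rod()])
        config = MovieConfig(shape=(128, 128))
        rng = np.random.default_rng(1)
        stack = np.stack([render_frame(pop, config, rng) for _ in range(4)])
        _, offsets = register_stack(stack)
        assert np.all(offsets == 0)

    def test_linear_ramp_recovered_within_one_pixel(self):
        pop = CellPopulation(
            [rod(cell_id=k, centroid=(8.0 + 6.0 * k, 10.0)) for k in range(3)]
        )
        config = MovieConfig(shape=(256, 256))
        rng = np.random.default_rng(2)
        drift = (0.7, -0.5)
        stack = np.stack(
            [
                render_frame(pop, config, rng, drift_px=(drift[0] * k, drift[1] * k))
                for k in range(10)
            ]
        )
        _, offsets = register_stack(stack)
        true = -np.outer(np.arange(10), drift)
        assert np.abs(offsets - true).max() <= 1.0


class TestSegmentation:
    def test_single_cell_iou(self):
        pop = CellPopulation([rod()])
        config = MovieConfig(shape=(256, 256), noise_sd=0.0)
        img, truth = render_frame(pop, config, None, return_labels=True)
        seg = segment_frame(img)
        assert seg.max() == 1
        inter = ((seg > 0) & (truth > 0)).sum()
        union = ((seg > 0) | (truth > 0)).sum()
        assert inter / union >= 0.9

    def test_blank_frame_empty_mask(self):
        rng = np.random.default_rng(3)
        blank = np.clip(0.55 + rng.normal(0, 0.02, (256, 256)), 0, 1)
        assert segment_frame(blank).max() == 0

    def test_label_count_on_crowded_frame(self, movie_37):
        """Cell count of the final, most crowded frame within ±5% of truth."""
        gt = movie_37.ground_truth
        last = int(gt["frame"].max())
        truth_n = (gt["frame"] == last).sum()
        seg = segment_frame(movie_37.stack[last].astype(np.float32) / 65535.0)
        n = len(np.unique(seg)) - 1
        assert abs(n - truth_n) <= 0.05 * truth_n


class TestContours:
    def test_disc_area_within_two_percent(self):
        mask = np.zeros((96, 96), dtype=np.int32)
        rr, cc = disk((48, 48), 20)
        mask[rr, cc] = 1
        contour = extract_contour(mask, 1)
        assert contour_area(contour) == pytest.approx(math.pi * 20**2, rel=0.02)

    def test_rendered_rod_area_close_to_truth(self):
        pop = CellPopulation([rod()])
        config = MovieConfig(shape=(256, 256), noise_sd=0.0)
        img, _ = render_frame(pop, config, None, return_labels=True)
        seg = segment_frame(img)
        contour = extract_contour(seg, 1)
        truth_px = pop.cells[0].area_um2 / config.pixel_size_um**2
        assert contour_area(contour) == pytest.approx(truth_px, rel=0.05)

    def test_missing_label_is_error(self):
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[10:20, 10:20] = 1
        with pytest.raises(ValueError):
            extract_contour(mask, 7)

    def test_single_pixel_label_degenerate(self):
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[16, 16] = 1
        with pytest.raises(DegenerateRegionError):
            extract_contour(mask, 1)


class TestCenterline:
    def test_ideal_capsule_dimensions(self):
        th = np.linspace(-np.pi / 2, np.pi / 2, 60)
        r, half = 5.0, 15.0
        right = np.column_stack([r * np.sin(th), half + r * np.cos(th)])
        left = np.column_stack([-r * np.sin(th), -half - r * np.cos(th)])
        contour = np.vstack([right, left, right[:1]]) + [50.0, 50.0]
        length, width, profile = centerline_and_dims(contour, 1.0)
        assert length == pytest.approx(40.0, rel=0.05)
        assert width == pytest.approx(10.0, rel=0.05)
        assert profile.size > 5

    def test_circle_has_aspect_one(self):
        th = np.linspace(0, 2 * np.pi, 100)
        contour = np.column_stack([30 + 10 * np.cos(th), 30 + 10 * np.sin(th)])
        length, width, _ = centerline_and_dims(contour, 1.0)
        assert length == pytest.approx(width, rel=0.05)
        assert length == pytest.approx(20.0, rel=0.05)

    def test_bent_rod_arc_length(self):
        yy, xx = np.mgrid[0:120, 0:120]
        mask = np.zeros((120, 120), dtype=bool)
        radius = 30.0
        for t in np.linspace(0, np.pi / 2, 40):
            py, px = 40 + radius * np.sin(t), 40 - radius * np.cos(t) + radius
            mask |= (yy - py) ** 2 + (xx - px) ** 2 <= 25.0
        contour = extract_contour(mask.astype(np.int32), 1)
        length, width, _ = centerline_and_dims(contour, 1.0)
        assert length == pytest.approx(radius * np.pi / 2 + 10.0, rel=0.05)
        assert width == pytest.approx(10.0, rel=0.05)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array(
            [[0.0, 0.0], [10.0, 10.0], [0.0, 10.0], [10.0, 0.0], [0.0, 0.0]]
        )
        with pytest.raises(ValueError, match="self-intersecting"):
            centerline_and_dims(bowtie, 1.0)


class TestTracking:
    def _stack_from_populations(self, pops, shape=(256, 256)):
        config = MovieConfig(shape=shape, noise_sd=0.0)
        masks, meas = [], []
        for pop in pops:
            _, labels = render_frame(pop, config, None, return_labels=True)
            masks.append(labels)
            meas.append(measure_frame(labels, config.pixel_size_um))
        return masks, meas

    def test_single_cell_single_full_track(self):
        pops = [CellPopulation([rod(length=3.0 + 0.1 * k)]) for k in range(6)]
        masks, meas = self._stack_from_populations(pops)
        lineages = track_cells(masks, meas)
        assert len(lineages) == 1
        assert lineages[0].frames == list(range(6))

    def test_two_distant_cells_no_crossover(self):
        pops = [
            CellPopulation([rod(0, centroid=(6.0, 6.0)), rod(1, centroid=(19.0, 19.0))])
            for _ in range(5)
        ]
        masks, meas = self._stack_from_populations(pops)
        lineages = track_cells(masks, meas)
        assert len(lineages) == 2
        for lin in lineages:
            assert len(lin.frames) == 5
            spread = np.ptp([c[0] for c in lin.centroids])
            assert spread < 2.0

    def test_division_recovery_on_synthetic_movie(self, movie_37, quant_37):
        """>= 90% of ground-truth divisions recovered within ±1 frame."""
        truth = ground_truth_divisions(movie_37.ground_truth)
        report = compare_divisions_to_truth(quant_37.lineages, list(truth["frame"]))
        assert report["recall"] >= 0.9


class TestGrowthRates:
    def _exp_lineage(self, lam=1.98, n=30, dt=30.0):
        lin = Lineage(track_id=0)
        for k in range(n):
            t_h = k * dt / 3600.0
            meas = type("M", (), {})()
            lin.frames.append(k)
            lin.centroids.append((0.0, 0.0))
            lin.lengths_um.append(3.0 * math.exp(lam * t_h))
            lin.widths_um.append(1.0)
        return lin

    def test_exact_exponential_gives_lambda_everywhere(self):
        lin = self._exp_lineage(lam=1.98)
        rates = growth_rates(lin, 30.0, smoothing_window=5)
        assert np.allclose(rates["rate_per_h"], 1.98, atol=1e-9)

    def test_constant_length_gives_zero(self):
        lin = Lineage(track_id=0)
        for k in range(20):
            lin.frames.append(k)
            lin.centroids.append((0.0, 0.0))
            lin.lengths_um.append(4.0)
            lin.widths_um.append(1.0)
        rates = growth_rates(lin, 30.0)
        assert np.allclose(rates["rate_per_h"], 0.0)

    def test_too_short_track_empty(self):
        lin = self._exp_lineage(n=4)
        assert growth_rates(lin, 30.0, smoothing_window=5).empty

    def test_full_movie_population_rate(self, quant_37):
        """37 °C maintenance movie: pipeline recovers ~1.98 h⁻¹."""
        rate = population_mean_rate(quant_37, min_n=5)
        assert rate == pytest.approx(1.98, rel=0.05)


class TestBinPopulation:
    def test_identical_series_zero_sd(self):
        s = pd.DataFrame({"time_s": [0.0, 60.0], "rate_per_h": [2.0, 2.0]})
        curve = bin_population([s, s.copy()], window_min=5.0)
        assert np.allclose(curve["sd_per_h"], 0.0)

    def test_two_constant_series_hand_computed(self):
        a = pd.DataFrame({"time_s": [0.0], "rate_per_h": [1.0]})
        b = pd.DataFrame({"time_s": [0.0], "rate_per_h": [3.0]})
        curve = bin_population([a, b], window_min=5.0)
        assert curve["mean_rate_per_h"].iloc[0] == pytest.approx(2.0)
        assert curve["sd_per_h"].iloc[0] == pytest.approx(math.sqrt(2.0))
        assert curve["n"].iloc[0] == 2

    def test_empty_input(self):
        assert bin_population([], 5.0).empty


class TestDivisions:
    def test_no_divisions_all_zero(self):
        lin = Lineage(track_id=0)
        lin.frames = list(range(10))
        hist = count_divisions([lin], 30.0, 5.0)
        assert hist["n_divisions"].sum() == 0

    def test_wildtype_totals_match_truth(self, movie_37, quant_37):
        truth_n = len(ground_truth_divisions(movie_37.ground_truth))
        detected = quant_37.division_histogram["n_divisions"].sum()
        assert abs(detected - truth_n) <= 0.1 * truth_n


class TestEndToEnd:
    def test_binned_rate_matches_truth_in_every_populated_bin(
        self, movie_37, quant_37
    ):
        """Per-bin population rate within 5% of the generator's truth (n >= 20)."""
        gt = movie_37.ground_truth.copy()
        interval_min = movie_37.config.frame_interval_s / 60.0
        gt["bin"] = (gt["frame"] * interval_min / 2.5).astype(int)
        truth_by_bin = gt.groupby("bin")["rate_per_h"].mean()
        curve = quant_37.population_curve
        for _, row in curve[curve["n"] >= 20].iterrows():
            k = int(row["bin_center_min"] / 2.5)
            if k in truth_by_bin.index:
                assert row["mean_rate_per_h"] == pytest.approx(
                    truth_by_bin[k], rel=0.05
                ), f"bin at {row['bin_center_min']} min"

    def test_length_trajectories_continuous(self, quant_37):
        """Frame-to-frame length ratios stay in [0.8, 1.3] within tracks."""
        bad = total = 0
        for lin in quant_37.lineages:
            lengths = np.asarray(lin.lengths_um)
            if len(lengths) < 2:
                continue
            ratios = lengths[1:] / lengths[:-1]
            total += len(ratios)
            bad += int(((ratios < 0.8) | (ratios > 1.3)).sum())
        assert total > 0
        assert bad / total < 0.02

    def test_registration_invariance_of_geometry(self):
        """A known global drift changes measured lengths by < 1 px-equivalent."""
        from thermocell.control import Hold, PIDGains, SetpointProgram, run_closed_loop
        from thermocell.plant import PlantParams
        from thermocell.simcell import GrowthModel, simulate_movie

        trace = run_closed_loop(
            PlantParams(ambient_c=25.0),
            PIDGains(),
            SetpointProgram((Hold(37.0, 600.0),)),
            seed=6,
            initial_temp_c=37.0,
        )
        model = GrowthModel()
        base_cfg = MovieConfig(shape=(384, 384), seed=17)
        drift_cfg = MovieConfig(shape=(384, 384), seed=17, drift_per_frame_px=(0.8, -0.6))
        res = []
        for cfg in (base_cfg, drift_cfg):
            movie = simulate_movie(cfg, model, trace, n_cells=4)
            out = quantify_stack(
                movie.stack.astype(np.float32) / 65535.0,
                cfg.pixel_size_um,
                cfg.frame_interval_s,
            )
            res.append(out.lineage_table["length_um"].mean())
        assert abs(res[0] - res[1]) < base_cfg.pixel_size_um

    def test_blank_stack_gives_empty_tables(self):
        rng = np.random.default_rng(5)
        stack = np.clip(0.55 + rng.normal(0, 0.02, (4, 128, 128)), 0, 1).astype(
            np.float32
        )
        res = quantify_stack(stack, 0.1, 30.0)
        assert res.n_tracks == 0
        assert res.population_curve.empty
        assert res.division_histogram["n_divisions"].sum() == 0
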