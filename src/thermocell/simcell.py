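"""Ground-truthed synthetic phase-contrast time-lapse movies of rod-shaped cells.

This module emulates what a temperature-shift experiment on an agarose pad
looks like to the analysis pipeline: spherocylindrical bacteria elongate
exponentially at a temperature-dependent rate, divide near a per-cell length
threshold, and are imaged every 30 s as dark rods with a bright halo on a
mid-gray background, with optional stage drift and Gaussian camera noise.
Every frame carries a complete ground-truth record (identity, lineage,
length, width, instantaneous rate), so the segmentation/tracking/growth-rate
pipeline can be scored against exact answers.

Growth physiology
-----------------
The steady-state elongation rate λ(T) is a monotone piecewise-linear map
anchored at 1.4 h⁻¹ (30 °C) and 1.98 h⁻¹ (37 °C).  After a temperature
shift the *instantaneous* rate relaxes toward λ(T) with a first-order time
constant: slow on the first shift in a given direction (~24 min, so a
30→37 °C upshift raises the rate by only ~14% in the first 10 min) and fast
on repeat shifts (~2.5 min, reaching the new steady state within 7–8 min) —
cells adapt to an oscillation within a single period.

Phenotypes
----------
``wildtype`` cells divide symmetrically (±3% noise) when they exceed a
per-cell threshold.  Above a nonpermissive temperature, ``filamentous``
cells stop dividing but keep elongating (division-machinery knockout),
``rounding`` cells redirect elongation into width until their aspect ratio
approaches 1 (elongation-machinery knockout), and ``shrinking`` cells lose
cross-sectional area (extreme-heat response).

Colony geometry
---------------
Cells are sessile: each founder seeds a microcolony that is laid out as
parallel lanes of rods sharing the founder's axis, with small gaps between
neighbors.  When a lane outgrows a maximum extent its outermost cell hops to
an adjacent lane — a deterministic stand-in for the mechanical rearrangement
of real microcolonies that keeps the packing overlap-free and compact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .trace import TemperatureTrace, setpoint_transitions

WILDTYPE = "wildtype"
FILAMENTOUS = "filamentous"
ROUNDING = "rounding"
SHRINKING = "shrinking"
PHENOTYPES = (WILDTYPE, FILAMENTOUS, ROUNDING, SHRINKING)


@dataclass(frozen=True)
class GrowthModel:
    """Temperature-dependent growth physiology of the simulated strain.

    Attributes
    ----------
    rate_map : tuple of (temperature °C, rate per hour)
        Monotone anchors of the steady-state elongation rate; linear
        interpolation in between, clamped (with a warning) outside.
    adaptation_tau_first_min, adaptation_tau_later_min : float
        First-order relaxation constants of the instantaneous rate for the
        first and for repeat shifts in a direction, minutes.
    division_length_mean_um, division_cv : float
        Mean and CV of the per-cell division-length threshold.
    division_asymmetry_sd : float
        SD of the symmetric-division noise (fractional imbalance).
    rate_cv : float
        Per-cell lognormal-ish variability of the steady-state rate scale.
    nonpermissive_temp_c : float
        Temperature above which the ts phenotypes activate.
    shrink_rate_per_h : float
        Fractional cross-sectional-area loss rate in shrinking mode.
    """

    rate_map: tuple[tuple[float, float], ...] = (
        (20.0, 0.75),
        (30.0, 1.4),
        (37.0, 1.98),
        (45.0, 2.0),
    )
    adaptation_tau_first_min: float = 24.0
    adaptation_tau_later_min: float = 2.5
    division_length_mean_um: float = 5.0
    division_cv: float = 0.1
    division_asymmetry_sd: float = 0.03
    rate_cv: float = 0.05
    nonpermissive_temp_c: float = 40.0
    shrink_rate_per_h: float = 0.55

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.rate_map]
        rates = [r for _, r in self.rate_map]
        if sorted(temps) != temps or any(r <= 0 for r in rates):
            raise ValueError("rate_map anchors must be sorted in T with rates > 0")
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise ValueError("rate_map must be monotone non-decreasing")
        if self.adaptation_tau_later_min > self.adaptation_tau_first_min:
            raise ValueError("later-shift adaptation must not be slower than the first")


def target_rate(model: GrowthModel, temperature_c: float) -> float:
    """Steady-state elongation rate (h⁻¹) at a temperature.

    Clamps (with a warning) outside the anchored temperature range.
    """
    temps = np.array([t for t, _ in model.rate_map])
    rates = np.array([r for _, r in model.rate_map])
    if temperature_c < temps[0] or temperature_c > temps[-1]:
        warnings.warn(
            f"temperature {temperature_c} °C outside the rate map "
            f"[{temps[0]}, {temps[-1]}]; clamping",
            stacklevel=2,
        )
    return float(np.interp(temperature_c, temps, rates))


@dataclass
class CellState:
    """One simulated cell (a spherocylinder).

    ``length_um`` is pole-to-pole; the invariant length >= width > 0 holds
    throughout.  ``current_rate_per_h`` is the instantaneous elongation rate,
    which lags the steady-state rate after temperature shifts; ``rate_scale``
    is the cell's static growth-capacity factor (population heterogeneity).
    """

    cell_id: int
    parent_id: int
    length_um: float
    width_um: float
    orientation_rad: float
    centroid_um: tuple[float, float]  # (y, x) in sample coordinates
    current_rate_per_h: float
    rate_scale: float
    phenotype: str
    division_threshold_um: float

    def __post_init__(self) -> None:
        if not (self.length_um >= self.width_um > 0):
            raise ValueError("need length >= width > 0")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")

    @property
    def area_um2(self) -> float:
        """Projected (2D) area of the spherocylinder."""
        w, length = self.width_um, self.length_um
        return (length - w) * w + math.pi * (w / 2.0) ** 2


def relax_rate(
    cell: CellState,
    model: GrowthModel,
    temperature_c: float,
    dt_s: float,
    shift_count: int = 0,
) -> float:
    """First-order relaxation of a cell's rate toward its target; returns it.

    ``shift_count`` counts temperature shifts already experienced in the
    current direction (including the ongoing one): the first shift relaxes
    with ``adaptation_tau_first_min``, repeats with the faster
    ``adaptation_tau_later_min``.
    """
    if not dt_s > 0:
        raise ValueError("dt must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tgt = target_rate(model, temperature_c) * cell.rate_scale
    tau_min = (
        model.adaptation_tau_first_min
        if shift_count <= 1
        else model.adaptation_tau_later_min
    )
    new = tgt + (cell.current_rate_per_h - tgt) * math.exp(-dt_s / (tau_min * 60.0))
    cell.current_rate_per_h = new
    return new


# ---------------------------------------------------------------------------
# Colony packing

LANE_GAP_UM = 0.25
AXIAL_GAP_UM = 0.2
MAX_LANE_EXTENT_UM = 12.0


@dataclass
class Colony:
    center_um: tuple[float, float]  # (y, x)
    axis_rad: float
    lanes: dict[int, list[int]] = field(default_factory=dict)  # lane -> cell ids


class CellPopulation:
    """Cells plus the colony bookkeeping that assigns them positions."""

    def __init__(self, cells: list[CellState] | None = None):
        self.cells: dict[int, CellState] = {}
        self.colonies: list[Colony] = []
        self._cell_colony: dict[int, int] = {}
        self._next_id = 0
        for c in cells or []:
            self.add_founder(c)

    def __len__(self) -> int:
        return len(self.cells)

    def add_founder(self, cell: CellState) -> None:
        """Register a cell as the founder of its own colony."""
        self._next_id = max(self._next_id, cell.cell_id + 1)
        self.cells[cell.cell_id] = cell
        colony = Colony(cell.centroid_um, cell.orientation_rad, {0: [cell.cell_id]})
        self.colonies.append(colony)
        self._cell_colony[cell.cell_id] = len(self.colonies) - 1
        self._repack(colony)

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def total_area_um2(self) -> float:
        return sum(c.area_um2 for c in self.cells.values())

    def _repack(self, colony: Colony) -> None:
        """Recompute centroids: contiguous cells per lane, lanes side by side."""
        cy, cx = colony.center_um
        ua = (math.sin(colony.axis_rad), math.cos(colony.axis_rad))  # axial (y,x)
        un = (-ua[1], ua[0])  # normal
        for lane_idx, ids in colony.lanes.items():
            lengths = [self.cells[i].length_um for i in ids]
            total = sum(lengths) + AXIAL_GAP_UM * (len(ids) - 1)
            pos = -total / 2.0
            offset = lane_idx * (
                max(self.cells[i].width_um for i in ids) + LANE_GAP_UM
            )
            for i, length in zip(ids, lengths):
                a = pos + length / 2.0
                self.cells[i].centroid_um = (
                    cy + ua[0] * a + un[0] * offset,
                    cx + ua[1] * a + un[1] * offset,
                )
                self.cells[i].orientation_rad = colony.axis_rad
                pos += length + AXIAL_GAP_UM

    def _lane_extent(self, colony: Colony, lane_idx: int) -> float:
        ids = colony.lanes[lane_idx]
        return sum(self.cells[i].length_um for i in ids) + AXIAL_GAP_UM * (
            len(ids) - 1
        )

    def _rebalance(self, colony: Colony) -> None:
        """Hop outermost cells from overlong lanes into adjacent lanes."""
        moved = True
        guard = 0
        while moved and guard < 100:
            moved = False
            guard += 1
            for lane_idx in sorted(colony.lanes):
                ids = colony.lanes[lane_idx]
                if len(ids) < 2:
                    continue
                if self._lane_extent(colony, lane_idx) <= MAX_LANE_EXTENT_UM:
                    continue
                # candidate destination lanes next to this one
                cands = [lane_idx - 1, lane_idx + 1]
                dest = min(
                    cands,
                    key=lambda k: (
                        self._lane_extent(colony, k) if k in colony.lanes else 0.0,
                        abs(k),
                    ),
                )
                # move the end cell whose side faces the destination lane
                cell_id = ids.pop(0) if dest < lane_idx else ids.pop()
                colony.lanes.setdefault(dest, [])
                if dest < lane_idx:
                    colony.lanes[dest].insert(0, cell_id)
                else:
                    colony.lanes[dest].append(cell_id)
                moved = True

    def repack_all(self) -> None:
        for colony in self.colonies:
            self._rebalance(colony)
            self._repack(colony)


def _divide(
    pop: CellPopulation,
    colony: Colony,
    lane_idx: int,
    cell: CellState,
    model: GrowthModel,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Split ``cell`` into two daughters in place (same lane, adjacent slots)."""
    asym = model.division_asymmetry_sd * rng.standard_normal()
    asym = float(np.clip(asym, -0.2, 0.2))
    l1 = cell.length_um * (0.5 + asym)
    l2 = cell.length_um - l1
    daughters = []
    for length in (l1, l2):
        did = pop.new_id()
        thresh = model.division_length_mean_um * (
            1.0 + model.division_cv * rng.standard_normal()
        )
        thresh = max(thresh, 2.5 * cell.width_um)
        scale = 1.0 + model.rate_cv * rng.standard_normal()
        daughters.append(
            CellState(
                cell_id=did,
                parent_id=cell.cell_id,
                length_um=max(length, cell.width_um),
                width_um=cell.width_um,
                orientation_rad=cell.orientation_rad,
                centroid_um=cell.centroid_um,
                current_rate_per_h=cell.current_rate_per_h,
                rate_scale=max(scale, 0.2),
                phenotype=cell.phenotype,
                division_threshold_um=thresh,
            )
        )
    ids = colony.lanes[lane_idx]
    k = ids.index(cell.cell_id)
    ids[k : k + 1] = [daughters[0].cell_id, daughters[1].cell_id]
    del pop.cells[cell.cell_id]
    del pop._cell_colony[cell.cell_id]
    ci = pop.colonies.index(colony)
    for d in daughters:
        pop.cells[d.cell_id] = d
        pop._cell_colony[d.cell_id] = ci
    return daughters[0].cell_id, daughters[1].cell_id


def advance_population(
    pop: CellPopulation,
    model: GrowthModel,
    temperature_c: float,
    dt_s: float,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Grow/divide every cell over one interval at its current rate.

    Length multiplies by exp(rate·dt); phenotype-specific behavior kicks in
    above the nonpermissive temperature.  Returns the division events as
    (mother_id, daughter1_id, daughter2_id); positions are repacked at the
    end so the population stays overlap-free.
    """
    if not dt_s >= 0:
        raise ValueError("dt must be >= 0")
    nonpermissive = temperature_c > model.nonpermissive_temp_c
    dt_h = dt_s / 3600.0
    events: list[tuple[int, int, int]] = []
    for colony in pop.colonies:
        for lane_idx in sorted(colony.lanes):
            for cell_id in list(colony.lanes[lane_idx]):
                cell = pop.cells[cell_id]
                factor = math.exp(cell.current_rate_per_h * dt_h)
                if cell.phenotype == SHRINKING and nonpermissive:
                    decay = math.exp(-model.shrink_rate_per_h * dt_h)
                    cell.length_um = max(
                        cell.length_um * math.sqrt(decay), cell.width_um * 1.0001
                    )
                    cell.width_um *= math.sqrt(decay)
                elif cell.phenotype == ROUNDING and nonpermissive:
                    # elongation redirected into width until aspect ~ 1
                    if cell.width_um < cell.length_um:
                        cell.width_um = min(
                            cell.width_um * factor, cell.length_um
                        )
                else:
                    cell.length_um *= factor
                divides = (
                    cell.length_um > cell.division_threshold_um
                    and cell.length_um > 2.0 * cell.width_um
                    and (
                        cell.phenotype == WILDTYPE
                        or (cell.phenotype == FILAMENTOUS and not nonpermissive)
                        or (cell.phenotype == ROUNDING and not nonpermissive)
                        or (cell.phenotype == SHRINKING and not nonpermissive)
                    )
                )
                if divides:
                    d1, d2 = _divide(pop, colony, lane_idx, cell, model, rng)
                    events.append((cell.cell_id, d1, d2))
    pop.repack_all()
    return events


def make_initial_population(
    n_cells: int,
    field_um: tuple[float, float],
    model: GrowthModel,
    rng: np.random.Generator,
    temperature_c: float = 37.0,
    phenotype: str = WILDTYPE,
    width_um: float = 1.0,
    margin_um: float = 12.0,
    min_spacing_um: float = 20.0,
) -> CellPopulation:
    """Scatter founder cells over the field with a minimum spacing."""
    pop = CellPopulation()
    centers: list[tuple[float, float]] = []
    h, w = field_um
    margin_um = min(margin_um, h / 4.0, w / 4.0)
    tries = 0
    spacing = min_spacing_um
    while len(centers) < n_cells:
        tries += 1
        if tries > 5000:
            # field too small for the requested spacing: relax it gradually
            spacing *= 0.8
            tries = 0
            if spacing < 2.0:
                raise RuntimeError("cannot place founders; reduce n_cells")
        y = margin_um + rng.random() * (h - 2 * margin_um)
        x = margin_um + rng.random() * (w - 2 * margin_um)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= spacing**2 for cy, cx in centers):
            centers.append((y, x))
    base_rate = target_rate(model, temperature_c)
    for k, (y, x) in enumerate(centers):
        scale = max(1.0 + model.rate_cv * rng.standard_normal(), 0.2)
        thresh = model.division_length_mean_um * (
            1.0 + model.division_cv * rng.standard_normal()
        )
        length = 2.5 + 2.0 * rng.random()
        pop.add_founder(
            CellState(
                cell_id=k,
                parent_id=-1,
                length_um=length,
                width_um=width_um,
                orientation_rad=rng.random() * math.pi,
                centroid_um=(y, x),
                current_rate_per_h=base_rate * scale,
                rate_scale=scale,
                phenotype=phenotype,
                division_threshold_um=max(thresh, 2.5 * width_um),
            )
        )
    return pop


# ---------------------------------------------------------------------------
# Rendering


@dataclass(frozen=True)
class MovieConfig:
    """Imaging parameters of the synthetic microscope.

    30-s frames at 0.1 µm/px emulate a 60X-equivalent phase-contrast setup.
    ``drift_per_frame_px`` is a constant (row, col) stage drift accumulated
    every frame.
    """

    frame_interval_s: float = 30.0
    pixel_size_um: float = 0.1
    shape: tuple[int, int] = (1024, 1024)
    noise_sd: float = 0.02
    drift_per_frame_px: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    background: float = 0.55
    cell_intensity: float = 0.25
    halo_intensity: float = 0.80
    halo_width_px: float = 2.0
    halo_gap_px: float = 1.0  # stand-off between cell edge and halo ring
    blur_sigma_px: float = 0.6
    crowding_stop_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not self.frame_interval_s > 0:
            raise ValueError("frame interval must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be positive")

    @property
    def field_um(self) -> tuple[float, float]:
        return (
            self.shape[0] * self.pixel_size_um,
            self.shape[1] * self.pixel_size_um,
        )


def render_frame(
    pop: CellPopulation,
    config: MovieConfig,
    rng: np.random.Generator | None = None,
    drift_px: tuple[float, float] = (0.0, 0.0),
    return_labels: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Render one phase-contrast-like frame (float32 in [0, 1]).

    Cells are dark capsules with a bright halo ring on a mid-gray
    background; the whole scene is shifted by ``drift_px``, softly blurred
    and corrupted with Gaussian noise.  With ``return_labels=True`` also
    returns the int32 ground-truth label mask (cell ids + 1, 0 background).
    """
    h, w = config.shape
    canvas = np.full((h, w), config.background, dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.int32) if return_labels else None
    # halo pass first so interiors of neighbors paint over halos
    for pass_kind in ("halo", "body"):
        for cell in pop.cells.values():
            cy = cell.centroid_um[0] / config.pixel_size_um + drift_px[0]
            cx = cell.centroid_um[1] / config.pixel_size_um + drift_px[1]
            r = cell.width_um / 2.0 / config.pixel_size_um
            half = max(cell.length_um / 2.0 / config.pixel_size_um - r, 0.0)
            dy, dx = math.sin(cell.orientation_rad), math.cos(cell.orientation_rad)
            pad = r + config.halo_gap_px + config.halo_width_px + 3.0
            extent = half * max(abs(dy), abs(dx)) + pad
            r0 = max(int(cy - half * abs(dy) - pad), 0)
            r1 = min(int(cy + half * abs(dy) + pad) + 1, h)
            c0 = max(int(cx - half * abs(dx) - pad), 0)
            c1 = min(int(cx + half * abs(dx) + pad) + 1, w)
            if r0 >= r1 or c0 >= c1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            # distance from each pixel to the capsule spine segment
            py, px = yy - cy, xx - cx
            t = np.clip(py * dy + px * dx, -half, half)
            d = np.hypot(py - t * dy, px - t * dx)
            patch = canvas[r0:r1, c0:c1]
            if pass_kind == "halo":
                r_in = r + config.halo_gap_px
                ring = (d > r_in) & (d <= r_in + config.halo_width_px)
                fall = 1.0 - (d - r_in) / config.halo_width_px
                val = config.background + (
                    config.halo_intensity - config.background
                ) * np.clip(fall, 0.0, 1.0)
                patch[ring] = np.maximum(patch[ring], val[ring])
            else:
                alpha = np.clip(r + 0.5 - d, 0.0, 1.0)  # antialiased edge
                patch[:] = alpha * config.cell_intensity + (1 - alpha) * patch
                if labels is not None:
                    labels[r0:r1, c0:c1][d <= r] = cell.cell_id + 1
    canvas = ndimage.gaussian_filter(canvas, config.blur_sigma_px)
    if rng is not None and config.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sd, canvas.shape)
    frame = np.clip(canvas, 0.0, 1.0).astype(np.float32)
    if return_labels:
        return frame, labels
    return frame


GROUND_TRUTH_COLUMNS = [
    "frame",
    "cell_id",
    "parent_id",
    "centroid_row_px",
    "centroid_col_px",
    "length_um",
    "width_um",
    "rate_per_h",
    "phenotype",
    "analyzable",
]


@dataclass
class SimulatedMovie:
    """In-memory result of :func:`simulate_movie`."""

    stack: np.ndarray | None  # (n_frames, H, W) uint16, None if not rendered
    ground_truth: pd.DataFrame
    config: MovieConfig
    model: GrowthModel

    def save(self, stack_path=None, ground_truth_path=None) -> None:
        if stack_path is not None and self.stack is not None:
            tifffile.imwrite(stack_path, self.stack, photometric="minisblack")
        if ground_truth_path is not None:
            self.ground_truth.to_csv(ground_truth_path, index=False)


def _temperature_at(trace: TemperatureTrace, t_s: float) -> float:
    i = int(np.searchsorted(trace.time_s, t_s, side="right")) - 1
    return float(trace.temp_c[max(i, 0)])


def simulate_movie(
    config: MovieConfig,
    model: GrowthModel,
    trace: TemperatureTrace,
    initial_pop: CellPopulation | None = None,
    n_cells: int = 16,
    duration_s: float | None = None,
    phenotype: str = WILDTYPE,
    render: bool = True,
) -> SimulatedMovie:
    """Drive a population with a temperature trace and image it every frame.

    The growth response follows the *measured* temperature in the trace —
    what the device itself knows.  ``duration_s`` defaults to the trace
    length; a trace shorter than the requested duration is an error.
    Everything (placement, division noise, camera noise) derives from
    ``config.seed``, so the ground-truth table is bit-reproducible.
    With ``render=False`` only the ground truth is produced (fast path for
    physiology-level studies).
    """
    if duration_s is None:
        duration_s = trace.duration_s
    if trace.duration_s < duration_s - 1e-9:
        raise ValueError(
            f"trace ({trace.duration_s} s) does not cover the movie ({duration_s} s)"
        )
    n_frames = int(math.floor(duration_s / config.frame_interval_s)) + 1
    # separate streams: ground truth must not depend on whether frames render
    seq_dyn, seq_cam = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(seq_dyn)
    rng_cam = np.random.default_rng(seq_cam)
    if initial_pop is None:
        t0_temp = _temperature_at(trace, 0.0)
        initial_pop = make_initial_population(
            n_cells, config.field_um, model, rng,
            temperature_c=t0_temp, phenotype=phenotype,
        )
    pop = initial_pop
    shifts = setpoint_transitions(trace)
    field_area = config.field_um[0] * config.field_um[1]
    frames = [] if render else None
    records: list[tuple] = []
    drift = np.zeros(2)
    for k in range(n_frames):
        t = k * config.frame_interval_s
        if k > 0:
            temp = _temperature_at(trace, t)
            n_up = sum(1 for ts_, lo, hi in shifts if ts_ <= t and hi > lo)
            n_down = sum(1 for ts_, lo, hi in shifts if ts_ <= t and hi < lo)
            # direction of the most recent shift decides which count applies
            last = max((s for s in shifts if s[0] <= t), default=None, key=lambda s: s[0])
            count = 0
            if last is not None:
                count = n_up if last[2] > last[1] else n_down
            for cell in pop.cells.values():
                relax_rate(cell, model, temp, config.frame_interval_s, count)
            advance_population(pop, model, temp, config.frame_interval_s, rng)
            drift = drift + np.array(config.drift_per_frame_px)
        analyzable = pop.total_area_um2() / field_area <= config.crowding_stop_fraction
        if render:
            frames.append(
                render_frame(pop, config, rng_cam, drift_px=tuple(drift))
            )
        for cell in pop.cells.values():
            records.append(
                (
                    k,
                    cell.cell_id,
                    cell.parent_id,
                    cell.centroid_um[0] / config.pixel_size_um + drift[0],
                    cell.centroid_um[1] / config.pixel_size_um + drift[1],
                    cell.length_um,
                    cell.width_um,
                    cell.current_rate_per_h,
                    cell.phenotype,
                    analyzable,
                )
            )
    gt = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    stack = None
    if render:
        stack = (np.stack(frames) * 65535.0).astype(np.uint16)
    return SimulatedMovie(stack=stack, ground_truth=gt, config=config, model=model)


def ground_truth_divisions(gt: pd.DataFrame) -> pd.DataFrame:
    """Division events (frame, mother_id, daughter ids) from a truth table."""
    first_seen = gt.groupby("cell_id")["frame"].min()
    parents = gt.groupby("cell_id")["parent_id"].first()
    rows = []
    for mother, group in parents[parents >= 0].groupby(parents):
        daughters = sorted(group.index)
        if len(daughters) == 2:
            frame = int(first_seen[daughters[0]])
            rows.append((frame, int(mother), daughters[0], daughters[1]))
    return pd.DataFrame(
        rows, columns=["frame", "mother_id", "daughter1", "daughter2"]
    ).sort_values("frame", ignore_index=True)
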