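"""Single-cell quantification pipeline for phase-contrast time-lapse stacks.

The stages mirror a standard rod-shaped-bacteria workflow:

1. **Registration** — per-frame integer-pixel drift correction by
   cross-correlation between consecutive frames (template-matching style),
   accumulated relative to the first frame.
2. **Segmentation** — classical: background-referenced thresholding of the
   dark cell interiors, morphological cleaning, and marker-based watershed
   splitting of touching cells.  (A learned segmenter could drop in here;
   the pipeline contract is defined against ground-truthed synthetic
   images, which the classical method satisfies.)
3. **Geometry** — subpixel contours from the 0.5-level of the smoothed
   label support; a centerline (medial path, spline-smoothed, extended to
   the poles) gives pole-to-pole length, and twice the medial-axis distance
   gives the width profile.
4. **Tracking** — frame-to-frame assignment by maximal mask overlap with a
   nearest-centroid gate; one-to-two assignments are recorded as division
   events that end the mother track and start two daughters.
5. **Growth rates** — λ = d(log L)/dt by central differences on smoothed
   log-length, pooled into time-binned population curves, plus division
   counts in 5-min windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import splev, splprep
from shapely.geometry import LineString, Polygon
from skimage import measure, morphology, registration, segmentation
from skimage.filters import gaussian, threshold_otsu


class DegenerateRegionError(ValueError):
    """Region too small to carry a subpixel contour."""


# ---------------------------------------------------------------------------
# Registration


def register_stack(
    stack: np.ndarray, min_confidence: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Align a (n, H, W) stack by integer-pixel drift correction.

    Each frame is cross-correlated against the first frame (the reference),
    so slow sub-pixel drift is detected once it accumulates to a pixel.
    Returns (aligned stack, offsets) where ``offsets[k]`` is the (row, col)
    shift that was *removed* from frame k.  Frames whose normalized
    correlation with the reference falls below ``min_confidence`` keep the
    previous frame's offset and trigger a warning.
    """
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (n>=2, H, W) stack")
    n = stack.shape[0]
    offsets = np.zeros((n, 2))
    aligned = np.empty_like(stack)
    aligned[0] = stack[0]
    ref = stack[0].astype(float)
    for k in range(1, n):
        cur = stack[k].astype(float)
        shift, error, _ = registration.phase_cross_correlation(
            ref, cur, upsample_factor=1, normalization=None
        )
        confidence = 1.0 - float(error)
        if not np.isfinite(confidence) or confidence < min_confidence:
            warnings.warn(
                f"frame {k}: registration confidence {confidence:.2f} below "
                f"{min_confidence}; keeping previous offset",
                stacklevel=2,
            )
            shift = offsets[k - 1]
        offsets[k] = shift
        aligned[k] = np.roll(
            stack[k], (int(round(shift[0])), int(round(shift[1]))), axis=(0, 1)
        )
    return aligned, offsets


# ---------------------------------------------------------------------------
# Segmentation


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the classical segmenter (pixel units)."""

    smooth_sigma_px: float = 0.6
    min_area_px: int = 60
    marker_rel_height: float = 0.75
    min_contrast: float = 0.08  # Otsu classes closer than this => blank frame


def segment_frame(
    image: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Label dark cells in one grayscale frame; 0 is background.

    Blank frames yield an empty mask rather than an error.  Touching cells
    are split by a watershed seeded at the high plateaus of the distance
    transform within each connected component.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    sm = gaussian(img, params.smooth_sigma_px, preserve_range=True)
    thr = threshold_otsu(sm)
    dark = sm < thr
    # guard: on a cell-free frame Otsu just splits the noise
    if dark.any() and not dark.all():
        if (sm[~dark].mean() - sm[dark].mean()) < params.min_contrast * np.ptp(sm):
            return np.zeros(img.shape, dtype=np.int32)
        if (sm[~dark].mean() - sm[dark].mean()) < 3.0 * sm[dark].std():
            return np.zeros(img.shape, dtype=np.int32)
    # refine to the midpoint of cell interior and true background: Otsu's
    # split is biased by the bright halos, which shrinks the masks
    cell_level = sm[dark].mean()
    bg_level = np.median(sm[~dark])
    dark = sm < 0.5 * (cell_level + bg_level)
    mask = morphology.remove_small_objects(dark, max_size=params.min_area_px - 1)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    labels, _ = ndimage.label(mask)
    out = np.zeros(img.shape, dtype=np.int32)
    next_label = 1
    edt = ndimage.distance_transform_edt(mask)
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        sub = labels[sl] == idx
        sub_edt = edt[sl] * sub
        peak = sub_edt.max()
        markers, n_mark = ndimage.label(sub_edt > params.marker_rel_height * peak)
        if n_mark > 1:
            split = segmentation.watershed(-sub_edt, markers, mask=sub)
            for m in range(1, n_mark + 1):
                piece = split == m
                if piece.sum() >= params.min_area_px:
                    out[sl][piece] = next_label
                    next_label += 1
        else:
            out[sl][sub] = next_label
            next_label += 1
    return out


# ---------------------------------------------------------------------------
# Subpixel geometry


def extract_contour(
    mask: np.ndarray, label: int, smooth_sigma_px: float = 0.75
) -> np.ndarray:
    """Closed subpixel contour of one label: (m, 2) array of (row, col).

    The binary support is smoothed and traced at its 0.5 level, giving a
    subpixel polygon.  Tiny regions (no interior at the 0.5 level) raise
    :class:`DegenerateRegionError`.
    """
    support = mask == label
    if not support.any():
        raise ValueError(f"label {label} not present in mask")
    sl = ndimage.find_objects(support.astype(np.int8))[0]
    pad = int(3 * smooth_sigma_px) + 2
    r0 = max(sl[0].start - pad, 0)
    c0 = max(sl[1].start - pad, 0)
    r1 = min(sl[0].stop + pad, mask.shape[0])
    c1 = min(sl[1].stop + pad, mask.shape[1])
    patch = support[r0:r1, c0:c1].astype(float)
    smooth = ndimage.gaussian_filter(patch, smooth_sigma_px)
    contours = measure.find_contours(smooth, 0.5)
    if not contours:
        raise DegenerateRegionError(
            f"label {label} too small for a subpixel contour"
        )
    contour = max(contours, key=len)
    if len(contour) < 8:
        raise DegenerateRegionError(f"label {label}: degenerate contour")
    contour = contour + [r0, c0]
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    return contour


def contour_area(contour: np.ndarray) -> float:
    """Enclosed (shoelace) area of a closed contour, px²."""
    y, x = contour[:, 0], contour[:, 1]
    return 0.5 * abs(float(np.dot(y[:-1], x[1:]) - np.dot(y[1:], x[:-1])))


def _skeleton_path(mask_patch: np.ndarray) -> np.ndarray | None:
    """Longest simple path through the skeleton of a binary patch."""
    skel = morphology.skeletonize(mask_patch)
    pts = np.argwhere(skel)
    if len(pts) < 2:
        return None
    idx = {tuple(p): i for i, p in enumerate(pts)}
    nbrs: list[list[int]] = [[] for _ in pts]
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = idx.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int) -> tuple[np.ndarray, int]:
        dist = np.full(len(pts), -1)
        parent = np.full(len(pts), -1)
        dist[start] = 0
        queue = [start]
        far = start
        while queue:
            u = queue.pop(0)
            for v in nbrs[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    parent[v] = u
                    if dist[v] > dist[far]:
                        far = v
                    queue.append(v)
        return parent, far

    _, a = bfs(0)
    parent, b = bfs(a)
    path = [b]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return pts[path[::-1]]


def centerline_and_dims(
    contour: np.ndarray, pixel_size_um: float = 1.0, upsample: int = 3
) -> tuple[float, float, np.ndarray]:
    """Pole-to-pole length, median width and width profile of a rod contour.

    The contour is rasterized; the medial path of the rasterized support is
    smoothed with a spline and extended along its end tangents to the
    contour (the poles).  Length is the arc length of that centerline;
    the width profile is twice the distance transform along it.  For
    near-round contours (no usable medial path) the equivalent-circle
    diameter is returned for both dimensions, so length ≈ width — the
    signature of the rounding phenotype.

    Raises ``ValueError`` on a self-intersecting contour.
    """
    poly = Polygon(contour)
    if not poly.is_valid:
        raise ValueError("self-intersecting contour")
    # work on an upsampled grid to beat pixel quantization of the medial axis
    up = max(int(upsample), 1)
    cont_up = contour * up
    rmin, cmin = np.floor(cont_up.min(axis=0)).astype(int) - 2
    rmax, cmax = np.ceil(cont_up.max(axis=0)).astype(int) + 3
    hh, ww = rmax - rmin, cmax - cmin
    from skimage.draw import polygon as _draw_polygon

    inside = np.zeros((hh, ww), dtype=bool)
    pr, pc = _draw_polygon(cont_up[:, 0] - rmin, cont_up[:, 1] - cmin, (hh, ww))
    inside[pr, pc] = True
    if inside.sum() < 4:
        raise DegenerateRegionError("contour encloses too few pixels")
    edt = ndimage.distance_transform_edt(inside)
    path = _skeleton_path(inside)
    equiv_diam = 2.0 * math.sqrt(poly.area / math.pi) * up
    if path is None or len(path) < 5:
        # blob with no elongation: report the equivalent-circle diameter
        d = equiv_diam / up * pixel_size_um
        return d, d, np.array([d])
    pts = path.astype(float)
    # spline-smooth the pixelated medial path
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tck, _ = splprep(
                [pts[:, 0], pts[:, 1]], s=max(len(pts) * 0.5, 2.0), k=min(3, len(pts) - 1)
            )
        uu = np.linspace(0, 1, max(len(pts) * 2, 32))
        ry, rx = splev(uu, tck)
        mid = np.column_stack([ry, rx])
    except Exception:
        mid = pts
    # extend each end along its tangent until it leaves the contour polygon
    poly_up = Polygon(cont_up)

    def extend(end: np.ndarray, tangent: np.ndarray) -> np.ndarray:
        norm = np.hypot(*tangent)
        if norm == 0:
            return end
        tangent = tangent / norm
        probe = LineString([end, end + tangent * max(hh + ww, 8)])
        inter = probe.intersection(poly_up)
        if inter.is_empty:
            return end
        far = max(
            (np.array(c) for g in getattr(inter, "geoms", [inter]) for c in g.coords),
            key=lambda c: np.hypot(*(c - end)),
        )
        return far

    k_t = min(4, len(mid) - 1)
    start = extend(mid[0] + [rmin, cmin], (mid[0] - mid[k_t]))
    stop = extend(mid[-1] + [rmin, cmin], (mid[-1] - mid[-1 - k_t]))
    center = mid + [rmin, cmin]
    full = np.vstack([start, center, stop])
    seglen = np.hypot(*np.diff(full, axis=0).T)
    length_px = float(seglen.sum()) / up
    # width: twice the exact distance from the centerline to the contour
    import shapely

    boundary = LineString(cont_up)
    pts = shapely.points(mid + [rmin, cmin])
    widths_px = 2.0 * shapely.distance(boundary, pts) / up
    widths_px = widths_px[widths_px > 0]
    if widths_px.size == 0:
        widths_px = np.array([equiv_diam / up])
    length_px = max(length_px, float(np.median(widths_px)))
    return (
        length_px * pixel_size_um,
        float(np.median(widths_px)) * pixel_size_um,
        widths_px * pixel_size_um,
    )


# ---------------------------------------------------------------------------
# Measurement + tracking


@dataclass
class RegionMeasurement:
    label: int
    centroid: tuple[float, float]
    area_px: float
    length_um: float
    width_um: float


def measure_frame(
    labels: np.ndarray, pixel_size_um: float
) -> list[RegionMeasurement]:
    """Contour + centerline measurements for every label in a mask."""
    out = []
    for region in measure.regionprops(labels):
        try:
            contour = extract_contour(labels, region.label)
            length, width, _ = centerline_and_dims(contour, pixel_size_um)
        except (DegenerateRegionError, ValueError):
            continue
        out.append(
            RegionMeasurement(
                label=region.label,
                centroid=region.centroid,
                area_px=float(region.area),
                length_um=length,
                width_um=width,
            )
        )
    return out


@dataclass
class Lineage:
    """One tracked cell: contiguous per-frame records until division/loss."""

    track_id: int
    parent_track: int = -1
    frames: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    lengths_um: list[float] = field(default_factory=list)
    widths_um: list[float] = field(default_factory=list)
    daughters: tuple[int, int] | None = None
    division_frame: int | None = None
    flagged: bool = False  # ended by ambiguity rather than division/exit

    def append(self, frame: int, meas: RegionMeasurement) -> None:
        self.frames.append(frame)
        self.centroids.append(meas.centroid)
        self.lengths_um.append(meas.length_um)
        self.widths_um.append(meas.width_um)


def track_cells(
    label_stack: list[np.ndarray] | np.ndarray,
    measurements: list[list[RegionMeasurement]],
    max_displacement_px: float = 10.0,
) -> list[Lineage]:
    """Link per-frame labels into lineages by maximal mask overlap.

    For each label in frame k+1 the best-overlapping label of frame k is its
    predecessor (fallback: nearest centroid within ``max_displacement_px``).
    A predecessor with two successors divides — provided the split is
    biologically plausible (each daughter no more than ~70% of the mother,
    combined length close to the mother's): its track ends and two daughter
    tracks start.  Implausible one-to-two assignments (e.g. a neighbor
    sliding over the mother's old footprint) continue the best-overlap
    child and flag the track.  More than two successors flags the track as
    ambiguous.
    """
    n = len(label_stack)
    lineages: list[Lineage] = []
    active: dict[int, int] = {}  # label in current frame -> lineage index
    meas0 = {m.label: m for m in measurements[0]}
    for lab, m in meas0.items():
        lin = Lineage(track_id=len(lineages))
        lin.append(0, m)
        active[lab] = lin.track_id
        lineages.append(lin)
    for k in range(1, n):
        prev_labels = label_stack[k - 1]
        cur_labels = label_stack[k]
        cur_meas = {m.label: m for m in measurements[k]}
        prev_meas = {m.label: m for m in measurements[k - 1]}
        # overlap histogram between the two label images
        both = (prev_labels > 0) & (cur_labels > 0)
        pairs, counts = np.unique(
            np.stack([prev_labels[both], cur_labels[both]]), axis=1, return_counts=True
        )
        best_parent: dict[int, tuple[int, int]] = {}
        for (p, c), cnt in zip(pairs.T, counts):
            if c not in cur_meas or p not in prev_meas:
                continue
            if c not in best_parent or cnt > best_parent[c][1]:
                best_parent[c] = (int(p), int(cnt))
        children: dict[int, list[int]] = {}
        for c, m in cur_meas.items():
            parent = best_parent.get(c, (None, 0))[0]
            if parent is None:
                # fallback: nearest previous centroid within the gate
                dists = {
                    p: math.hypot(
                        m.centroid[0] - pm.centroid[0], m.centroid[1] - pm.centroid[1]
                    )
                    for p, pm in prev_meas.items()
                }
                if dists:
                    p_near, d_near = min(dists.items(), key=lambda kv: kv[1])
                    if d_near <= max_displacement_px:
                        parent = p_near
            if parent is not None:
                children.setdefault(parent, []).append(c)
        new_active: dict[int, int] = {}
        for parent_lab, childs in children.items():
            lin_idx = active.get(parent_lab)
            if lin_idx is None:
                for c in childs:
                    lin = Lineage(track_id=len(lineages))
                    lin.append(k, cur_meas[c])
                    new_active[c] = lin.track_id
                    lineages.append(lin)
                continue
            lin = lineages[lin_idx]
            if len(childs) == 1:
                c = childs[0]
                m = cur_meas[c]
                pm = prev_meas[parent_lab]
                disp = math.hypot(
                    m.centroid[0] - pm.centroid[0], m.centroid[1] - pm.centroid[1]
                )
                ratio = m.length_um / pm.length_um if pm.length_um > 0 else 1.0
                wratio = m.width_um / pm.width_um if pm.width_um > 0 else 1.0
                if (
                    disp > max_displacement_px
                    or not 0.75 <= ratio <= 1.35
                    or not 0.7 <= wratio <= 1.4
                ):
                    # a jump or a length discontinuity (e.g. two touching
                    # cells transiently merging into one blob): end the
                    # track so the artifact never enters a rate estimate
                    lin.flagged = True
                    nlin = Lineage(track_id=len(lineages))
                    nlin.append(k, m)
                    new_active[c] = nlin.track_id
                    lineages.append(nlin)
                else:
                    lin.append(k, m)
                    new_active[c] = lin_idx
            elif len(childs) == 2:
                mother_len = prev_meas[parent_lab].length_um
                d_lens = [cur_meas[c].length_um for c in childs]
                plausible = (
                    len(lin.frames) >= 2  # a 1-frame "mother" is usually a
                    # transient merge of neighbors splitting apart again
                    and max(d_lens) <= 0.7 * mother_len
                    and 0.7 * mother_len <= sum(d_lens) <= 1.3 * mother_len
                )
                if plausible:
                    dids = []
                    for c in childs:
                        d = Lineage(track_id=len(lineages), parent_track=lin_idx)
                        d.append(k, cur_meas[c])
                        new_active[c] = d.track_id
                        lineages.append(d)
                        dids.append(d.track_id)
                    lin.daughters = (dids[0], dids[1])
                    lin.division_frame = k
                else:
                    # a neighbor slid over this track's footprint, not a
                    # division: end the track here and start fresh ones, so
                    # the spurious length jump never enters a rate estimate
                    lin.flagged = True
                    for c in childs:
                        d = Lineage(track_id=len(lineages))
                        d.append(k, cur_meas[c])
                        new_active[c] = d.track_id
                        lineages.append(d)
            else:
                lin.flagged = True
                for c in childs:
                    d = Lineage(track_id=len(lineages))
                    d.append(k, cur_meas[c])
                    new_active[c] = d.track_id
                    lineages.append(d)
        # labels with no parent at all: brand-new tracks
        for c, m in cur_meas.items():
            if c not in new_active:
                lin = Lineage(track_id=len(lineages))
                lin.append(k, m)
                new_active[c] = lin.track_id
                lineages.append(lin)
        active = new_active
    return lineages


# ---------------------------------------------------------------------------
# Growth rates and population summaries


def growth_rates(
    lineage: Lineage,
    frame_interval_s: float,
    smoothing_window: int = 5,
) -> pd.DataFrame:
    """λ(t) = d log L / dt for one track, h⁻¹.

    Log-lengths are smoothed with a centered moving average, then
    differentiated by central differences; only interior samples with a full
    smoothing window are reported.  Tracks shorter than the window return an
    empty frame.  (Tracks never span a division — division ends a track —
    so no masking is needed within one lineage.)
    """
    n = len(lineage.frames)
    if n <= smoothing_window or n < 3:
        return pd.DataFrame(columns=["time_s", "rate_per_h"])
    logl = np.log(np.asarray(lineage.lengths_um))
    kernel = np.ones(smoothing_window) / smoothing_window
    sm = np.convolve(logl, kernel, mode="valid")  # length n - w + 1
    t = np.asarray(lineage.frames, dtype=float) * frame_interval_s
    t_sm = t[smoothing_window // 2 : smoothing_window // 2 + len(sm)]
    rate = np.gradient(sm, t_sm) * 3600.0
    return pd.DataFrame({"time_s": t_sm, "rate_per_h": rate})


def bin_population(
    rate_series: list[pd.DataFrame], window_min: float = 2.5
) -> pd.DataFrame:
    """Pool per-cell rate series into a time-binned population curve.

    Returns (bin_center_min, mean_rate_per_h, sd_per_h, n) with one row per
    bin that holds at least one sample.
    """
    if not rate_series:
        return pd.DataFrame(
            columns=["bin_center_min", "mean_rate_per_h", "sd_per_h", "n"]
        )
    allpts = pd.concat(rate_series, ignore_index=True)
    if allpts.empty:
        return pd.DataFrame(
            columns=["bin_center_min", "mean_rate_per_h", "sd_per_h", "n"]
        )
    t_min = allpts["time_s"] / 60.0
    idx = np.floor(t_min / window_min).astype(int)
    rows = []
    for k, grp in allpts.groupby(idx):
        vals = grp["rate_per_h"].to_numpy()
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(((k + 0.5) * window_min, float(vals.mean()), sd, len(vals)))
    return pd.DataFrame(
        rows, columns=["bin_center_min", "mean_rate_per_h", "sd_per_h", "n"]
    )


def count_divisions(
    lineages: list[Lineage],
    frame_interval_s: float,
    window_min: float = 5.0,
    total_duration_s: float | None = None,
) -> pd.DataFrame:
    """Histogram of division events in fixed time windows (5 min default)."""
    times = [
        lin.division_frame * frame_interval_s
        for lin in lineages
        if lin.division_frame is not None
    ]
    if total_duration_s is None:
        last = max(
            (lin.frames[-1] for lin in lineages if lin.frames), default=0
        )
        total_duration_s = last * frame_interval_s
    n_bins = max(int(math.ceil(total_duration_s / 60.0 / window_min)), 1)
    edges = np.arange(n_bins + 1) * window_min
    counts, _ = np.histogram(np.asarray(times) / 60.0, bins=edges)
    return pd.DataFrame(
        {
            "bin_start_min": edges[:-1],
            "bin_end_min": edges[1:],
            "n_divisions": counts,
        }
    )


# ---------------------------------------------------------------------------
# End-to-end convenience


@dataclass
class QuantResult:
    """Everything the pipeline extracts from one stack."""

    offsets: np.ndarray
    lineages: list[Lineage]
    lineage_table: pd.DataFrame
    population_curve: pd.DataFrame
    division_histogram: pd.DataFrame

    @property
    def n_tracks(self) -> int:
        return len(self.lineages)


def quantify_stack(
    stack: np.ndarray,
    pixel_size_um: float,
    frame_interval_s: float,
    seg_params: SegmentationParams = SegmentationParams(),
    smoothing_window: int = 5,
    bin_window_min: float = 2.5,
    division_window_min: float = 5.0,
    register: bool = True,
    min_track_frames: int = 3,
) -> QuantResult:
    """Run the full pipeline: register → segment → measure → track → rates."""
    if stack.ndim != 3:
        raise ValueError("expected a (n_frames, H, W) stack")
    if register and stack.shape[0] >= 2:
        aligned, offsets = register_stack(stack)
    else:
        aligned, offsets = stack, np.zeros((stack.shape[0], 2))
    label_stack = [segment_frame(frame, seg_params) for frame in aligned]
    measurements = [measure_frame(lab, pixel_size_um) for lab in label_stack]
    if stack.shape[0] >= 2:
        lineages = track_cells(label_stack, measurements)
    else:
        lineages = []
        for m in measurements[0]:
            lin = Lineage(track_id=len(lineages))
            lin.append(0, m)
            lineages.append(lin)
    rows = []
    for lin in lineages:
        for f, c, length, width in zip(
            lin.frames, lin.centroids, lin.lengths_um, lin.widths_um
        ):
            rows.append(
                (
                    lin.track_id,
                    lin.parent_track,
                    f,
                    c[0],
                    c[1],
                    length,
                    width,
                    lin.division_frame if lin.division_frame is not None else -1,
                    lin.flagged,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "parent_track",
            "frame",
            "centroid_row_px",
            "centroid_col_px",
            "length_um",
            "width_um",
            "division_frame",
            "flagged",
        ],
    )
    series = [
        growth_rates(lin, frame_interval_s, smoothing_window)
        for lin in lineages
        if len(lin.frames) >= max(min_track_frames, smoothing_window + 2)
    ]
    curve = bin_population([s for s in series if not s.empty], bin_window_min)
    divisions = count_divisions(
        lineages, frame_interval_s, division_window_min,
        total_duration_s=(stack.shape[0] - 1) * frame_interval_s,
    )
    return QuantResult(
        offsets=offsets,
        lineages=lineages,
        lineage_table=table,
        population_curve=curve,
        division_histogram=divisions,
    )


def population_mean_rate(result: QuantResult, min_n: int = 1) -> float:
    """n-weighted mean rate over all population-curve bins with n >= min_n."""
    curve = result.population_curve
    sel = curve[curve["n"] >= min_n]
    if sel.empty:
        return float("nan")
    return float(
        np.average(sel["mean_rate_per_h"], weights=sel["n"])
    )


def compare_divisions_to_truth(
    lineages: list[Lineage],
    truth_frames: list[int],
    tolerance_frames: int = 1,
) -> dict[str, float]:
    """Recall/precision of detected division events against ground truth."""
    detected = sorted(
        lin.division_frame for lin in lineages if lin.division_frame is not None
    )
    truth = sorted(truth_frames)
    used = np.zeros(len(detected), dtype=bool)
    hits = 0
    for tf in truth:
        for i, df_ in enumerate(detected):
            if not used[i] and abs(df_ - tf) <= tolerance_frames:
                used[i] = True
                hits += 1
                break
    recall = hits / len(truth) if truth else float("nan")
    precision = hits / len(detected) if detected else float("nan")
    return {
        "n_truth": len(truth),
        "n_detected": len(detected),
        "recall": recall,
        "precision": precision,
    }
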