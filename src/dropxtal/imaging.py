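"""Droplet segmentation and per-droplet crystal-appearance calling.

The pipeline mirrors how cross-polarized emulsion time-lapses are read
out in practice: droplets are segmented once from the first frame (the
capillary is sealed, so droplets do not move), simple intensity features
are extracted per droplet per frame, and a transparent threshold
classifier calls each droplet ``clear`` or ``crystal``.  Calls are
debounced (two consecutive crystal frames required) and made monotone:
once a droplet is called crystal it stays crystal.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.filters import sobel
from skimage.transform import hough_circle, hough_circle_peaks

from dropxtal.synthetic import NEVER, FrameStack

CLEAR = "clear"
CRYSTAL = "crystal"


@dataclass
class DropletROI:
    """A segmented droplet: fitted circle plus its pixel mask."""

    droplet_id: int
    center_px: tuple[float, float]  # (row, col)
    radius_px: float
    mask: np.ndarray  # boolean, full-frame shape

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("ROI mask must be non-empty")


@dataclass(frozen=True)
class FrameFeatures:
    """Per-droplet, per-frame classifier inputs.

    ``max_intensity`` is background-subtracted (max over the eroded
    interior minus the background mean) so that all three features are
    invariant to a constant offset applied to the whole frame, provided
    background statistics are recomputed.
    """

    droplet_id: int
    max_intensity: float
    bright_area_fraction: float
    gradient_energy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.bright_area_fraction <= 1.0):
            raise ValueError("bright_area_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Thresholds of the clear/crystal feature classifier.

    A droplet frame is called crystal iff its bright-area fraction is at
    least ``area`` OR its background-subtracted max intensity is at least
    ``max_intensity``.  Defaults were calibrated on seeded synthetic
    stacks rendered at the default noise level (see
    :func:`calibrate_thresholds`).
    """

    area: float = 0.01
    max_intensity: float = 0.4
    bright_k: float = 6.0  # "bright" = background mean + k * background sd


@dataclass
class DropletStateSeries:
    """Per-frame clear/crystal states of one droplet (monotone)."""

    droplet_id: int
    timestamps_s: np.ndarray
    states: list[str]
    first_crystal_time_s: float  # NEVER if the droplet stayed clear

    def __post_init__(self) -> None:
        if len(self.states) != len(self.timestamps_s):
            raise ValueError("states and timestamps must have equal length")
        seen_crystal = False
        for s in self.states:
            if s == CRYSTAL:
                seen_crystal = True
            elif seen_crystal:
                raise ValueError("states must be monotone: once crystal, never clear")


# ---------------------------------------------------------------------------
# Segmentation


def segment_droplets(
    first_frame: np.ndarray,
    min_radius_px: float,
    max_radius_px: float,
    accumulator_threshold: float = 0.35,
    canny_sigma: float = 2.0,
) -> list[DropletROI]:
    """Detect droplets in the first frame by circular Hough voting.

    The frame is contrast-normalized, Canny edges are extracted, and a
    circular Hough transform over integer radii in
    [min_radius_px, max_radius_px] votes for droplet boundaries.
    Candidates below ``accumulator_threshold`` (fraction of the circle
    perimeter supported by edges) are discarded; the rest are reduced by
    greedy non-maximum suppression at center distance ≥ 1.5·min_radius_px.
    ROIs are sorted by (row, col) and given ids 0..n−1.  Masks of distinct
    ROIs are disjoint: contested pixels go to the nearer center.
    """
    frame = np.asarray(first_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("first_frame must be a 2-D image")
    if not (0 < min_radius_px < max_radius_px):
        raise ValueError("need 0 < min_radius_px < max_radius_px")
    lo, hi = frame.min(), frame.max()
    if hi == lo:
        return []
    norm = (frame - lo) / (hi - lo)
    edges = canny(norm, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(int(math.floor(min_radius_px)), int(math.ceil(max_radius_px)) + 1)
    hspaces = hough_circle(edges, radii)
    accums, cols, rows, rads = hough_circle_peaks(
        hspaces,
        radii,
        min_xdistance=max(1, int(min_radius_px)),
        min_ydistance=max(1, int(min_radius_px)),
        threshold=accumulator_threshold,
    )
    if len(accums) == 0:
        return []

    # Greedy euclidean NMS (hough_circle_peaks suppresses per-axis only).
    order = np.argsort(accums)[::-1]
    min_sep = 1.5 * min_radius_px
    kept: list[int] = []
    for i in order:
        if all(
            (rows[i] - rows[j]) ** 2 + (cols[i] - cols[j]) ** 2 >= min_sep**2 for j in kept
        ):
            kept.append(i)
    centers = np.array([(rows[i], cols[i]) for i in kept], dtype=float)
    kept_radii = np.array([rads[i] for i in kept], dtype=float)
    order2 = np.lexsort((centers[:, 1], centers[:, 0]))
    centers, kept_radii = centers[order2], kept_radii[order2]

    rois = []
    for i, ((r0, c0), rad) in enumerate(zip(centers, kept_radii)):
        refined = _refine_radius(norm, (r0, c0), rad)
        mask = _disjoint_disk_mask(frame.shape, centers, i, refined)
        rois.append(
            DropletROI(droplet_id=i, center_px=(r0, c0), radius_px=float(refined), mask=mask)
        )
    return rois


def _refine_radius(
    norm: np.ndarray, center: tuple[float, float], radius: float, search_px: float = 4.0
) -> float:
    """Refine a Hough radius to the peak of the radial intensity profile.

    The droplet boundary is a bright ring; Canny tends to fire on its
    outer edge, so the raw Hough radius overshoots by a pixel or two.
    The centroid of the ring's intensity peak is a better boundary
    estimate (and an unbiased droplet-volume input downstream).
    """
    r0, c0 = center
    nrow, ncol = norm.shape
    lo = max(1.0, radius - search_px)
    hi = radius + search_px
    lo_r = max(0, int(r0 - hi) - 1)
    hi_r = min(nrow, int(r0 + hi) + 2)
    lo_c = max(0, int(c0 - hi) - 1)
    hi_c = min(ncol, int(c0 + hi) + 2)
    rows = np.arange(lo_r, hi_r)[:, None]
    cols = np.arange(lo_c, hi_c)[None, :]
    dist = np.hypot(rows - r0, cols - c0)
    sel = (dist >= lo) & (dist <= hi)
    if not sel.any():
        return radius
    bins = np.round(dist[sel] - lo).astype(int)
    vals = norm[lo_r:hi_r, lo_c:hi_c][sel]
    profile = np.bincount(bins, weights=vals) / np.maximum(np.bincount(bins), 1)
    peak = int(np.argmax(profile))
    # Sub-pixel: intensity-weighted centroid over the peak ± 2 bins.
    j = np.arange(max(0, peak - 2), min(len(profile), peak + 3))
    weights = np.maximum(profile[j] - profile.min(), 0)
    if weights.sum() == 0:
        return radius
    return float(lo + np.sum(j * weights) / weights.sum())


def _disjoint_disk_mask(
    shape: tuple[int, int], centers: np.ndarray, idx: int, radius: float
) -> np.ndarray:
    """Disk mask around centers[idx], yielding contested pixels to the nearer center."""
    r0, c0 = centers[idx]
    nrow, ncol = shape
    lo_r = max(0, int(math.floor(r0 - radius)))
    hi_r = min(nrow, int(math.ceil(r0 + radius)) + 1)
    lo_c = max(0, int(math.floor(c0 - radius)))
    hi_c = min(ncol, int(math.ceil(c0 + radius)) + 1)
    rows = np.arange(lo_r, hi_r)[:, None]
    cols = np.arange(lo_c, hi_c)[None, :]
    d2 = (rows - r0) ** 2 + (cols - c0) ** 2
    inside = d2 <= radius**2
    for j, (r1, c1) in enumerate(centers):
        if j == idx:
            continue
        if abs(r1 - r0) > 2 * radius + 1 or abs(c1 - c0) > 2 * radius + 1:
            continue
        other = (rows - r1) ** 2 + (cols - c1) ** 2
        inside &= d2 < other
    mask = np.zeros(shape, dtype=bool)
    mask[lo_r:hi_r, lo_c:hi_c] = inside
    return mask


# ---------------------------------------------------------------------------
# Features and classification


def background_stats(frame: np.ndarray, rois: list[DropletROI], pad_px: float = 3.0) -> tuple[float, float]:
    """Mean and sd of pixels outside every (padded) droplet disk."""
    frame = np.asarray(frame, dtype=float)
    outside = np.ones(frame.shape, dtype=bool)
    for roi in rois:
        r0, c0 = roi.center_px
        rad = roi.radius_px + pad_px
        lo_r = max(0, int(r0 - rad))
        hi_r = min(frame.shape[0], int(r0 + rad) + 1)
        lo_c = max(0, int(c0 - rad))
        hi_c = min(frame.shape[1], int(c0 + rad) + 1)
        rows = np.arange(lo_r, hi_r)[:, None]
        cols = np.arange(lo_c, hi_c)[None, :]
        outside[lo_r:hi_r, lo_c:hi_c] &= (rows - r0) ** 2 + (cols - c0) ** 2 > rad**2
    vals = frame[outside]
    if vals.size == 0:
        vals = frame.ravel()
    return float(vals.mean()), float(vals.std())


def _interior_mask(roi: DropletROI, erosion_fraction: float = 0.2) -> np.ndarray:
    """Eroded interior of the droplet disk: keeps the boundary ring out."""
    r0, c0 = roi.center_px
    rad = roi.radius_px * (1.0 - erosion_fraction) - 1.0
    nrow, ncol = roi.mask.shape
    if rad <= 0:
        return np.zeros((nrow, ncol), dtype=bool)
    lo_r = max(0, int(r0 - rad) - 1)
    hi_r = min(nrow, int(r0 + rad) + 2)
    lo_c = max(0, int(c0 - rad) - 1)
    hi_c = min(ncol, int(c0 + rad) + 2)
    rows = np.arange(lo_r, hi_r)[:, None]
    cols = np.arange(lo_c, hi_c)[None, :]
    interior = np.zeros((nrow, ncol), dtype=bool)
    interior[lo_r:hi_r, lo_c:hi_c] = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad**2
    return interior & roi.mask


def extract_features(
    frame: np.ndarray,
    roi: DropletROI,
    background: tuple[float, float],
    bright_k: float = 6.0,
) -> FrameFeatures:
    """Classifier features for one droplet in one frame.

    ``bright_area_fraction`` is the fraction of eroded-interior pixels
    exceeding background mean + ``bright_k``·sd; ``max_intensity`` is the
    interior maximum minus the background mean; ``gradient_energy`` is
    the mean Sobel gradient magnitude over the interior.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != roi.mask.shape:
        raise ValueError("frame and ROI mask shapes differ")
    interior = _interior_mask(roi)
    if not interior.any():
        raise ValueError(f"droplet {roi.droplet_id}: empty interior after erosion")
    bg_mean, bg_sd = background
    vals = frame[interior]
    bright = vals > bg_mean + bright_k * bg_sd
    # Sobel over the droplet bounding box only (cheap, identical inside).
    r0, c0 = roi.center_px
    rad = roi.radius_px + 2
    lo_r = max(0, int(r0 - rad))
    hi_r = min(frame.shape[0], int(r0 + rad) + 1)
    lo_c = max(0, int(c0 - rad))
    hi_c = min(frame.shape[1], int(c0 + rad) + 1)
    grad = sobel(frame[lo_r:hi_r, lo_c:hi_c])
    grad_interior = grad[interior[lo_r:hi_r, lo_c:hi_c]]
    return FrameFeatures(
        droplet_id=roi.droplet_id,
        max_intensity=float(vals.max() - bg_mean),
        bright_area_fraction=float(bright.mean()),
        gradient_energy=float(grad_interior.mean()),
    )


def classify_state(features: FrameFeatures, thresholds: ClassifierThresholds | None = None) -> str:
    """Call one droplet frame crystal or clear from its features."""
    th = thresholds or ClassifierThresholds()
    if features.bright_area_fraction >= th.area or features.max_intensity >= th.max_intensity:
        return CRYSTAL
    return CLEAR


def calibrate_thresholds(
    clear_features: list[FrameFeatures],
    crystal_features: list[FrameFeatures],
    bright_k: float = 6.0,
) -> ClassifierThresholds:
    """Choose thresholds separating labeled clear and crystal feature sets.

    Each threshold is placed at the geometric midpoint between the largest
    clear value and the smallest crystal value, so any margin present in
    the training set is split evenly.
    """
    if not clear_features or not crystal_features:
        raise ValueError("need at least one example of each class")

    def midpoint(lo: float, hi: float) -> float:
        lo = max(lo, 1e-6)
        hi = max(hi, lo)
        return math.sqrt(lo * hi)

    area = midpoint(
        max(f.bright_area_fraction for f in clear_features),
        min(f.bright_area_fraction for f in crystal_features),
    )
    mx = midpoint(
        max(f.max_intensity for f in clear_features),
        min(f.max_intensity for f in crystal_features),
    )
    return ClassifierThresholds(area=area, max_intensity=mx, bright_k=bright_k)


# ---------------------------------------------------------------------------
# Tracking


def track_states(
    stack: FrameStack,
    rois: list[DropletROI],
    thresholds: ClassifierThresholds | None = None,
    debounce_frames: int = 2,
) -> list[DropletStateSeries]:
    """Call per-droplet crystal appearance through the time-lapse.

    Droplets are stationary (sealed capillary), so first-frame ROIs apply
    to every frame.  Raw per-frame calls are debounced: a droplet is
    committed crystal from the first frame at which it classifies crystal
    in ``debounce_frames`` consecutive frames, and stays crystal onward.
    Background statistics are recomputed per frame.
    """
    if not rois:
        return []
    if stack.frames[0].shape != rois[0].mask.shape:
        raise ValueError("stack frame shape does not match ROI masks")
    th = thresholds or ClassifierThresholds()
    n_frames, n_drops = len(stack), len(rois)
    raw = np.zeros((n_frames, n_drops), dtype=bool)
    for k, frame in enumerate(stack.frames):
        bg = background_stats(frame, rois)
        for j, roi in enumerate(rois):
            feats = extract_features(frame, roi, bg, bright_k=th.bright_k)
            raw[k, j] = classify_state(feats, th) == CRYSTAL

    series = []
    for j, roi in enumerate(rois):
        commit = None
        for k in range(n_frames - debounce_frames + 1):
            if raw[k : k + debounce_frames, j].all():
                commit = k
                break
        if commit is None:
            states = [CLEAR] * n_frames
            first = NEVER
        else:
            states = [CLEAR] * commit + [CRYSTAL] * (n_frames - commit)
            first = float(stack.timestamps_s[commit])
        series.append(
            DropletStateSeries(
                droplet_id=roi.droplet_id,
                timestamps_s=stack.timestamps_s.copy(),
                states=states,
                first_crystal_time_s=first,
            )
        )
    return series


def estimate_drift(stack: FrameStack) -> np.ndarray:
    """Per-frame rigid drift (row, col) versus the first frame.

    Optional QC aid via phase cross-correlation of successive frames;
    droplets in a sealed capillary normally do not move, so tracking does
    not apply this by default.
    """
    from skimage.registration import phase_cross_correlation

    shifts = np.zeros((len(stack), 2))
    for k in range(1, len(stack)):
        shift, _, _ = phase_cross_correlation(
            stack.frames[k - 1], stack.frames[k], upsample_factor=4
        )
        shifts[k] = shifts[k - 1] + shift
    return shifts


# ---------------------------------------------------------------------------
# Serialization and QC overlays


def write_state_table(series: list[DropletStateSeries], path) -> None:
    """Long-format CSV: droplet_id, frame_index, time_s, state."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["droplet_id", "frame_index", "time_s", "state"])
        for s in series:
            for k, (t, state) in enumerate(zip(s.timestamps_s, s.states)):
                w.writerow([s.droplet_id, k, repr(float(t)), state])


def read_state_table(path) -> list[DropletStateSeries]:
    rows: dict[int, list[tuple[int, float, str]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            state = row["state"].strip().lower()
            if state not in (CLEAR, CRYSTAL):
                raise ValueError(f"unknown state {row['state']!r} for droplet {row['droplet_id']}")
            rows.setdefault(int(row["droplet_id"]), []).append(
                (int(row["frame_index"]), float(row["time_s"]), state)
            )
    series = []
    for droplet_id in sorted(rows):
        entries = sorted(rows[droplet_id])
        times = np.array([t for _, t, _ in entries])
        states = [s for _, _, s in entries]
        first = next(
            (t for t, s in zip(times, states) if s == CRYSTAL),
            NEVER,
        )
        series.append(
            DropletStateSeries(
                droplet_id=droplet_id,
                timestamps_s=times,
                states=states,
                first_crystal_time_s=float(first),
            )
        )
    return series


def write_summary_table(series: list[DropletStateSeries], path) -> None:
    """Summary CSV: droplet_id, first_crystal_time_s (empty = never)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["droplet_id", "first_crystal_time_s"])
        for s in series:
            t = "" if math.isinf(s.first_crystal_time_s) else repr(s.first_crystal_time_s)
            w.writerow([s.droplet_id, t])


def overlay_frame(
    frame: np.ndarray, rois: list[DropletROI], states: list[str]
) -> np.ndarray:
    """RGB QC overlay: red ring = clear droplet, green ring = crystal."""
    img = np.asarray(frame, dtype=float)
    rgb = np.stack([img, img, img], axis=-1)
    for roi, state in zip(rois, states):
        r0, c0 = roi.center_px
        rad = roi.radius_px
        lo_r = max(0, int(r0 - rad) - 2)
        hi_r = min(img.shape[0], int(r0 + rad) + 3)
        lo_c = max(0, int(c0 - rad) - 2)
        hi_c = min(img.shape[1], int(c0 + rad) + 3)
        rows = np.arange(lo_r, hi_r)[:, None]
        cols = np.arange(lo_c, hi_c)[None, :]
        ring = np.abs(np.hypot(rows - r0, cols - c0) - rad) <= 1.5
        channel = 1 if state == CRYSTAL else 0
        patch = rgb[lo_r:hi_r, lo_c:hi_c]
        patch[ring, :] = 0.0
        patch[ring, channel] = 1.0
    return np.clip(rgb, 0, 1)


def write_overlay_png(frame, rois, states, path) -> None:
    import imageio.v3 as iio

    rgb = (overlay_frame(frame, rois, states) * 255).astype(np.uint8)
    iio.imwrite(path, rgb)
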