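"""Synthetic droplet emulsions with stochastic crystal nucleation.

Generates ground-truth droplet populations whose nucleation times follow
the Poisson model P_crystal = J·V·dt (exponential waiting times with
per-droplet rate J·V), renders cross-polarized-style time-lapse frames in
which crystals appear as bright compact blobs on a dark background, and
simulates batch-crystallization outcome tables.  Everything is seeded and
bit-reproducible, so the imaging and kinetics stages can be tested against
known ground truth without any external data.

Units: μm for geometry, mm³ for droplet volume, mm⁻³ s⁻¹ for the
nucleation rate J, seconds for time.  Pixel intensities are floats in
[0, 1]; stacks are serialized as 16-bit grayscale TIFFs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

#: Sentinel for "this droplet never nucleates within the simulated horizon".
NEVER = math.inf

# Rendering constants (float intensity scale, [0, 1]).
BACKGROUND_LEVEL = 0.08
RING_LEVEL = 0.22
CRYSTAL_LEVEL = 0.95
CRYSTAL_MIN_RADIUS_PX = 2.0
CRYSTAL_GROWTH_PX_PER_S = 0.03
CRYSTAL_MAX_RADIUS_FRACTION = 0.4
RING_HALF_WIDTH_PX = 1.2


class CapacityError(RuntimeError):
    """Droplets could not be placed without overlap after bounded retries."""


def droplet_volume_mm3(radius_um: float, capillary_thickness_um: float = 200.0) -> float:
    """Volume of a droplet confined in a monolayer capillary, in mm³.

    If the droplet diameter fits within the capillary thickness the droplet
    is a sphere, V = 4/3·π·r³; otherwise it is squashed into a disk of
    height equal to the capillary thickness, V = π·r²·h.
    """
    if radius_um <= 0:
        raise ValueError("droplet radius must be positive")
    if capillary_thickness_um <= 0:
        raise ValueError("capillary thickness must be positive")
    um3_to_mm3 = 1e-9
    if 2.0 * radius_um <= capillary_thickness_um:
        return (4.0 / 3.0) * math.pi * radius_um**3 * um3_to_mm3
    return math.pi * radius_um**2 * capillary_thickness_um * um3_to_mm3


@dataclass(frozen=True)
class EmulsionConfig:
    """Parameters of a simulated emulsion experiment.

    ``nucleation_rate_J`` is the volumetric nucleation rate in mm⁻³ s⁻¹;
    each droplet of volume V then nucleates with exponential waiting time
    of rate J·V.  Frames are rendered on the grid 0, Δt, 2Δt, …,
    ``total_time_s`` with Δt = ``frame_interval_s`` (60 s by default —
    one frame per minute).
    """

    n_droplets: int = 200
    droplet_radius_um: float = 50.0
    capillary_thickness_um: float = 200.0
    nucleation_rate_J: float = 4.4
    frame_interval_s: float = 60.0
    total_time_s: float = 3600.0
    image_shape_px: tuple[int, int] = (1200, 1200)
    pixel_size_um: float = 2.0
    noise_sd: float = 0.02
    illumination_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        for name in ("droplet_radius_um", "capillary_thickness_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nucleation_rate_J < 0:
            raise ValueError("nucleation_rate_J must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.total_time_s < 0:
            raise ValueError("total_time_s must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def droplet_radius_px(self) -> float:
        return self.droplet_radius_um / self.pixel_size_um

    @property
    def droplet_volume_mm3(self) -> float:
        return droplet_volume_mm3(self.droplet_radius_um, self.capillary_thickness_um)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["image_shape_px"] = list(self.image_shape_px)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EmulsionConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "image_shape_px" in d:
            d["image_shape_px"] = tuple(d["image_shape_px"])
        return cls(**d)


@dataclass(frozen=True)
class DropletGroundTruth:
    """True geometry and nucleation time of one simulated droplet."""

    droplet_id: int
    center_px: tuple[float, float]  # (row, col)
    radius_px: float
    volume_mm3: float
    nucleation_time_s: float  # NEVER if no nucleation within the horizon

    def __post_init__(self) -> None:
        if self.volume_mm3 <= 0:
            raise ValueError("volume_mm3 must be positive")
        if self.nucleation_time_s < 0:
            raise ValueError("nucleation_time_s must be >= 0")


@dataclass
class FrameStack:
    """An ordered time-lapse of 2-D grayscale frames.

    Timestamps are seconds since the capillary-sealing epoch (t = 0) and
    must be strictly increasing, starting at 0.
    """

    frames: list[np.ndarray]
    timestamps_s: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if len(self.frames) != len(self.timestamps_s):
            raise ValueError("frames and timestamps must have equal length")
        if len(self.frames) == 0:
            raise ValueError("empty stack")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share one shape")
        if self.timestamps_s[0] != 0:
            raise ValueError("timestamps must start at 0 (sealing epoch)")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class BatchCondition:
    """Outcomes of one batch-crystallization condition.

    Each drop's outcome is one of ``clear``, ``crystal`` or
    ``precipitate``.
    """

    condition_name: str
    outcomes: list[str]

    OUTCOMES = ("clear", "crystal", "precipitate")

    def __post_init__(self) -> None:
        bad = set(self.outcomes) - set(self.OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcome labels: {sorted(bad)}")

    @property
    def n_total(self) -> int:
        return len(self.outcomes)

    def count(self, outcome: str) -> int:
        return self.outcomes.count(outcome)


# ---------------------------------------------------------------------------
# Stochastic nucleation


def sample_nucleation_times(
    J: float,
    volumes: np.ndarray | list[float],
    t_max: float = math.inf,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw per-droplet nucleation times under the Poisson model.

    For a droplet of volume V the probability of nucleating in dt is
    J·V·dt, so waiting times are exponential with rate J·V.  Times past
    ``t_max`` are replaced by the ``NEVER`` sentinel; J = 0 yields all
    ``NEVER``.

    Parameters
    ----------
    J : volumetric nucleation rate, mm⁻³ s⁻¹
    volumes : droplet volumes, mm³
    t_max : censoring horizon, s
    seed : integer seed or a Generator (consumed)
    """
    volumes = np.asarray(volumes, dtype=float)
    if J < 0:
        raise ValueError("J must be >= 0")
    if np.any(volumes <= 0):
        raise ValueError("all volumes must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if J == 0:
        return np.full(volumes.shape, NEVER)
    times = rng.exponential(1.0 / (J * volumes))
    times[times > t_max] = NEVER
    return times


# ---------------------------------------------------------------------------
# Rendering


def _crystal_radius_px(time_since_nucleation_s: float, droplet_radius_px: float) -> float:
    cap = CRYSTAL_MAX_RADIUS_FRACTION * droplet_radius_px
    r = CRYSTAL_MIN_RADIUS_PX + CRYSTAL_GROWTH_PX_PER_S * time_since_nucleation_s
    return min(r, cap) if cap > CRYSTAL_MIN_RADIUS_PX else min(r, CRYSTAL_MIN_RADIUS_PX)


def _crystal_offset(droplet: DropletGroundTruth, config_seed: int) -> tuple[float, float]:
    # Deterministic per-droplet placement of the crystal inside the droplet.
    rng = np.random.default_rng((config_seed, droplet.droplet_id, 7919))
    angle = rng.uniform(0, 2 * math.pi)
    rho = rng.uniform(0, 0.3) * droplet.radius_px
    return rho * math.sin(angle), rho * math.cos(angle)


def render_frame(
    population: list[DropletGroundTruth],
    t: float,
    config: EmulsionConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one cross-polarized-style frame at time ``t``.

    Droplets are faint rings on a dark background; droplets whose
    nucleation time is ≤ t contain a bright blob whose radius grows
    linearly with time since nucleation up to 40% of the droplet radius.
    Additive Gaussian noise (sd = ``config.noise_sd``) is applied and
    intensities are clipped to [0, 1].  When ``rng`` is None the noise is
    seeded deterministically from ``config.seed`` and ``t``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    nrow, ncol = config.image_shape_px
    img = np.full((nrow, ncol), BACKGROUND_LEVEL, dtype=np.float64)
    if config.illumination_gradient:
        ramp = np.linspace(0, config.illumination_gradient, ncol)
        img += ramp[None, :]

    for drop in population:
        r0, c0 = drop.center_px
        rad = drop.radius_px
        if not (rad <= r0 <= nrow - 1 - rad and rad <= c0 <= ncol - 1 - rad):
            raise ValueError(f"droplet {drop.droplet_id} out of image bounds")
        lo_r = int(max(0, math.floor(r0 - rad - 2)))
        hi_r = int(min(nrow, math.ceil(r0 + rad + 3)))
        lo_c = int(max(0, math.floor(c0 - rad - 2)))
        hi_c = int(min(ncol, math.ceil(c0 + rad + 3)))
        rows = np.arange(lo_r, hi_r)[:, None]
        cols = np.arange(lo_c, hi_c)[None, :]
        dist = np.hypot(rows - r0, cols - c0)
        ring = np.abs(dist - rad) <= RING_HALF_WIDTH_PX
        patch = img[lo_r:hi_r, lo_c:hi_c]
        patch[ring] = np.maximum(patch[ring], RING_LEVEL)

        if drop.nucleation_time_s <= t:
            blob_r = _crystal_radius_px(t - drop.nucleation_time_s, rad)
            dr, dc = _crystal_offset(drop, config.seed)
            bdist = np.hypot(rows - (r0 + dr), cols - (c0 + dc))
            blob = bdist <= blob_r
            patch[blob] = CRYSTAL_LEVEL

    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng((config.seed, 104729, int(round(t * 1000))))
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def _place_centers(config: EmulsionConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping droplet centers by seeded rejection sampling."""
    nrow, ncol = config.image_shape_px
    rad = config.droplet_radius_px
    margin = rad + 3.0
    if nrow - 2 * margin <= 0 or ncol - 2 * margin <= 0:
        raise CapacityError("image too small for droplet radius")
    min_sep = 2.0 * rad + 4.0
    centers: list[tuple[float, float]] = []
    max_tries = 2000 * config.n_droplets
    tries = 0
    while len(centers) < config.n_droplets:
        if tries >= max_tries:
            raise CapacityError(
                f"placed only {len(centers)}/{config.n_droplets} droplets "
                f"after {max_tries} tries; reduce density"
            )
        tries += 1
        r = rng.uniform(margin, nrow - 1 - margin)
        c = rng.uniform(margin, ncol - 1 - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep**2 for rr, cc in centers):
            centers.append((r, c))
    return np.array(centers)


def simulate_experiment(
    config: EmulsionConfig,
) -> tuple[FrameStack, list[DropletGroundTruth]]:
    """Simulate a full emulsion time-lapse experiment.

    Places droplets without overlap, samples their nucleation times, and
    renders frames at 0, Δt, 2Δt, …, ``total_time_s``.  Returns the frame
    stack together with the ground truth for downstream testing.
    Bit-identical for identical config (including seed).
    """
    ss = np.random.SeedSequence(config.seed)
    place_seed, time_seed, noise_seed = ss.spawn(3)
    centers = _place_centers(config, np.random.default_rng(place_seed))
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    centers = centers[order]

    volume = config.droplet_volume_mm3
    times = sample_nucleation_times(
        config.nucleation_rate_J,
        np.full(config.n_droplets, volume),
        t_max=math.inf,
        seed=np.random.default_rng(time_seed),
    )
    population = [
        DropletGroundTruth(
            droplet_id=i,
            center_px=(float(centers[i, 0]), float(centers[i, 1])),
            radius_px=config.droplet_radius_px,
            volume_mm3=volume,
            nucleation_time_s=float(times[i]),
        )
        for i in range(config.n_droplets)
    ]

    n_frames = int(math.floor(config.total_time_s / config.frame_interval_s)) + 1
    timestamps = np.arange(n_frames) * config.frame_interval_s
    noise_rng = np.random.default_rng(noise_seed)
    frames = [render_frame(population, float(t), config, rng=noise_rng) for t in timestamps]
    return FrameStack(frames=frames, timestamps_s=timestamps), population


# ---------------------------------------------------------------------------
# Batch outcomes


def simulate_batch(
    p_crystal: float,
    p_precipitate: float,
    n: int,
    seed: int = 0,
    condition_name: str = "condition",
) -> BatchCondition:
    """Draw n i.i.d. categorical drop outcomes (clear/crystal/precipitate)."""
    if not (0 <= p_crystal <= 1 and 0 <= p_precipitate <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_crystal + p_precipitate > 1 + 1e-12:
        raise ValueError("p_crystal + p_precipitate must be <= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p_clear = max(0.0, 1.0 - p_crystal - p_precipitate)
    draws = rng.choice(
        ["crystal", "precipitate", "clear"], size=n, p=[p_crystal, p_precipitate, p_clear]
    )
    return BatchCondition(condition_name=condition_name, outcomes=list(draws))


# ---------------------------------------------------------------------------
# Serialization


def write_frame_stack(stack: FrameStack, directory: str | Path) -> None:
    """Write frames as zero-padded 16-bit grayscale TIFFs + timestamps CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        u16 = np.clip(np.asarray(frame, dtype=np.float64), 0, 1)
        tifffile.imwrite(directory / f"frame_{i:05d}.tif", (u16 * 65535).astype(np.uint16))
    with open(directory / "timestamps.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "time_s"])
        for i, t in enumerate(stack.timestamps_s):
            w.writerow([i, repr(float(t))])


def read_frame_stack(directory: str | Path) -> FrameStack:
    """Read a stack written by :func:`write_frame_stack` (TIFF or PNG)."""
    import imageio.v3 as iio

    directory = Path(directory)
    ts_path = directory / "timestamps.csv"
    if not ts_path.exists():
        raise FileNotFoundError(f"missing timestamps CSV: {ts_path}")
    index, times = [], []
    with open(ts_path, newline="") as fh:
        for row in csv.DictReader(fh):
            index.append(int(row["frame_index"]))
            times.append(float(row["time_s"]))
    frames = []
    for i in index:
        for ext in ("tif", "tiff", "png"):
            path = directory / f"frame_{i:05d}.{ext}"
            if path.exists():
                break
        else:
            raise FileNotFoundError(f"missing frame {i} in {directory}")
        raw = iio.imread(path)
        if raw.dtype == np.uint16:
            frames.append((raw / 65535.0).astype(np.float32))
        elif raw.dtype == np.uint8:
            frames.append((raw / 255.0).astype(np.float32))
        else:
            frames.append(np.asarray(raw, dtype=np.float32))
    return FrameStack(frames=frames, timestamps_s=np.array(times))


def write_ground_truth(population: list[DropletGroundTruth], path: str | Path) -> None:
    """Ground-truth CSV; never-nucleated droplets get an empty time field."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["droplet_id", "center_row", "center_col", "radius_px", "volume_mm3", "nucleation_time_s"]
        )
        for d in population:
            t = "" if math.isinf(d.nucleation_time_s) else repr(d.nucleation_time_s)
            w.writerow([d.droplet_id, d.center_px[0], d.center_px[1], d.radius_px, d.volume_mm3, t])


def read_ground_truth(path: str | Path) -> list[DropletGroundTruth]:
    population = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            t = row["nucleation_time_s"]
            population.append(
                DropletGroundTruth(
                    droplet_id=int(row["droplet_id"]),
                    center_px=(float(row["center_row"]), float(row["center_col"])),
                    radius_px=float(row["radius_px"]),
                    volume_mm3=float(row["volume_mm3"]),
                    nucleation_time_s=NEVER if t == "" else float(t),
                )
            )
    return population


def write_batch_outcomes(conditions: list[BatchCondition], path: str | Path) -> None:
    """Outcome CSV with columns drop_id, condition, outcome."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["drop_id", "condition", "outcome"])
        for cond in conditions:
            for i, outcome in enumerate(cond.outcomes):
                w.writerow([i, cond.condition_name, outcome])


def read_batch_outcomes(path: str | Path) -> list[BatchCondition]:
    by_name: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            outcome = row["outcome"].strip().lower()
            if outcome not in BatchCondition.OUTCOMES:
                raise ValueError(f"{path}, line {lineno}: unknown outcome {row['outcome']!r}")
            name = row["condition"]
            if name not in by_name:
                by_name[name] = []
                order.append(name)
            by_name[name].append(outcome)
    return [BatchCondition(condition_name=n, outcomes=by_name[n]) for n in order]
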