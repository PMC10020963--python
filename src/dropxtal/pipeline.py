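"""End-to-end pipelines tying the stages together.

Two pipelines mirror the two experiment types: the emulsion-kinetics
pipeline (segment → classify/track → clear-fraction curve → J and
induction time) and the batch-statistics pipeline (outcome table →
probabilities → bootstrap comparisons vs control).  Every run writes a
provenance JSON (config, seed, package versions) alongside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dropxtal import __version__
from dropxtal import batch as batch_mod
from dropxtal import imaging, kinetics, synthetic

log = logging.getLogger("dropxtal")


@dataclass
class PipelineConfig:
    """Configuration shared by the pipelines; defaults match the
    published analysis constants (induction threshold 0.75, fit window
    0.1–0.75, one frame per minute input cadence, 10⁴ bootstrap
    resamples)."""

    input_path: str = "."
    output_dir: str = "results"
    min_radius_px: float = 15.0
    max_radius_px: float = 40.0
    threshold_area: float = 0.01
    threshold_max_intensity: float = 0.4
    induction_threshold: float = 0.75
    fit_window: tuple[float, float] = (0.1, 0.75)
    droplet_volume_mm3: float | None = None  # None → median volume from segmented radii
    pixel_size_um: float = 2.0
    capillary_thickness_um: float = 200.0
    control_condition: str = "control"
    n_bootstrap: int = 10_000
    seed: int = 0
    verbose: bool = False

    def classifier_thresholds(self) -> imaging.ClassifierThresholds:
        return imaging.ClassifierThresholds(
            area=self.threshold_area, max_intensity=self.threshold_max_intensity
        )


_DEFAULTS = PipelineConfig()


def _warn_overrides(config: PipelineConfig) -> None:
    for f in dataclasses.fields(config):
        if f.name in ("input_path", "output_dir", "seed", "verbose"):
            continue
        if getattr(config, f.name) != getattr(_DEFAULTS, f.name):
            log.warning("default overridden: %s = %r", f.name, getattr(config, f.name))


def write_provenance(config: PipelineConfig, out_dir: Path, stage: str) -> None:
    record = {
        "stage": stage,
        "dropxtal_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "config": {
            f.name: (list(v) if isinstance(v := getattr(config, f.name), tuple) else v)
            for f in dataclasses.fields(config)
        },
    }
    (out_dir / f"provenance_{stage}.json").write_text(json.dumps(record, indent=2) + "\n")


def run_emulsion_pipeline(config: PipelineConfig) -> kinetics.KineticsResult:
    """Full Fig.-3-style workflow on a frame stack directory.

    Reads the stack at ``config.input_path``, segments droplets from the
    first frame, tracks per-droplet crystal appearance, and fits the
    nucleation rate.  Writes state CSV, summary CSV, curve CSV, result
    JSON, a QC overlay of the final frame, and a provenance record.
    """
    _warn_overrides(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    in_path = Path(config.input_path)
    if not in_path.exists():
        raise FileNotFoundError(f"input stack not found: {in_path}")
    log.info("reading stack from %s", in_path)
    stack = synthetic.read_frame_stack(in_path)

    log.info("segmenting %d×%d first frame", *stack.frames[0].shape)
    rois = imaging.segment_droplets(
        stack.frames[0], config.min_radius_px, config.max_radius_px
    )
    if not rois:
        raise RuntimeError("segmentation found no droplets")
    log.info("found %d droplets", len(rois))

    series = imaging.track_states(stack, rois, config.classifier_thresholds())
    imaging.write_state_table(series, out / "states.csv")
    imaging.write_summary_table(series, out / "first_crystal_times.csv")
    imaging.write_overlay_png(
        stack.frames[-1], rois, [s.states[-1] for s in series], out / "overlay_final.png"
    )

    curve = kinetics.clear_fraction_curve(series)
    if config.droplet_volume_mm3 is not None:
        volume = config.droplet_volume_mm3
    else:
        median_radius_um = float(
            np.median([r.radius_px for r in rois]) * config.pixel_size_um
        )
        volume = synthetic.droplet_volume_mm3(median_radius_um, config.capillary_thickness_um)
        log.info("median droplet radius %.1f μm → volume %.3g mm³", median_radius_um, volume)
    result = kinetics.fit_nucleation_rate(curve, volume, window=config.fit_window)
    if config.induction_threshold != kinetics.DEFAULT_INDUCTION_THRESHOLD:
        result.induction_time_s = kinetics.induction_time(curve, config.induction_threshold)

    kinetics.write_curve_csv(curve, out / "clear_fraction.csv", window=config.fit_window)
    result.to_json(out / "kinetics.json")
    kinetics.plot_curve(curve, result, out / "clear_fraction.png")
    write_provenance(config, out, "emulsion")
    log.info(
        "J = %.3g ± %.2g mm⁻³ s⁻¹, induction time = %.1f s",
        result.J_estimate, result.J_stderr, result.induction_time_s,
    )
    return result


def run_batch_pipeline(config: PipelineConfig) -> list[batch_mod.ProbabilityComparison]:
    """Fig.-2-style workflow: probabilities + bootstrap CIs vs control."""
    _warn_overrides(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = Path(config.input_path)
    if not path.exists():
        raise FileNotFoundError(f"outcome table not found: {path}")
    conditions = synthetic.read_batch_outcomes(path)
    by_name = {c.condition_name: c for c in conditions}
    if config.control_condition not in by_name:
        raise ValueError(
            f"control condition {config.control_condition!r} not in table "
            f"(have: {sorted(by_name)})"
        )
    control = by_name[config.control_condition]
    comparisons = []
    for cond in conditions:
        if cond.condition_name == config.control_condition:
            continue
        comparisons.append(
            batch_mod.compare_to_control(
                cond, control, n_bootstrap=config.n_bootstrap, seed=config.seed
            )
        )
        log.info(
            "%s: Δp = %+.3f [%+.3f, %+.3f]",
            cond.condition_name,
            comparisons[-1].delta,
            comparisons[-1].ci_low,
            comparisons[-1].ci_high,
        )
    batch_mod.write_comparison_csv(comparisons, out / "batch_comparisons.csv")
    batch_mod.plot_comparisons(comparisons, out / "batch_comparisons.png")
    write_provenance(config, out, "batch")
    return comparisons
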