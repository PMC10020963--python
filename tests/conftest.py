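import numpy as np
import pytest

from dropxtal import EmulsionConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """50-droplet, 20-minute simulated emulsion (700×700 px, default noise)."""
    cfg = EmulsionConfig(
        n_droplets=50,
        image_shape_px=(700, 700),
        nucleation_rate_J=4.4,
        total_time_s=1200.0,
        seed=7,
    )
    stack, truth = simulate_experiment(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def nucleated_half_frame():
    """Single rendered frame where a known subset of droplets has crystals."""
    from dropxtal import render_frame, DropletGroundTruth, NEVER

    cfg = EmulsionConfig(
        n_droplets=50,
        image_shape_px=(700, 700),
        nucleation_rate_J=0.0,
        total_time_s=600.0,
        seed=11,
    )
    _, truth = simulate_experiment(cfg)
    # Re-assign: first 20 droplets nucleated 5 min before the snapshot.
    population = [
        DropletGroundTruth(
            droplet_id=d.droplet_id,
            center_px=d.center_px,
            radius_px=d.radius_px,
            volume_mm3=d.volume_mm3,
            nucleation_time_s=300.0 if d.droplet_id < 20 else NEVER,
        )
        for d in truth
    ]
    frame = render_frame(population, 600.0, cfg)
    return cfg, population, frame
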