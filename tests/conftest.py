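"""Shared fixtures: simulated runs reused across test modules.

The session-scoped runs are the study conditions exercised by the
population-level tests: the default motile population (200 cells,
61 frames, 512 x 512 px) and its immobile low-noise counterpart.
"""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from crrc.pipeline import PipelineConfig, run_pipeline
from crrc.simulate import SimulationConfig, SpeedDistribution, simulate_timelapse


@pytest.fixture(scope="session")
def default_motile_run():
    """Full pipeline on the default motile simulation (seed 1)."""
    cfg = PipelineConfig(simulation=SimulationConfig(rng_seed=1), seed=1)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def zero_motility_run():
    """Full pipeline on an immobile, low-noise population (seed 3).

    Read noise 1 a.u. (vs 600 a.u. cell amplitude) keeps per-cell k
    measurement error near 0.1%, so recovery checks probe bias, not noise.
    """
    sim = SimulationConfig(
        speed=SpeedDistribution(mode_um_h=0.0, iqr_um_h=0.0),
        noise_sd=1.0,
        rng_seed=3,
    )
    return run_pipeline(PipelineConfig(simulation=sim, seed=3))


@pytest.fixture(scope="session")
def small_motile_sim():
    """A small motile simulation for unit-level checks (30 cells, 21 frames)."""
    return simulate_timelapse(SimulationConfig(n_cells=30, field_size=(256, 256), n_frames=21, rng_seed=7))


@pytest.fixture(scope="session")
def small_noiseless_sim():
    """Noise-free motile simulation with zero background for closed-form checks."""
    cfg = SimulationConfig(
        n_cells=12,
        field_size=(192, 192),
        n_frames=16,
        noise_sd=0.0,
        background_level=0.0,
        intensity_offset=0.0,
        min_separation_um=12.0,  # isolate footprints for per-cell windowed sums
        rng_seed=11,
    )
    return simulate_timelapse(cfg)
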