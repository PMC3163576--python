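"""Shared fixtures: seeded phantoms and one full pipeline run.

The expensive objects (default phantom, end-to-end registration run) are
session-scoped and shared across test modules.
"""

import numpy as np
import pytest

from histomri.phantom import PhantomConfig, generate, generate_invivo, simulate_exvivo
from histomri.pipeline import PipelineConfig
from histomri.workflow import run_pipeline


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """The default-condition phantom at seed 1 (the standard test subject)."""
    return generate(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def exvivo_phantom():
    """A phantom with in vivo + ex vivo only (no sectioning), seed 2."""
    return simulate_exvivo(generate_invivo(PhantomConfig(seed=2)))


@pytest.fixture(scope="session")
def pipeline_run(default_phantom):
    """One full stacking -> stack2ex -> ex2in -> stack2in run with evaluation."""
    return run_pipeline(default_phantom, PipelineConfig())


def quick_phantom_config(seed=0, **overrides):
    """A reduced phantom for fast smoke tests (small grids, few sections)."""
    base = dict(
        seed=seed,
        shape=(40, 40, 40),
        tumor_center_mm=(4.0, 4.0, 4.0),
        tumor_radii_mm=(3.2, 2.2, 1.9),
        realigned_shape=(41, 41, 13),
        exvivo_shape=(41, 41, 15),
        n_sections=8,
        section_shape=(80, 80),
        landmark_count=6,
        landmark_min_separation_mm=0.8,
        landmark_depth_range_mm=(0.2, 0.62),
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def quick_phantom():
    return generate(quick_phantom_config(seed=5))
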