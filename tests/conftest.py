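"""Shared fixtures: phantoms and pipeline runs reused across test modules.

Session scope keeps the expensive full-pipeline runs (registration over
250 frames) to one execution each.
"""

from __future__ import annotations

import numpy as np
import pytest

from preful.phantom import PhantomSpec, defect_covering_fraction, generate_phantom
from preful.pipeline import run_pipeline

VENT_TRUTH_PCT = 100.0 * 0.95 * 0.10 / 0.90  # a=0.10 -> 10.556 %
LUNG_BASELINE = 55.0


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def default_run(default_phantom):
    series, truth = default_phantom
    return run_pipeline(series), truth


@pytest.fixture(scope="session")
def vent_defect_phantom():
    spec = PhantomSpec(
        seed=7,
        vent_defect_regions=(defect_covering_fraction(PhantomSpec(), 0.20),),
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def vent_defect_run(vent_defect_phantom):
    series, truth = vent_defect_phantom
    return run_pipeline(series), truth


@pytest.fixture(scope="session")
def perf_defect_phantom():
    spec = PhantomSpec(
        seed=7,
        perf_defect_regions=(defect_covering_fraction(PhantomSpec(), 0.20),),
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def perf_defect_run(perf_defect_phantom):
    series, truth = perf_defect_phantom
    return run_pipeline(series), truth


@pytest.fixture(scope="session")
def moving_phantom():
    return generate_phantom(PhantomSpec(seed=7, diaphragm_motion_px=3.0))


@pytest.fixture(scope="session")
def small_spec():
    """Fast phantom for tests that do not need the full acquisition."""
    return PhantomSpec(grid_shape=(64, 64), n_frames=120, seed=3)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)
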