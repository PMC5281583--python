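"""Shared fixtures: all data are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import strokeseg as ss


@pytest.fixture(scope="session")
def two_population_volume():
    """64x64x8 volume with two well-separated Gaussian intensity populations
    (object ellipsoid at 0.7, background at 0.3, sd 0.03)."""
    rng = np.random.default_rng(42)
    x, y, z = np.ogrid[:64, :64, :8]
    truth = ((x - 32) / 18.0) ** 2 + ((y - 30) / 14.0) ** 2 + ((z - 3.5) / 2.5) ** 2 <= 1
    values = np.where(truth, 0.7, 0.3) + 0.03 * rng.standard_normal((64, 64, 8))
    return ss.ScalarVolume(values), truth


def _run_case(seed: int, archetype: str = "corticostriatal", **kwargs):
    spec = ss.PhantomSpec(seed=seed, archetype=archetype, **kwargs)
    data, echoes = ss.phantom_with_echoes(spec)
    bundle, report = ss.run_pipeline(data.t2, echoes, data.template_atlas)
    truth_lesion = data.truth_lesion[bundle.crop_report.slices()]
    return {
        "spec": spec,
        "data": data,
        "echoes": echoes,
        "bundle": bundle,
        "report": report,
        "truth_lesion": truth_lesion,
    }


@pytest.fixture(scope="session")
def run_phantom_case():
    """Factory running the full pipeline on one phantom, with memoization."""
    cache: dict = {}

    def run(seed: int, archetype: str = "corticostriatal", **kwargs):
        key = (seed, archetype, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = _run_case(seed, archetype, **kwargs)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def phantom_suite(run_phantom_case):
    """The 10-phantom corticostriatal suite (seeds 1..10, defaults)."""
    return [run_phantom_case(seed) for seed in range(1, 11)]
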