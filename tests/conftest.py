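import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from mpsl4d import BinaryMask, PhaseVolume, generate_phantom
from mpsl4d.phantom_synth import suite_case

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


def random_mask(rng, shape, p=0.4, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(rng.random(shape) < p, spacing)


@pytest.fixture(scope="session")
def baseline_case():
    """Baseline moving-sphere phantom (noise seed 1) with its config."""
    case = suite_case("baseline", rng_seed=1)
    series, truth, ttraj = generate_phantom(case.spec)
    return case, series, truth, ttraj


@pytest.fixture(scope="session")
def noise_free_case():
    """Baseline geometry with the noise turned off (for exactness checks)."""
    case = suite_case("baseline", rng_seed=0)
    spec = dataclasses.replace(case.spec, noise_sd=0.0)
    series, truth, ttraj = generate_phantom(spec)
    return dataclasses.replace(case, spec=spec), series, truth, ttraj


def two_sphere_volume(mover_dz_mm: float, phase_label: int) -> PhaseVolume:
    """Lung-background volume holding two equal 2-cm spheres: one static
    at (35, 35, 50) mm, one at (85, 85, 50 + mover_dz) mm."""
    dims, spacing = (60, 60, 40), (2.0, 2.0, 2.5)
    axes = np.ix_(*[np.arange(n) * s for n, s in zip(dims, spacing)])
    X, Y, Z = axes
    vol = np.full(dims, -800.0, dtype=np.float32)
    for cx, cy, cz in [(35.0, 35.0, 50.0), (85.0, 85.0, 50.0 + mover_dz_mm)]:
        sph = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= 10.0 ** 2
        vol[sph] = 0.0
    return PhaseVolume(vol, spacing, phase_label=phase_label)
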