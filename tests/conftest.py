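import dataclasses

import numpy as np
import pytest

from ktblast import PhantomSpec, generate_phantom, corrupt_kspace


@pytest.fixture(scope="session")
def small_spec():
    """Down-sized phantom: 48^2 matrix, 2 slices, 12 frames, noise-free."""
    return PhantomSpec(matrix_size=48, fov_mm=30.0, n_slices=2, n_frames=12,
                       noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def static_spec(small_spec):
    """Temporally constant variant (ES radii equal to ED radii)."""
    return dataclasses.replace(
        small_spec,
        endo_radius_es_mm=small_spec.endo_radius_ed_mm,
        epi_radius_es_mm=small_spec.epi_radius_ed_mm,
    )


@pytest.fixture(scope="session")
def small_kt(small_phantom):
    stack, _ = small_phantom
    return corrupt_kspace(stack, 0.0, 0)


@pytest.fixture(scope="session")
def noisy_kt(small_phantom):
    stack, _ = small_phantom
    return corrupt_kspace(stack, 0.05, 11)
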