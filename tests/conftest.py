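"""Shared fixtures: sphere and ear-head models with assembled BEM systems.

The expensive artefacts (BEM factorizations, lead fields, the carved
ear head) are session-scoped and shared across test modules so the
whole suite stays within a desk-scale runtime.
"""

import numpy as np
import pytest

from earshell.bem_forward import assemble, build_source_grid, compute_leadfield
from earshell.synthetic_head import (
    EarSpec,
    SphereSpec,
    _fibonacci_sphere,
    make_ear_head,
    make_sphere_head,
)

#: mesh sizes used throughout the suite (documented in docs/methods.md):
#: a small sphere for self-consistency checks, a finer one for the
#: analytic-accuracy checks, and a medium ear head for the carving and
#: sensitivity checks
SMALL_FACES = 1280
ACCURACY_FACES = 2500
EAR_FACES = 1500


@pytest.fixture(scope="session")
def sphere_spec_small():
    return SphereSpec(faces_per_shell=SMALL_FACES)


@pytest.fixture(scope="session")
def sphere_model_small(sphere_spec_small):
    return make_sphere_head(sphere_spec_small)


@pytest.fixture(scope="session")
def bem_small(sphere_model_small):
    return assemble(sphere_model_small)


@pytest.fixture(scope="session")
def sphere_spec_accurate():
    return SphereSpec(faces_per_shell=ACCURACY_FACES)


@pytest.fixture(scope="session")
def bem_accurate(sphere_spec_accurate):
    return assemble(make_sphere_head(sphere_spec_accurate))


@pytest.fixture(scope="session")
def scalp_electrodes_64():
    pos = _fibonacci_sphere(64) * 92.0
    labels = [f"E{i:02d}" for i in range(64)]
    return labels, pos


@pytest.fixture(scope="session")
def sphere_grid4(sphere_model_small):
    return build_source_grid(sphere_model_small.brain, spacing=4.0)


@pytest.fixture(scope="session")
def sphere_lfm(bem_small, sphere_grid4, scalp_electrodes_64):
    labels, pos = scalp_electrodes_64
    return compute_leadfield(bem_small, sphere_grid4, labels, pos)


@pytest.fixture(scope="session")
def ear_head():
    """Default-condition synthetic ear head: (model, electrode layout)."""
    return make_ear_head(
        SphereSpec(faces_per_shell=EAR_FACES), EarSpec(), seed=0
    )


@pytest.fixture(scope="session")
def ear_lfm(ear_head):
    model, layout = ear_head
    system = assemble(model)
    grid = build_source_grid(model.brain, spacing=4.0)
    elec = layout.all
    return compute_leadfield(system, grid, elec.labels, elec.points)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
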