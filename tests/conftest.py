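"""Shared fixtures: analytic phantoms solved once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cortrad as ct

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def slab():
    """Noiseless zero-dispersion flat slab with solved radial geometry."""
    spec = ct.PhantomSpec(
        grid_shape=(24, 24, 24), cortex_thickness=10.0,
        dispersion_kappa=np.inf, seed=1,
    )
    truth, tensors = ct.make_phantom(spec)
    potential = ct.solve_cortical_potential(truth.labels)
    field = ct.radial_field(potential, truth.labels)
    profiles = ct.trace_profiles(field, potential, truth.labels, step=0.25)
    return {
        "spec": spec,
        "truth": truth,
        "tensors": tensors,
        "potential": potential,
        "field": field,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def annulus():
    """Spherical annulus (a=20 mm, b=40 mm, 1 mm grid) with solved geometry."""
    spec = ct.PhantomSpec(
        geometry="spherical_annulus", grid_shape=(84, 84, 84),
        cortex_thickness=20.0, dispersion_kappa=np.inf, seed=1,
    )
    truth, _ = ct.make_phantom(spec)
    potential = ct.solve_cortical_potential(truth.labels)
    field = ct.radial_field(potential, truth.labels)
    arr = truth.labels.labels
    center = (np.asarray(arr.shape) - 1) / 2.0
    coords = np.indices(arr.shape).transpose(1, 2, 3, 0).astype(float)
    radius = np.linalg.norm(coords - center, axis=-1)
    return {
        "spec": spec,
        "truth": truth,
        "potential": potential,
        "field": field,
        "a": 20.0,
        "b": 40.0,
        "radius": radius,
        "center": center,
    }


@pytest.fixture(scope="session")
def uniform_axes_result():
    """Slab phantom with uniformly random principal axes (kappa = 0)."""
    spec = ct.PhantomSpec(
        grid_shape=(48, 48, 48), cortex_thickness=20.0,
        dispersion_kappa=0.0, seed=4,
    )
    truth, result = ct.process_phantom(spec, through_dwi=False)
    return truth, result


@pytest.fixture(scope="session")
def zero_dispersion_dwi_result():
    """Zero-dispersion noiseless slab processed through DWI synthesis + refit."""
    spec = ct.PhantomSpec(
        grid_shape=(32, 32, 32), cortex_thickness=12.0,
        dispersion_kappa=np.inf, seed=3,
    )
    truth, result = ct.process_phantom(spec, through_dwi=True)
    return truth, result
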