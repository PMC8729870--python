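"""Shared fixtures: all phantom data is generated programmatically at test
time; session scope keeps the expensive simulations to one run each."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from petmoco import phantom as ph
from petmoco.core import make_schedule
from petmoco.kinetics import KineticParams


@pytest.fixture(scope="session")
def schedule37():
    """The 37-frame, 60-min dynamic protocol."""
    return make_schedule(ph.DEFAULT_FRAME_PATTERN)


@pytest.fixture(scope="session")
def small_spec():
    """Quarter-scale phantom (32x32x24 at 3 mm) for fast unit tests."""
    # margins sized so the interframe protocol (up to 2 voxels = 6 mm) never
    # pushes the brain outside the field of view
    return ph.PhantomSpec(
        grid_shape=(32, 32, 24),
        brain_semi_axes_mm=(30.0, 36.0, 18.0),
        brain_centre_offset_mm=(0.0, 0.0, 4.0),
        vessel_separation_mm=20.0,
        vessel_z_extent_mm=(6.0, 15.0),
        ventricle_semi_axes_mm=((6.0, 10.0, 5.0), (4.0, 8.0, 4.0)),
        ventricle_centres_mm=((-8.0, 5.0, 4.0), (8.0, 2.0, 5.0)),
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec, schedule37):
    """One noise-free + noisy quarter-scale subject with ground truth."""
    return ph.make_dataset(small_spec, schedule37, seed=11)


@pytest.fixture(scope="session")
def desk_spec():
    """The default desk-scale phantom (64x64x48 at 3 mm)."""
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def desk_dataset(desk_spec, schedule37):
    return ph.make_dataset(desk_spec, schedule37, seed=7)


@pytest.fixture(scope="session")
def vessel_only_spec():
    """Blood-pool-only phantom with no PSF: vessel voxels carry the
    whole-blood curve exactly."""
    return ph.PhantomSpec(
        grid_shape=(32, 32, 24),
        brain_semi_axes_mm=(30.0, 36.0, 18.0),
        brain_centre_offset_mm=(0.0, 0.0, 4.0),
        vessel_separation_mm=20.0,
        vessel_z_extent_mm=(6.0, 15.0),
        psf_fwhm=0.0,
        kinetics={
            "gm": KineticParams(0.0, 0.0, 0.0, 0.0),
            "wm": KineticParams(0.0, 0.0, 0.0, 0.0),
            "ventricle": KineticParams(0.0, 0.0, 0.0, 0.0),
            "vessel": KineticParams(K1=0.0, k2=0.0, k3=0.0, Vb=1.0),
        },
    )
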