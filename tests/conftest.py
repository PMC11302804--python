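"""Shared fixtures: a small phantom so unit tests stay fast."""

import numpy as np
import pytest

from dermadose import synthetic as syn
from dermadose.structures import contact_surface, threshold_structure


def small_spec_kwargs():
    return dict(
        breast_radius=2.0,
        breast_length=6.0,
        contact_area_target=24.0,   # 4 cm arc x 6 cm axial band
        lateral_extent=2.5,
        inferior_extent=3.5,
        ct_spacing=(0.2, 0.2, 0.3),
        dose_grid_spacing=0.2,
        margin=0.5,
        body_overhang=0.9,
    )


@pytest.fixture(scope="session")
def small_spec():
    return syn.PhantomSpec(**small_spec_kwargs())


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """CT + ground-truth masks + thresholded structures + contact contour."""
    ct, gt = syn.generate_phantom_ct(small_spec)
    body = threshold_structure(ct, -300, 3071, keep_largest=True, label="body")
    cradle = threshold_structure(ct, -800, -600, label="cradle")
    contact = contact_surface(body, cradle)
    return {"ct": ct, "gt": gt, "body": body, "cradle": cradle,
            "contact": contact}


@pytest.fixture(scope="session")
def small_geometry(small_spec):
    return syn.compute_dose_geometry(small_spec)


@pytest.fixture(scope="session")
def small_doses(small_spec, small_geometry):
    return {
        name: syn.generate_dose_grid(small_spec, prof, small_geometry)
        for name, prof in syn.default_profiles().items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
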