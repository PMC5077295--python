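"""Shared synthetic fixtures.  Everything is generated at test time from
seeded generators; session scope keeps the rendering cost paid once."""

import numpy as np
import pytest

import ringcurv as rc

NOISE = dict(read_noise_sd=0.02, photon_scale=2000.0, camera_offset=0.1)


@pytest.fixture(scope="session")
def circle_stack():
    """Noiseless circle, radius 1.5 µm, no bundles."""
    geom = rc.circle(1.5)
    stack, truth = rc.generate_ring_stack(geom)
    return geom, stack, truth


@pytest.fixture(scope="session")
def circle_skeleton(circle_stack):
    _, stack, _ = circle_stack
    skel, proj = rc.segment_ring(stack)
    return skel, proj


@pytest.fixture(scope="session")
def stadium_stack():
    """Noiseless compressed ring, d = 2 µm, h = 2 µm."""
    geom = rc.stadium(2.0, 2.0)
    stack, truth = rc.generate_ring_stack(geom)
    return geom, stack, truth


@pytest.fixture(scope="session")
def stadium_skeleton(stadium_stack):
    _, stack, _ = stadium_stack
    skel, proj = rc.segment_ring(stack)
    return skel, proj


@pytest.fixture(scope="session")
def stadium_profile(stadium_skeleton):
    """Curvature profile with a feature-resolving offset (see methods)."""
    skel, _ = stadium_skeleton
    return rc.local_curvature_profile(skel, arc_offset=0.6, smooth_window=5)


@pytest.fixture(scope="session")
def bundled_stadium():
    """Stadium with four planted 3.9 µm bundles, noiseless."""
    geom = rc.stadium(2.5, 2.5)
    rng = np.random.default_rng(7)
    specs = rc.simulate.plant_bundles(geom, 4, 3.9, curved_origin_prob=1.0,
                                      rng=rng)
    stack, truth = rc.generate_ring_stack(geom, specs)
    return geom, specs, stack, truth


@pytest.fixture(scope="session")
def noiseless_timelapse():
    """Contracting circle time-lapse with programmed bundle expulsion."""
    geom = rc.circle(5.5 / 2)
    stack, truth = rc.generate_timelapse(
        geom, contraction_rate=1.26, bundle_onset_diameter=2.0,
        n_frames=12, dt=1.0, expelled_fraction=0.68,
        bundle_elongation_rate=2.19)
    return stack, truth
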