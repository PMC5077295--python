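"""Three-point circle curvature, profiles, region classification,
compression factor."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ringcurv as rc
from ringcurv.curvature import _circular_moving_average, _runs_circular
from ringcurv.errors import (DegenerateTripleError, NotCompressedRingError,
                             OffsetTooLargeError)


class TestThreePointCircle:
    @pytest.mark.parametrize("p1,p2,p3,expected", [
        ((1, 0), (0, 1), (-1, 0), 1.0),          # unit circle
        ((0, 0), (1, 0), (2, 0), 0.0),           # collinear
        ((0, 0), (1, 1), (2, 0), 1.0),           # R = abc/4K = 1
    ])
    def test_known_triples(self, p1, p2, p3, expected):
        assert rc.circle_through_three_points(p1, p2, p3) == pytest.approx(
            expected, abs=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateTripleError):
            rc.circle_through_three_points((1, 1), (1, 1), (2, 0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0),
           st.lists(st.floats(0.0, 2 * math.pi), min_size=3, max_size=3,
                    unique=True))
    def test_exact_on_circle_samples(self, radius, angles):
        pts = [(radius * math.cos(a), radius * math.sin(a)) for a in angles]
        # degenerate triples (nearly coincident) are excluded by uniqueness
        if min(np.linalg.norm(np.subtract(a, b))
               for a, b in [(pts[0], pts[1]), (pts[1], pts[2]),
                            (pts[0], pts[2])]) < 1e-6 * radius:
            return
        kappa = rc.circle_through_three_points(*pts)
        assert kappa == pytest.approx(1.0 / radius, rel=1e-9)


class TestSmoothing:
    def test_conserves_mean(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2, 97)
        for w in (2, 5, 10):
            sm = _circular_moving_average(x, w)
            assert sm.mean() == pytest.approx(x.mean(), abs=1e-12)

    def test_window_one_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(_circular_moving_average(x, 1), x)


class TestProfileOnAnalyticCycle:
    """Exactness on polygonal cycles sampled straight from the geometry
    (no rasterization)."""

    def _skel(self, geom, n=600):
        s = np.linspace(0, geom.perimeter, n, endpoint=False)
        return rc.RingSkeleton(cycle=geom.point_at_arc(s))

    def test_circle_exact(self):
        g = rc.circle(1.0)
        prof = rc.local_curvature_profile(self._skel(g), arc_offset=1.0)
        assert np.allclose(prof.kappa, 1.0, rtol=2e-3)

    def test_scale_covariance(self):
        g1, g2 = rc.circle(1.0), rc.circle(3.0)
        p1 = rc.local_curvature_profile(self._skel(g1), arc_offset=0.8)
        p2 = rc.local_curvature_profile(self._skel(g2), arc_offset=2.4,
                                        resample_step=0.6)
        # scaling coordinates by 3 scales kappa by 1/3
        assert p2.mean_kappa == pytest.approx(p1.mean_kappa / 3.0, rel=1e-2)

    def test_offset_exceeding_half_perimeter_rejected(self):
        g = rc.circle(0.5)
        with pytest.raises(OffsetTooLargeError):
            rc.local_curvature_profile(self._skel(g), arc_offset=2.0)


class TestPipelineRecovery:
    def test_circle_mean_curvature_within_10pct(self, circle_skeleton):
        skel, _ = circle_skeleton
        prof = rc.adaptive_curvature_profile(skel)
        assert prof.mean_kappa == pytest.approx(1 / 1.5, rel=0.10)

    def test_curvature_to_diameter_consistency(self, circle_skeleton):
        # kappa 1.1 µm⁻¹ corresponds to a ~2 µm ring diameter (2/kappa)
        skel, _ = circle_skeleton
        prof = rc.adaptive_curvature_profile(skel)
        implied_diameter = 2.0 / prof.mean_kappa
        assert implied_diameter == pytest.approx(2 * 1.5, rel=0.10)


class TestClassification:
    def test_circle_all_flat(self, circle_skeleton):
        skel, _ = circle_skeleton
        prof = rc.adaptive_curvature_profile(skel)
        curved = rc.classify_regions(prof)
        # near-uniform curvature: no large curved fraction
        assert curved.mean() < 0.6  # noise splits around the mean

    def test_stadium_caps_curved_flats_flat(self, stadium_stack,
                                            stadium_profile):
        geom, _, _ = stadium_stack
        prof = stadium_profile
        curved = rc.classify_regions(prof)
        c = prof.points.mean(axis=0)
        p = prof.points - c
        on_cap_true = np.abs(p[:, 0]) > geom.flat_length_d / 2 + 0.35
        on_flat_true = np.abs(p[:, 0]) < geom.flat_length_d / 2 - 0.35
        assert curved[on_cap_true].mean() > 0.9
        assert (~curved[on_flat_true]).mean() > 0.9

    def test_stadium_cap_and_flat_kappa(self, stadium_stack, stadium_profile):
        geom, _, _ = stadium_stack
        prof = stadium_profile
        c = prof.points.mean(axis=0)
        p = prof.points - c
        on_cap = np.abs(p[:, 0]) > geom.flat_length_d / 2 + 0.35
        on_flat = np.abs(p[:, 0]) < geom.flat_length_d / 2 - 0.35
        assert prof.kappa[on_cap].mean() == pytest.approx(
            2.0 / geom.height_h, rel=0.15)
        assert prof.kappa[on_flat].mean() < 0.2

    def test_runs_decomposition(self):
        labels = np.array([0, 0, 1, 1, 1, 0, 0, 1], dtype=bool)
        runs = _runs_circular(labels)
        assert sum(r[1] for r in runs) == len(labels)
        # circular: the leading and trailing False runs are NOT merged in the
        # list, but each run is homogeneous
        for start, length, val in runs:
            idx = (np.arange(start, start + length)) % len(labels)
            assert (labels[idx] == val).all()


class TestCompressionFactor:
    def test_circle_factor_one(self, circle_skeleton):
        skel, _ = circle_skeleton
        factor, d, h = rc.compression_factor(skel)
        assert factor == pytest.approx(1.0, abs=0.05)
        assert d == 0.0

    def test_stadium_closed_form(self, stadium_skeleton, stadium_profile):
        skel, _ = stadium_skeleton
        factor, d, h = rc.compression_factor(skel, stadium_profile)
        # truth: h=2, perimeter 4+2π, factor = h/(P/π) ≈ 0.611
        expected = 2.0 / ((4 + 2 * math.pi) / math.pi)
        assert expected == pytest.approx(0.611, abs=0.001)
        assert factor == pytest.approx(expected, rel=0.05)
        assert h == pytest.approx(2.0, rel=0.05)
        assert d == pytest.approx(2.0, rel=0.25)  # flats blur at the caps

    def test_monotone_in_flattening(self):
        # more flattening (larger d at fixed h) → smaller factor
        factors = []
        for d in (0.0, 1.0, 2.0, 3.0):
            g = rc.stadium(d, 2.0)
            factors.append(2.0 / (g.perimeter / math.pi))
        assert all(a > b for a, b in zip(factors, factors[1:]))
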