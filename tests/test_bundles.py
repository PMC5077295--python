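"""Bundle detection, summaries, curved-origin classification, onset."""

import numpy as np
import pytest

import ringcurv as rc
from ringcurv.bundles import BundleRecord
from ringcurv.errors import NoBundlesError, NoExpulsionError


@pytest.fixture(scope="module")
def stadium_with_bundles(bundled_stadium):
    _, specs, stack, _ = bundled_stadium
    skel, proj = rc.segment_ring(stack)
    prof = rc.local_curvature_profile(skel, arc_offset=0.6, smooth_window=5)
    return specs, skel, prof


class TestDetect:
    def test_planted_bundle_count_and_length(self, stadium_with_bundles):
        specs, skel, prof = stadium_with_bundles
        recs = rc.detect_bundles(skel, min_len=0.5, profile=prof)
        assert len(recs) == len(specs) == 4
        for r in recs:
            assert r.length == pytest.approx(3.9, abs=0.2)
            assert r.origin_kappa >= 0

    def test_ring_without_branches_empty(self, circle_skeleton):
        skel, _ = circle_skeleton
        assert rc.detect_bundles(skel, min_len=0.5) == []

    def test_min_len_excludes_short_branches(self):
        cyc = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        short = np.array([[0, 0], [-0.1, -0.1], [-0.2, -0.2]])
        skel = rc.RingSkeleton(cycle=cyc, branches=[(short, 0)])
        assert rc.detect_bundles(skel, min_len=0.5) == []
        assert len(rc.detect_bundles(skel, min_len=0.1)) == 1


class TestSummaries:
    def test_arithmetic(self):
        recs = [BundleRecord(id=0, path=np.zeros((2, 2)), length=3.0,
                             origin_arc=0.0),
                BundleRecord(id=1, path=np.zeros((2, 2)), length=5.0,
                             origin_arc=1.0)]
        s = rc.summarize_bundles(recs, perimeter=8.0)
        assert (s.count, s.mean_length, s.total_length,
                s.total_plus_perimeter) == (2, 4.0, 8.0, 16.0)
        assert s.size_class == "small"

    def test_zero_bundles(self):
        s = rc.summarize_bundles([], perimeter=15.0)
        assert s.count == 0 and s.mean_length == 0.0
        assert s.total_plus_perimeter == 15.0
        assert s.size_class == "large"

    def test_small_large_grouping_threshold(self):
        assert rc.summarize_bundles([], 10.99).size_class == "small"
        assert rc.summarize_bundles([], 11.0).size_class == "large"

    def test_permutation_invariance(self):
        recs = [BundleRecord(id=i, path=np.zeros((2, 2)), length=l,
                             origin_arc=0.0)
                for i, l in enumerate([1.0, 2.5, 4.0])]
        a = rc.summarize_bundles(recs, 9.0)
        b = rc.summarize_bundles(recs[::-1], 9.0)
        assert (a.total_length, a.mean_length) == (b.total_length,
                                                   b.mean_length)


class TestCurvedFraction:
    def test_all_on_caps(self, stadium_with_bundles):
        specs, skel, prof = stadium_with_bundles
        recs = rc.detect_bundles(skel, min_len=0.5, profile=prof)
        assert rc.fraction_from_curved(recs, prof) == 1.0

    def test_no_records_rejected(self, stadium_with_bundles):
        _, _, prof = stadium_with_bundles
        with pytest.raises(NoBundlesError):
            rc.fraction_from_curved([], prof)

    def test_rigid_motion_invariance(self, bundled_stadium):
        _, specs, stack, _ = bundled_stadium
        skel, _ = rc.segment_ring(stack)
        prof = rc.local_curvature_profile(skel, arc_offset=0.6,
                                          smooth_window=5)
        recs = rc.detect_bundles(skel, min_len=0.5, profile=prof)
        f0 = rc.fraction_from_curved(recs, prof)
        # rotate and translate all coordinates rigidly
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        skel2 = rc.RingSkeleton(cycle=skel.cycle @ R.T + 3.0,
                                branches=[(p @ R.T + 3.0, a)
                                          for p, a in skel.branches],
                                pixel_size=skel.pixel_size)
        prof2 = rc.local_curvature_profile(skel2, arc_offset=0.6,
                                           smooth_window=5)
        recs2 = rc.detect_bundles(skel2, min_len=0.5, profile=prof2)
        assert rc.fraction_from_curved(recs2, prof2) == pytest.approx(f0)

    def test_ground_truth_agreement(self):
        """Planted curved/flat origins recovered at ≥ 90% agreement."""
        agree = total = 0
        for seed in range(4):
            rng = np.random.default_rng(20 + seed)
            geom = rc.stadium(2.5, 2.5)
            specs = rc.simulate.plant_bundles(geom, 5, 3.0,
                                              curved_origin_prob=0.5, rng=rng)
            stack, _ = rc.generate_ring_stack(geom, specs)
            skel, _ = rc.segment_ring(stack)
            prof = rc.local_curvature_profile(skel, arc_offset=0.6,
                                              smooth_window=5)
            recs = rc.detect_bundles(skel, min_len=0.5, profile=prof)
            if len(recs) != len(specs):
                continue
            # match records to specs by attachment position
            for r in recs:
                att = r.path[0]
                truth_pts = np.array([geom.point_at_arc(s.origin_arc)
                                      for s in specs])
                truth_pts += skel.cycle.mean(axis=0) - truth_pts.mean(axis=0)
                j = int(np.argmin(np.linalg.norm(truth_pts - att, axis=1)))
                total += 1
                want = "curved" if specs[j].on_curved_region else "flat"
                agree += (r.origin_label == want)
        assert total >= 10
        assert agree / total >= 0.9


class TestOnset:
    def _frames(self, n_bundle_frames):
        frames = []
        for i in range(5):
            g = rc.circle(2.0 - 0.2 * i)
            s = np.linspace(0, g.perimeter, 200, endpoint=False)
            skel = rc.RingSkeleton(cycle=g.point_at_arc(s))
            prof = rc.adaptive_curvature_profile(skel)
            recs = []
            if i >= 5 - n_bundle_frames:
                recs = [BundleRecord(id=0, path=np.zeros((2, 2)), length=1.0,
                                     origin_arc=0.0, origin_kappa=0.9)]
            frames.append({"skeleton": skel, "profile": prof,
                           "bundles": recs})
        return frames

    def test_onset_frame_and_time(self):
        rep = rc.expulsion_onset(self._frames(2), dt=0.5)
        assert rep.onset_frame == 3
        assert rep.onset_time == pytest.approx(1.5)
        # circle radius 1.4 at frame 3
        assert rep.onset_diameter == pytest.approx(2.8, rel=1e-3)
        assert rep.onset_mean_kappa == pytest.approx(1 / 1.4, rel=1e-2)
        assert rep.origin_kappas == pytest.approx([0.9])

    def test_no_expulsion_rejected(self):
        with pytest.raises(NoExpulsionError):
            rc.expulsion_onset(self._frames(0))

    def test_onset_mean_curvature_matches_diameter(self):
        rep = rc.expulsion_onset(self._frames(1), dt=1.0)
        assert rep.onset_mean_kappa == pytest.approx(
            2.0 / rep.onset_diameter, rel=1e-2)
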