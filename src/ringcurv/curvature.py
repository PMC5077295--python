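"""Local curvature along a ring skeleton by three-point circle fitting.

For every point of interest (POI) on the resampled ring cycle, two
neighbours are taken at a fixed arc offset (default 2.0 µm) on either side
along the skeleton.  The unique circle through the three points has radius
R; the local curvature is κ = 1/R (µm⁻¹, unsigned).  κ is then smoothed
with a centred circular moving average (default 10 resampled points, i.e.
2 µm at the default 0.2 µm resampling step).  For a perfect circle the
estimator is exact for any offset; for a compressed "stadium" ring the
caps report κ ≈ 2/h and the flats κ ≈ 0.

Regions are classified curved/flat against the mean ring curvature, and the
degree of mechanical compression is summarised by the compression factor
h / (perimeter/π), which is 1 for a circle and decreases with flattening.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (DegenerateTripleError, NotCompressedRingError,
                     OffsetTooLargeError)
from .segmentation import RingSkeleton

log = logging.getLogger(__name__)

__all__ = [
    "CurvatureProfile", "circle_through_three_points",
    "local_curvature_profile", "adaptive_curvature_profile",
    "classify_regions", "compression_factor",
]


@dataclass
class CurvatureProfile:
    """Per-point local curvature of a closed ring cycle."""

    arc_position: np.ndarray   # µm, uniform resampling of the cycle
    kappa: np.ndarray          # µm⁻¹, smoothed, unsigned
    kappa_raw: np.ndarray      # µm⁻¹, before smoothing
    points: np.ndarray         # (N, 2) resampled cycle points, µm
    arc_offset: float          # µm, neighbour distance each side
    smooth_window: int         # points
    resample_step: float       # µm

    @property
    def mean_kappa(self) -> float:
        """Arithmetic mean curvature over the closed cycle (µm⁻¹)."""
        return float(np.mean(self.kappa))

    @property
    def perimeter(self) -> float:
        return float(self.arc_position[-1] + self.resample_step)

    def kappa_at_arc(self, s) -> np.ndarray:
        """Curvature at arbitrary arc position(s) (nearest resampled point)."""
        s = np.mod(np.asarray(s, dtype=float), self.perimeter)
        idx = np.rint(s / self.resample_step).astype(int) % len(self.kappa)
        return self.kappa[idx]


def circle_through_three_points(p1, p2, p3) -> float:
    """Curvature (1/R, µm⁻¹) of the circle through three distinct 2D points.

    Uses κ = 4·|area| / (|p1p2|·|p2p3|·|p1p3|), which is exact and returns
    0 for collinear points (infinite radius).  Coincident points raise
    :class:`DegenerateTripleError`.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    if a == 0.0 or b == 0.0 or c == 0.0:
        raise DegenerateTripleError("coincident points in three-point circle fit")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    return float(4.0 * abs(0.5 * cross) / (a * b * c))


def _circular_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average on a circular signal; conserves the mean."""
    if window <= 1:
        return x.copy()
    from scipy.ndimage import uniform_filter1d
    return uniform_filter1d(x, size=min(window, len(x)), mode="wrap")


def local_curvature_profile(skel: RingSkeleton, arc_offset: float = 2.0,
                            smooth_window: int = 10,
                            resample_step: float = 0.2) -> CurvatureProfile:
    """Local curvature at every resampled cycle point.

    The cycle is resampled to a uniform ``resample_step``; the two
    neighbours of each POI sit ``arc_offset`` µm away along the cycle in
    either direction (wrapping around), and κ comes from the circumscribed
    circle of the triple.  κ is then smoothed over ``smooth_window``
    consecutive points with a circular moving average.

    Raises :class:`OffsetTooLargeError` when ``arc_offset`` reaches half
    the cycle perimeter (the neighbours would collide).
    """
    pts = skel.resample(resample_step)
    n = len(pts)
    perimeter = n * resample_step
    if 2 * arc_offset >= perimeter:
        raise OffsetTooLargeError(
            f"arc offset {arc_offset} µm exceeds half the perimeter "
            f"{perimeter / 2:.3f} µm")
    k = max(int(round(arc_offset / resample_step)), 1)
    prev_pts = np.roll(pts, k, axis=0)
    next_pts = np.roll(pts, -k, axis=0)
    kappa_raw = np.empty(n)
    for i in range(n):
        kappa_raw[i] = circle_through_three_points(prev_pts[i], pts[i],
                                                   next_pts[i])
    kappa = _circular_moving_average(kappa_raw, smooth_window)
    arc = np.arange(n) * resample_step
    return CurvatureProfile(arc_position=arc, kappa=kappa,
                            kappa_raw=kappa_raw, points=pts,
                            arc_offset=arc_offset,
                            smooth_window=smooth_window,
                            resample_step=resample_step)


def adaptive_curvature_profile(skel: RingSkeleton, arc_offset: float = 2.0,
                               smooth_window: int = 10,
                               resample_step: float = 0.2,
                               max_offset_fraction: float = 0.2
                               ) -> CurvatureProfile:
    """Curvature profile with the arc offset capped at a fraction of the
    perimeter, so small rings remain measurable with the same defaults."""
    eff = min(arc_offset, max_offset_fraction * skel.perimeter)
    return local_curvature_profile(skel, arc_offset=eff,
                                   smooth_window=smooth_window,
                                   resample_step=resample_step)


def classify_regions(profile: CurvatureProfile, factor: float = 1.0
                     ) -> np.ndarray:
    """Label each profile point curved/flat against the mean curvature.

    A point is ``curved`` iff κ > factor × mean κ (strictly).  Returns a
    boolean array (True = curved).  On a perfect circle no point strictly
    exceeds the mean, so everything is flat; this degenerate case is
    logged.
    """
    if len(profile.kappa) == 0:
        raise ValueError("empty curvature profile")
    curved = profile.kappa > factor * profile.mean_kappa
    if not curved.any():
        log.info("no point exceeds the mean curvature: uniform (circular) ring")
    return curved


def _runs_circular(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    """Contiguous runs (start, length, value) of a circular boolean array."""
    n = len(labels)
    if n == 0:
        return []
    if labels.all() or (~labels).all():
        return [(0, n, bool(labels[0]))]
    # rotate so position 0 starts a run
    change = np.nonzero(labels != np.roll(labels, 1))[0]
    start0 = int(change[0])
    rolled = np.roll(labels, -start0)
    runs = []
    i = 0
    while i < n:
        j = i
        while j < n and rolled[j] == rolled[i]:
            j += 1
        runs.append(((i + start0) % n, j - i, bool(rolled[i])))
        i = j
    return runs


def compression_factor(skel: RingSkeleton, profile: CurvatureProfile | None = None,
                       factor: float = 1.0
                       ) -> tuple[float, float, float]:
    """Degree of mechanical ring compression: ``(factor, d, h)``.

    ``h`` is the maximal extent of the ring perpendicular to the dominant
    flat direction, ``d`` the mean arc length of the two flat runs, and
    the compression factor is h / (perimeter/π) — 1 for a circle,
    decreasing with flattening.

    A ring whose curvature profile has no curved run is treated as
    uncompressed (d = 0, h = max extent).  Any run topology other than
    uniform or two-flat/two-cap raises :class:`NotCompressedRingError`.
    """
    if profile is None:
        profile = adaptive_curvature_profile(skel)
    curved = classify_regions(profile, factor=factor)
    pts = profile.points
    perimeter = profile.perimeter
    d0 = perimeter / math.pi

    # near-uniform curvature: an uncompressed (circular) ring
    mean_k = profile.mean_kappa
    if not curved.any() or (mean_k > 0 and np.ptp(profile.kappa) < 0.3 * mean_k):
        h = _max_extent(pts)
        return h / d0, 0.0, h

    runs = _runs_circular(curved)
    flat_runs = [r for r in runs if not r[2]]
    curved_runs = [r for r in runs if r[2]]
    # tolerate tiny spurious runs below 5% of the perimeter
    min_pts = max(int(0.05 * len(curved)), 2)
    flat_major = [r for r in flat_runs if r[1] >= min_pts]
    curved_major = [r for r in curved_runs if r[1] >= min_pts]
    if len(flat_major) != 2 or len(curved_major) != 2:
        raise NotCompressedRingError(
            f"expected two flat and two curved runs, found "
            f"{len(flat_major)} flat / {len(curved_major)} curved")

    step = profile.resample_step
    d = float(np.mean([r[1] * step for r in flat_major]))
    # dominant flat direction: principal axis of the flat-run points, each
    # run centred on its own mean (the two flats are parallel but offset)
    fp = np.concatenate([
        pts[np.arange(r[0], r[0] + r[1]) % len(pts)]
        - pts[np.arange(r[0], r[0] + r[1]) % len(pts)].mean(axis=0)
        for r in flat_major])
    _, _, vt = np.linalg.svd(fp, full_matrices=False)
    direction = vt[0]
    perp = np.array([-direction[1], direction[0]])
    proj = pts @ perp
    h = float(proj.max() - proj.min())
    return h / d0, d, h


def _max_extent(pts: np.ndarray) -> float:
    """Diameter of the point set (max pairwise extent via convex hull PCA)."""
    c = pts - pts.mean(axis=0)
    # max extent over a modest set of directions is enough for ring shapes
    thetas = np.linspace(0, math.pi, 180, endpoint=False)
    dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=-1)
    proj = c @ dirs.T
    return float((proj.max(axis=0) - proj.min(axis=0)).max())
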