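"""ROI intensity bookkeeping: ring-line and box sums, photobleaching
correction, and the bundle-expulsion intensity fraction.

All intensities are in arbitrary units; sum-intensity projections should be
used for bookkeeping (maximum projections are for geometry only).  The
central quantity is the expulsion fraction

    Actin_bundle / (Actin_early_ring − Actin_late_ring),

the share of intensity lost from the ring between two time points that
reappears in expelled bundles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .errors import IntensityError, InsufficientFramesError
from .image import ImageStack
from .segmentation import RingSkeleton

__all__ = [
    "IntensityTriple", "BlotPair", "ring_line_sum", "box_sum",
    "bleach_correct", "bleach_control_ratio", "expulsion_fraction",
    "blot_fraction",
]


@dataclass
class IntensityTriple:
    """Bundle / early-ring / late-ring intensities (a.u.)."""

    actin_bundle: float
    actin_early_ring: float
    actin_late_ring: float

    def __post_init__(self):
        if min(self.actin_bundle, self.actin_early_ring,
               self.actin_late_ring) < 0:
            raise ValueError("intensities must be non-negative")


@dataclass
class BlotPair:
    """Supernatant / pellet band intensities of an immunoblot lane pair."""

    S: float
    P: float

    def __post_init__(self):
        if self.S < 0 or self.P < 0:
            raise ValueError("band intensities must be non-negative")
        if self.S + self.P <= 0:
            raise ValueError("S + P must be > 0")


def _polyline_mask_distance(shape, paths, pixel_size):
    """Distance (px) of every pixel to the union of rasterised polylines."""
    raster = np.zeros(shape, dtype=bool)
    for path in paths:
        p = np.asarray(path, dtype=float) / pixel_size  # (x, y) in px
        # densely sample each segment at sub-pixel steps
        for a, b in zip(p[:-1], p[1:]):
            n = max(int(np.ceil(np.linalg.norm(b - a) * 2)), 1)
            ts = np.linspace(0, 1, n + 1)
            xs = np.clip(np.rint(a[0] + ts * (b[0] - a[0])).astype(int), 0,
                         shape[1] - 1)
            ys = np.clip(np.rint(a[1] + ts * (b[1] - a[1])).astype(int), 0,
                         shape[0] - 1)
            raster[ys, xs] = True
        if len(p) == 1:
            raster[int(np.clip(round(p[0][1]), 0, shape[0] - 1)),
                   int(np.clip(round(p[0][0]), 0, shape[1] - 1))] = True
    if not raster.any():
        return np.full(shape, np.inf)
    return ndimage.distance_transform_edt(~raster)


def ring_line_sum(img: ImageStack, skel: RingSkeleton,
                  width_px: float = 5.0,
                  branch_halo_px: float | None = None) -> float:
    """Sum of intensities along the ring circumference, excluding bundles.

    The ring band is every pixel within ``width_px`` pixels of the cycle
    polyline.  Where an attached bundle crosses the band its tails overlap
    the ring signal, so band pixels within ``branch_halo_px`` of a branch
    (default: same as ``width_px``) are treated as contaminated: the sum
    is the mean intensity of the clean band pixels scaled to the full band
    area — the automated equivalent of drawing a line along the ring
    without including the ring-associated bundles.
    """
    if img.ndim != 2:
        raise ValueError("ring_line_sum expects a 2D projection")
    data = np.asarray(img.data, dtype=np.float64)
    closed = np.vstack([skel.cycle, skel.cycle[:1]])
    d_cycle = _polyline_mask_distance(data.shape, [closed], img.pixel_size)
    band = d_cycle <= width_px
    n_band = int(band.sum())
    if n_band == 0:
        return 0.0
    if not skel.branches:
        return float(data[band].sum())
    ring_radius = skel.perimeter / (2.0 * math.pi)
    annulus = width_px * img.pixel_size < 0.8 * ring_radius
    branch_paths = [p for p, _ in skel.branches]
    if annulus:
        # thin-band regime: drop band sectors contaminated by bundle
        # crossings and scale the clean mean to the full band area
        halo = branch_halo_px if branch_halo_px is not None else width_px
        d_branch = _polyline_mask_distance(data.shape, branch_paths,
                                           img.pixel_size)
        clean = band & (d_branch > halo)
        if clean.sum() >= 0.2 * n_band:
            return float(data[clean].mean() * n_band)
    # disc-like band on a small ring (or nothing clean left): assign each
    # pixel to the nearer structure, with branches trimmed clear of the
    # cycle so the band keeps its width near attachments
    trim = min(0.35, 0.5 * width_px * img.pixel_size)
    trimmed = []
    for p in branch_paths:
        d_to_cycle = np.min(
            np.linalg.norm(p[:, None, :] - skel.cycle[None, :, :], axis=2),
            axis=1)
        keep = p[d_to_cycle > trim]
        if len(keep):
            trimmed.append(keep)
    d_branch = (_polyline_mask_distance(data.shape, trimmed, img.pixel_size)
                if trimmed else np.full(data.shape, np.inf))
    return float(data[band & (d_cycle <= d_branch)].sum())


def box_sum(img: ImageStack, skel: RingSkeleton, margin: float = 0.5) -> float:
    """Sum over the bounding box of the ring and all its bundles.

    ``margin`` (µm) pads the box; boxes exceeding the image are clipped
    with a warning.
    """
    if img.ndim != 2:
        raise ValueError("box_sum expects a 2D projection")
    data = np.asarray(img.data, dtype=np.float64)
    pts = [skel.cycle] + [p for p, _ in skel.branches]
    allp = np.vstack(pts)
    lo = (allp.min(axis=0) - margin) / img.pixel_size
    hi = (allp.max(axis=0) + margin) / img.pixel_size
    x0, y0 = int(np.floor(lo[0])), int(np.floor(lo[1]))
    x1, y1 = int(np.ceil(hi[0])) + 1, int(np.ceil(hi[1])) + 1
    if x0 < 0 or y0 < 0 or x1 > data.shape[1] or y1 > data.shape[0]:
        warnings.warn("ROI box exceeds the image; clipping to bounds")
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, data.shape[1]), min(y1, data.shape[0])
    return float(data[y0:y1, x0:x1].sum())


def bleach_correct(frames: np.ndarray) -> tuple[np.ndarray, float]:
    """Mono-exponential photobleaching correction of a time series.

    Fits ``I_t = I_0 · exp(−k·t)`` to the per-frame whole-field sums and
    divides each frame by its fitted decay factor.  A non-decaying series
    is returned unchanged with decay constant 0.

    Parameters
    ----------
    frames : array (t, ...) — any per-frame image (or scalar sum) series.

    Returns
    -------
    corrected frames, decay constant k (per frame)
    """
    frames = np.asarray(frames, dtype=np.float64)
    n = frames.shape[0]
    if n < 3:
        raise InsufficientFramesError("bleach correction needs >= 3 frames")
    sums = frames.reshape(n, -1).sum(axis=1)
    if np.any(sums <= 0):
        raise IntensityError("non-positive frame sums cannot be bleach-fitted")
    t = np.arange(n, dtype=float)
    # log-linear fit; robust enough for mono-exponential decay
    k = -np.polyfit(t, np.log(sums), 1)[0]
    if k <= 1e-10:  # numerically non-decaying
        return frames.copy(), 0.0
    factors = np.exp(-k * t)
    corrected = frames / factors.reshape((n,) + (1,) * (frames.ndim - 1))
    return corrected, float(k)


def bleach_control_ratio(frame_early: np.ndarray, frame_late: np.ndarray,
                         rois: list[tuple[slice, slice]] | None = None) -> float:
    """Late/early intensity ratio over control ROIs (≈1 means no bleaching).

    ``rois`` is a list of (row slice, col slice) applied identically to
    both frames; the whole frame is used when omitted.
    """
    fe = np.asarray(frame_early, dtype=np.float64)
    fl = np.asarray(frame_late, dtype=np.float64)
    if rois:
        early = sum(float(fe[r, c].sum()) for r, c in rois)
        late = sum(float(fl[r, c].sum()) for r, c in rois)
    else:
        early, late = float(fe.sum()), float(fl.sum())
    if early <= 0:
        raise IntensityError("early-frame control sum is zero")
    return late / early


def expulsion_fraction(t: IntensityTriple) -> float:
    """Fraction of ring intensity lost that reappears in bundles.

    Actin_bundle / (Actin_early_ring − Actin_late_ring).  Values above 1
    are allowed (measurement noise) but warned about.
    """
    denom = t.actin_early_ring - t.actin_late_ring
    if denom <= 0:
        raise IntensityError("ring did not lose intensity between time points")
    f = t.actin_bundle / denom
    if f > 1:
        warnings.warn(f"expulsion fraction {f:.2f} > 1 (measurement noise?)")
    return f


def blot_fraction(b: BlotPair) -> float:
    """Supernatant fraction of an immunoblot: S / (S + P)."""
    return b.S / (b.S + b.P)
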