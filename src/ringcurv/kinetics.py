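"""Ring contraction kinetics: perimeter/diameter time series and OLS rates.

The ring perimeter of each frame is the total arc length of the traced
skeleton cycle; the diameter is perimeter/π.  Contraction rate, flat/height
shortening rates of compressed rings and bundle travel rates are all the
magnitude of an ordinary-least-squares slope against time, reported with a
95% confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientFramesError, NoRingError
from .segmentation import RingSkeleton

__all__ = [
    "KineticsSeries", "RateEstimate", "perimeter_of_skeleton",
    "diameter_from_perimeter", "contraction_rate", "flat_and_height_rates",
    "bundle_travel_rate",
]


@dataclass
class RateEstimate:
    """|OLS slope| with its 95% confidence interval."""

    rate: float           # magnitude of the slope, µm/min
    ci_low: float
    ci_high: float
    slope: float          # signed slope
    stderr: float
    intercept: float

    def __iter__(self):
        return iter((self.rate, self.ci_low, self.ci_high))


@dataclass
class KineticsSeries:
    """Per-frame ring measurements of one time-lapse."""

    time: np.ndarray                 # min
    perimeter: np.ndarray            # µm
    flat_length_d: np.ndarray | None = None
    height_h: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.perimeter = np.asarray(self.perimeter, dtype=float)
        if self.time.shape != self.perimeter.shape:
            raise ValueError("time and perimeter must have the same length")

    @property
    def diameter(self) -> np.ndarray:
        return self.perimeter / math.pi


def perimeter_of_skeleton(skel: RingSkeleton) -> float:
    """Total length of the closed ring skeleton (µm)."""
    if skel.n_points < 3:
        raise NoRingError("skeleton has no closed cycle")
    return skel.perimeter


def diameter_from_perimeter(perimeter: float) -> float:
    """Ring diameter (µm) from its perimeter: perimeter / π."""
    if np.any(np.asarray(perimeter) <= 0):
        raise ValueError("perimeter must be > 0")
    return perimeter / math.pi


def _ols_rate(t: np.ndarray, y: np.ndarray) -> RateEstimate:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 3:
        raise InsufficientFramesError("need >= 3 frames for a rate estimate")
    res = stats.linregress(t, y)
    dof = len(t) - 2
    tcrit = stats.t.ppf(0.975, dof)
    lo = res.slope - tcrit * res.stderr
    hi = res.slope + tcrit * res.stderr
    mag = abs(res.slope)
    return RateEstimate(rate=mag, ci_low=min(abs(lo), abs(hi)) if lo * hi > 0 else 0.0,
                        ci_high=max(abs(lo), abs(hi)), slope=res.slope,
                        stderr=res.stderr, intercept=res.intercept)


def contraction_rate(series: KineticsSeries, on: str = "perimeter"
                     ) -> RateEstimate:
    """Ring contraction rate: |slope| of a fitted line vs. time (µm/min).

    ``on`` selects the fitted quantity: ``"perimeter"`` (default) or
    ``"diameter"``.
    """
    if on == "perimeter":
        y = series.perimeter
    elif on == "diameter":
        y = series.diameter
    else:
        raise ValueError("on must be 'perimeter' or 'diameter'")
    return _ols_rate(series.time, y)


def flat_and_height_rates(series: KineticsSeries
                          ) -> tuple[RateEstimate, RateEstimate]:
    """Shortening rates (Δd/min, Δh/min) of a compressed ring's flat
    segments and height."""
    if series.flat_length_d is None or series.height_h is None:
        raise ValueError("series lacks compressed-ring d/h measurements")
    return (_ols_rate(series.time, np.asarray(series.flat_length_d)),
            _ols_rate(series.time, np.asarray(series.height_h)))


def bundle_travel_rate(times: np.ndarray, tip_positions: np.ndarray,
                       attachment_point: np.ndarray,
                       max_gap_frames: int = 1) -> list[RateEstimate]:
    """Travel rate of an expelled bundle tip away from its ring attachment.

    ``tip_positions`` is (N, 2) µm per tracked frame; the distance from the
    frozen ``attachment_point`` is regressed against time.  Tracks with
    gaps longer than ``max_gap_frames`` (detected from irregular time
    steps) are split with a warning and one rate per segment is returned.
    """
    times = np.asarray(times, dtype=float)
    tips = np.atleast_2d(np.asarray(tip_positions, dtype=float))
    ap = np.asarray(attachment_point, dtype=float)
    dist = np.linalg.norm(tips - ap[None, :], axis=1)
    dt = np.diff(times)
    base = np.min(dt) if len(dt) else 1.0
    breaks = np.nonzero(dt > (max_gap_frames + 0.5) * base)[0]
    segments = np.split(np.arange(len(times)), breaks + 1)
    if len(segments) > 1:
        warnings.warn(f"track has gaps; split into {len(segments)} segments")
    out = []
    for seg in segments:
        if len(seg) >= 3:
            out.append(_ols_rate(times[seg], dist[seg]))
    if not out:
        raise InsufficientFramesError("no track segment with >= 3 frames")
    return out
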