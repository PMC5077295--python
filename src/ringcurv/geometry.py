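"""Analytic ring geometries: circles and mechanically compressed "stadium" rings.

A stadium is the closed curve formed by two parallel flat segments of length
``d`` joined by two semicircular caps of diameter ``h`` (the ring height).
It models a contractile ring flattened by mechanical compression: the flat
segments have zero curvature, the caps have curvature ``2/h``.  A stadium
with ``d = 0`` degenerates to a circle of diameter ``h``.

All lengths are in micrometres.  Rings are parameterised by arc length
``s in [0, perimeter)`` starting at the left end of the top flat segment
(for a circle: the point at angle 0) and proceeding counter-clockwise in the
ring plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RingGeometry", "BundleSpec", "circle", "stadium"]


@dataclass(frozen=True)
class RingGeometry:
    """A planar ring centreline placed in 3D.

    Parameters
    ----------
    kind : {"circle", "stadium"}
    radius : float
        Circle radius (µm); ignored for stadiums.
    flat_length_d : float
        Stadium flat-segment length d (µm).
    height_h : float
        Stadium height h (µm) = diameter of the semicircular caps.
    center : 3-tuple of float
        Ring centre in µm, (x, y, z).
    normal_tilt : float
        Angle in degrees between the ring-plane normal and the optical (z)
        axis.  The tilt is a rotation about the x axis.
    """

    kind: str = "circle"
    radius: float = 1.0
    flat_length_d: float = 0.0
    height_h: float = 0.0
    center: tuple = (0.0, 0.0, 0.0)
    normal_tilt: float = 0.0

    def __post_init__(self):
        if self.kind not in ("circle", "stadium"):
            raise ValueError(f"unknown ring kind {self.kind!r}")
        if self.kind == "circle" and self.radius <= 0:
            raise ValueError("circle radius must be > 0")
        if self.kind == "stadium":
            if self.flat_length_d < 0:
                raise ValueError("stadium flat length d must be >= 0")
            if self.height_h <= 0:
                raise ValueError("stadium height h must be > 0")

    # -- scalars -----------------------------------------------------------

    @property
    def perimeter(self) -> float:
        """Perimeter in µm: 2πr (circle) or 2d + πh (stadium)."""
        if self.kind == "circle":
            return 2.0 * math.pi * self.radius
        return 2.0 * self.flat_length_d + math.pi * self.height_h

    @property
    def diameter(self) -> float:
        """Effective diameter, perimeter / π."""
        return self.perimeter / math.pi

    @property
    def mean_curvature(self) -> float:
        """Arc-length-weighted mean of the local curvature (µm⁻¹)."""
        if self.kind == "circle":
            return 1.0 / self.radius
        # caps contribute 2/h over arc πh, flats contribute 0 over 2d
        return (math.pi * self.height_h * (2.0 / self.height_h)) / self.perimeter

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the ring plane (tilt about x)."""
        t = math.radians(self.normal_tilt)
        return np.array([0.0, math.sin(t), math.cos(t)])

    # -- arc-length parameterisation --------------------------------------

    def point_at_arc(self, s):
        """In-plane 2D point(s) (x, y) at arc position(s) ``s`` µm.

        Counter-clockwise; ``s`` wraps modulo the perimeter.
        """
        s = np.mod(np.asarray(s, dtype=float), self.perimeter)
        if self.kind == "circle":
            # start at angle +90° so s=0 sits on top, matching the stadium
            theta = s / self.radius + math.pi / 2.0
            return np.stack(
                [self.radius * np.cos(theta), self.radius * np.sin(theta)], axis=-1
            )
        d, r = self.flat_length_d, self.height_h / 2.0
        cap = math.pi * r
        x = np.empty_like(s)
        y = np.empty_like(s)
        # segment boundaries: top flat (d, right to left in -x), left cap,
        # bottom flat, right cap; CCW with y up.
        s1, s2, s3 = d, d + cap, 2 * d + cap
        m = s < s1
        x[m] = d / 2.0 - s[m]
        y[m] = r
        m = (s >= s1) & (s < s2)
        phi = (s[m] - s1) / r  # 0..π around the left cap
        x[m] = -d / 2.0 - r * np.sin(phi)
        y[m] = r * np.cos(phi)
        m = (s >= s2) & (s < s3)
        x[m] = -d / 2.0 + (s[m] - s2)
        y[m] = -r
        m = s >= s3
        phi = (s[m] - s3) / r
        x[m] = d / 2.0 + r * np.sin(phi)
        y[m] = -r * np.cos(phi)
        return np.stack([x, y], axis=-1)

    def curvature_at_arc(self, s):
        """True local curvature (µm⁻¹) at arc position(s) ``s``."""
        s = np.mod(np.asarray(s, dtype=float), self.perimeter)
        if self.kind == "circle":
            return np.full_like(s, 1.0 / self.radius)
        d, r = self.flat_length_d, self.height_h / 2.0
        cap = math.pi * r
        s1, s2, s3 = d, d + cap, 2 * d + cap
        on_cap = ((s >= s1) & (s < s2)) | (s >= s3)
        return np.where(on_cap, 2.0 / self.height_h, 0.0)

    def on_curved_region(self, s):
        """Ground-truth curved/flat flag at arc position(s) ``s``."""
        if self.kind == "circle":
            return np.ones(np.shape(np.asarray(s)), dtype=bool)
        return self.curvature_at_arc(s) > 0

    def outward_direction_at_arc(self, s):
        """In-plane outward unit vector(s) at arc position(s) ``s``."""
        p = np.atleast_2d(self.point_at_arc(s))
        if self.kind == "circle":
            out = p / np.linalg.norm(p, axis=-1, keepdims=True)
        else:
            d = self.flat_length_d
            # outward = away from the nearest point of the core segment
            # [-d/2, d/2] × {0}
            cx = np.clip(p[:, 0], -d / 2.0, d / 2.0)
            v = p - np.stack([cx, np.zeros_like(cx)], axis=-1)
            out = v / np.linalg.norm(v, axis=-1, keepdims=True)
        return out.reshape(np.shape(np.atleast_1d(np.asarray(s))) + (2,)).squeeze()

    def to_world(self, points_2d: np.ndarray) -> np.ndarray:
        """Map in-plane 2D points to 3D world coordinates (tilt + centre)."""
        p = np.atleast_2d(points_2d)
        t = math.radians(self.normal_tilt)
        x = p[:, 0]
        y = p[:, 1] * math.cos(t)
        z = p[:, 1] * math.sin(t)
        world = np.stack([x, y, z], axis=-1) + np.asarray(self.center)
        return world

    def sample_world(self, step: float) -> tuple[np.ndarray, np.ndarray]:
        """Densely sample the centreline; returns (arc positions, 3D points)."""
        n = max(int(math.ceil(self.perimeter / step)), 8)
        s = np.arange(n) * (self.perimeter / n)
        return s, self.to_world(self.point_at_arc(s))


def circle(radius: float, center=(0.0, 0.0, 0.0), normal_tilt: float = 0.0) -> RingGeometry:
    return RingGeometry(kind="circle", radius=radius, center=tuple(center),
                        normal_tilt=normal_tilt)


def stadium(flat_length_d: float, height_h: float, center=(0.0, 0.0, 0.0),
            normal_tilt: float = 0.0) -> RingGeometry:
    return RingGeometry(kind="stadium", flat_length_d=flat_length_d,
                        height_h=height_h, center=tuple(center),
                        normal_tilt=normal_tilt)


@dataclass
class BundleSpec:
    """A linear bundle attached to the ring, elongating over time.

    Attributes
    ----------
    origin_arc : float
        Arc position (µm) of the attachment point on the ring.
    lengths : sequence of float
        Bundle length per frame (µm), non-negative and non-decreasing.
    direction : 2-vector or None
        Outward unit vector in the ring plane; derived from the geometry
        when None.
    on_curved_region : bool
        Ground truth: whether the attachment sits on a curved region.
    """

    origin_arc: float
    lengths: np.ndarray
    direction: np.ndarray | None = None
    on_curved_region: bool = True

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("bundle lengths must be non-negative")
        if np.any(np.diff(self.lengths) < -1e-9):
            raise ValueError("bundle lengths must be non-decreasing over frames")
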