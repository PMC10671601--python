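"""Root midline geometry: arc-length resampling, disk placement, axial projection.

The positional reference frame for all kinematic quantities is the root
midline, anchored at the quiescent center (QC).  A user supplies a handful
of seed points running from the QC toward the mature part of the root; the
midline is the piecewise-linear curve through those seeds resampled to a
fixed number of points equally spaced in arc length.  Circular tracking
disks are then placed on the midline at regular arc-length stations, the
first disk sitting exactly on the QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "Midline",
    "Disk",
    "interpolate_midline",
    "place_disks",
    "tangent_at",
    "axial_component",
]


class GeometryError(ValueError):
    """Raised for degenerate midline geometry (e.g. zero-length tangent)."""


@dataclass(frozen=True)
class Midline:
    """Arc-length parameterized polyline from the QC along the root axis.

    Attributes
    ----------
    points : (N, 2) float array
        Midline vertices as ``(x, y)`` pixel coordinates (x = column,
        y = row, 0-based, sub-pixel positions allowed).  The first point is
        the QC.
    arc_length : (N,) float array
        Cumulative polyline distance in px from the QC to each vertex;
        strictly increasing, ``arc_length[0] == 0``.
    """

    points: np.ndarray
    arc_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise GeometryError("midline needs at least two 2-D points")
        object.__setattr__(self, "points", pts)
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            object.__setattr__(
                self, "arc_length", np.concatenate([[0.0], np.cumsum(seg)])
            )
        else:
            s = np.asarray(self.arc_length, dtype=float)
            if s.shape != (pts.shape[0],) or np.any(np.diff(s) <= 0):
                raise GeometryError("arc_length must be strictly increasing")
            object.__setattr__(self, "arc_length", s)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, station: float | np.ndarray) -> np.ndarray:
        """Interpolate the midline position at an arc-length station (px)."""
        x = np.interp(station, self.arc_length, self.points[:, 0])
        y = np.interp(station, self.arc_length, self.points[:, 1])
        return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class Disk:
    """Circular tracking patch centered on the midline.

    ``offsets`` holds every integer pixel offset ``(dx, dy)`` with
    ``dx**2 + dy**2 <= radius**2``, relative to the (possibly sub-pixel)
    center.  These are the in-patch coordinates the affine motion model
    acts on.
    """

    center: np.ndarray
    radius: float
    station: float
    disk_id: int = 0
    offsets: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.offsets is None:
            object.__setattr__(self, "offsets", disk_offsets(self.radius))


def disk_offsets(radius: float) -> np.ndarray:
    """Integer pixel offsets covering the closed disk of the given radius."""
    r = int(np.floor(radius))
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    keep = dx**2 + dy**2 <= radius**2
    return np.stack([dx[keep], dy[keep]], axis=1).astype(float)


def _collapse_duplicates(pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > tol:
            keep.append(i)
    if len(keep) < len(pts):
        warnings.warn(
            "collapsed duplicated consecutive seed points", stacklevel=3
        )
    return pts[keep]


def interpolate_midline(seed_points, count: int = 100) -> Midline:
    """Resample a seed polyline to `count` points equally spaced in arc length.

    The curve is piecewise linear through the seeds; the first output point
    is exactly the first seed (the QC).  Duplicated consecutive seeds are
    collapsed with a warning; fewer than two distinct seeds is an error.
    """
    pts = np.asarray(seed_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError("seed points must be an (N, 2) array of (x, y)")
    pts = _collapse_duplicates(pts)
    if len(pts) < 2:
        raise GeometryError("need at least two distinct seed points")
    if count < 2:
        raise GeometryError("count must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], count)
    out = np.column_stack(
        [np.interp(targets, s, pts[:, 0]), np.interp(targets, s, pts[:, 1])]
    )
    out[0] = pts[0]  # QC is preserved exactly
    return Midline(points=out, arc_length=None)


def place_disks(midline: Midline, spacing: float = 10.0, radius: float = 15.0,
                ) -> list[Disk]:
    """Place tracking disks at stations 0, spacing, 2*spacing, ... on the midline.

    The first disk sits on the QC; the last station does not exceed the
    midline's total arc length.
    """
    if spacing <= 0 or radius <= 0:
        raise GeometryError("spacing and radius must be positive")
    n = int(np.floor(midline.total_length / spacing + 1e-9)) + 1
    stations = np.arange(n) * spacing
    offsets = disk_offsets(radius)
    return [
        Disk(center=midline.point_at(st), radius=radius, station=float(st),
             disk_id=i, offsets=offsets)
        for i, st in enumerate(stations)
    ]


def tangent_at(midline: Midline, station: float) -> np.ndarray:
    """Unit tangent of the midline at an arc-length station, pointing away
    from the QC (direction of increasing arc length).

    Estimated by central difference of the midline vertices bracketing the
    station (one-sided at the ends).
    """
    s = midline.arc_length
    if not (s[0] - 1e-9 <= station <= s[-1] + 1e-9):
        raise GeometryError("station outside the midline arc-length range")
    i = int(np.searchsorted(s, station))
    i = min(max(i, 0), len(s) - 1)
    lo = max(i - 1, 0)
    hi = min(i + 1, len(s) - 1)
    vec = midline.points[hi] - midline.points[lo]
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise GeometryError("degenerate midline segment: zero-length tangent")
    return vec / norm


def axial_component(displacement, disk: Disk, midline: Midline,
                    qc_displacement) -> float:
    """Axial velocity of a disk relative to the QC (px/frame).

    Projects the QC-referenced displacement onto the local midline tangent;
    positive values point away from the QC.  Subtracting the tracked QC
    disk's displacement makes the result insensitive to whole-root
    translation in the image frame.
    """
    rel = np.asarray(displacement, dtype=float) - np.asarray(
        qc_displacement, dtype=float
    )
    return float(rel @ tangent_at(midline, disk.station))
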