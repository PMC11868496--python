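"""Geometry of magnetically tilted pillar electrodes.

A soft pillar electrode of height ``h`` anchored at its base and deflected
by an external magnet tilts through an angle ``theta``; its tip travels an
arc of length ``d = 2*pi*h*theta/360``.  These relations, the tilt angle
recovered from tracked tip coordinates, linear trajectory fits, and the
area swept by the tip over a set of tilt trajectories are what this module
computes.

All lengths are micrometres, all angles degrees unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

__all__ = [
    "TiltState",
    "TipTrack",
    "SweptArea",
    "min_height",
    "tip_displacement",
    "tilt_degree_from_coords",
    "fit_trajectory",
    "swept_area",
    "TIP_OPEN_AREA_UM2",
]

#: Open (uninsulated) tip area of a pillar electrode, um^2.
TIP_OPEN_AREA_UM2 = 78.5


@dataclass(frozen=True)
class TiltState:
    """Height, tilt angle and arc-length tip displacement of one electrode."""

    h: float        # electrode height, um
    theta: float    # tilt angle, degrees
    d: float        # tip displacement (arc length), um

    @classmethod
    def from_height_angle(cls, h: float, theta: float) -> "TiltState":
        return cls(h=h, theta=theta, d=tip_displacement(h, theta))


@dataclass
class TipTrack:
    """Tracked tip coordinates along a magnet sweep.

    ``magnet_um`` is the magnet displacement, ``x_um``/``z_um`` the tip
    coordinates in the imaging (xz) plane.  ``x_ref`` is the pre-tilt tip
    x-coordinate (defaults to the first tracked point).
    """

    magnet_um: np.ndarray
    x_um: np.ndarray
    z_um: np.ndarray
    x_ref: float | None = None
    cycle: int = 0

    def __post_init__(self) -> None:
        self.magnet_um = np.asarray(self.magnet_um, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if not (self.magnet_um.shape == self.x_um.shape == self.z_um.shape):
            raise ValueError("magnet, x and z tracks must have equal length")
        if np.any(self.z_um <= 0):
            raise ValueError("tracked z coordinates must be positive")
        if self.x_ref is None:
            self.x_ref = float(self.x_um[0])


@dataclass
class SweptArea:
    """Union area covered by the electrode tip over a set of trajectories."""

    area: float                 # um^2
    tip_open_area: float        # um^2
    n_trajectories: int
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = self.area / self.tip_open_area


def min_height(d: float, theta: float) -> float:
    """Minimum electrode height whose tip moves ``d`` um at tilt ``theta`` deg.

    Inverts the arc-length relation: ``h = d * 360 / (2 * pi * theta)``.

    Raises
    ------
    ValueError
        If ``d <= 0`` or ``theta <= 0`` (a zero tilt gives no displacement,
        so no finite height exists).
    """
    if d <= 0:
        raise ValueError(f"tip displacement must be positive, got {d}")
    if theta <= 0:
        raise ValueError(f"tilt angle must be positive, got {theta}")
    return d * 360.0 / (2.0 * np.pi * theta)


def tip_displacement(h: float, theta: float) -> float:
    """Arc-length displacement of the tip of an ``h``-um electrode tilted ``theta`` deg."""
    if h <= 0:
        raise ValueError(f"electrode height must be positive, got {h}")
    if theta < 0:
        raise ValueError(f"tilt angle must be non-negative, got {theta}")
    return 2.0 * np.pi * h * theta / 360.0


def tilt_degree_from_coords(x1: float, x2: float, z2: float) -> float:
    """Tilt angle from tracked tip coordinates.

    ``theta = atan(|x2 - x1| / z2)`` in degrees, where ``x1`` is the
    pre-tilt tip x-coordinate and ``(x2, z2)`` the tilted tip position.
    """
    if z2 <= 0:
        raise ValueError(f"z2 must be positive, got {z2}")
    return float(np.degrees(np.arctan2(abs(x2 - x1), z2)))


def fit_trajectory(track: TipTrack) -> dict:
    """Least-squares slopes of tilt angle and tip displacement vs magnet travel.

    Returns a dict with

    - ``theta_slope``: degrees of tilt per um of magnet displacement,
    - ``tip_slope``: um of lateral tip displacement per um of magnet
      displacement,
    - ``theta_intercept``, ``tip_intercept`` and per-fit RMS residuals.
    """
    if track.magnet_um.size < 2:
        raise ValueError("at least two track points are required for a fit")
    theta = np.array(
        [tilt_degree_from_coords(track.x_ref, x, z)
         for x, z in zip(track.x_um, track.z_um)]
    )
    disp = np.abs(track.x_um - track.x_ref)
    m = track.magnet_um

    out: dict = {}
    for name, y in (("theta", theta), ("tip", disp)):
        slope, intercept = np.polyfit(m, y, 1)
        resid = y - (slope * m + intercept)
        out[f"{name}_slope"] = float(slope)
        out[f"{name}_intercept"] = float(intercept)
        out[f"{name}_rms_residual"] = float(np.sqrt(np.mean(resid**2)))
    return out


def swept_area(
    trajectories: Sequence[np.ndarray],
    tip_open_area: float = TIP_OPEN_AREA_UM2,
) -> SweptArea:
    """Area of the union of tip-radius-dilated trajectory strips.

    Each trajectory is an (n, 2) array of planar tip positions (um).  The
    detectable strip around a trajectory is the trajectory dilated by the
    tip radius ``r = sqrt(tip_open_area / pi)``; the reported area is the
    area of the union of all strips (exact polygonal union).  A
    single-point trajectory contributes one tip-sized disc, so with no
    motion the area equals ``tip_open_area`` and the ratio is 1.
    """
    if tip_open_area <= 0:
        raise ValueError("tip_open_area must be positive")
    if len(trajectories) == 0:
        raise ValueError("at least one trajectory is required")
    r = float(np.sqrt(tip_open_area / np.pi))
    shapes = []
    for traj in trajectories:
        pts = np.atleast_2d(np.asarray(traj, dtype=float))
        if pts.shape[1] != 2:
            raise ValueError("trajectories must be (n, 2) arrays of xy points")
        # collapse exact duplicates; a degenerate path is a disc
        if pts.shape[0] == 1 or np.allclose(pts, pts[0]):
            shapes.append(Point(pts[0]).buffer(r, quad_segs=64))
        else:
            shapes.append(LineString(pts).buffer(r, quad_segs=64))
    union = unary_union(shapes)
    return SweptArea(
        area=float(union.area),
        tip_open_area=float(tip_open_area),
        n_trajectories=len(trajectories),
    )
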