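"""Exact geometry of circular-arc stimuli and the half-disk occluder.

A dot travels rightward along a circular arc, disappears behind the
straight edge of a half-disk occluder, and reemerges somewhere on the
curved edge.  The curved edge is divided into 20 contiguous response
bins of 9 degrees each, numbered clockwise from the top (-90 deg) to
the bottom (+90 deg).

Coordinate convention
---------------------
The origin sits at the occlusion point (the midpoint of the occluder's
straight edge) and the occluded region lies in the +x half-plane.  The
emergence position angle ``phi`` is measured at the origin, clockwise
positive: ``phi = 0`` along +x, ``phi = -90`` at the top edge (bin 1
side) and ``phi = +90`` at the bottom edge (bin 20 side).  The launch
orientation ``theta`` uses the same clockwise-positive sense, so a
straight continuation of a trajectory with heading ``theta`` would
emerge at ``phi = theta``.  Positive curvature bends the path upward
(toward negative ``phi``).

Internally angles are radians in the ordinary counter-clockwise
mathematical sense; all public interfaces speak degrees in the
clockwise convention above.

Curvature is the inverse radius of the generating circle in inverse
*pixels* (1 px = 0.032 degrees of visual angle on the reference
display).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArcTrajectory",
    "OccluderGeometry",
    "EmergencePrediction",
    "GeometryError",
    "bin_of_angle",
    "bin_center",
    "bin_edges",
    "emergence_angle",
    "is_legal",
    "occlusion_kinematics",
    "arc_position",
    "arc_state",
    "predict_emergence",
]

#: display scale of the reference setup
DVA_PER_PX = 0.032
#: default visible arc length, px (4 degrees of visual angle)
DEFAULT_VISIBLE_LENGTH = 125.0
#: default dot speed, px/s (12 degrees of visual angle per second)
DEFAULT_SPEED = 375.0


class GeometryError(ValueError):
    """A trajectory/occluder combination is geometrically infeasible."""


@dataclass(frozen=True)
class ArcTrajectory:
    """A visible circular-arc stimulus.

    Parameters
    ----------
    curvature
        Signed inverse radius of the generating circle, 1/px.  Positive
        curvature deflects the heading toward negative emergence angles
        (upward).  Must be nonzero; straight lines are excluded by the
        task design.
    orientation
        Signed heading at the occlusion point, degrees, clockwise
        positive (so positive orientation points toward positive
        emergence angles).
    visible_length
        Length of the visible portion of the arc, px.
    speed
        Constant dot speed along the arc, px/s.
    """

    curvature: float
    orientation: float
    visible_length: float = DEFAULT_VISIBLE_LENGTH
    speed: float = DEFAULT_SPEED

    def __post_init__(self) -> None:
        if self.curvature == 0:
            raise GeometryError("straight trajectories (curvature = 0) are excluded")
        if not self.visible_length > 0:
            raise ValueError("visible_length must be positive")
        if not self.speed > 0:
            raise ValueError("speed must be positive")


@dataclass(frozen=True)
class OccluderGeometry:
    """The half-disk occluder and its response-bin partition."""

    radius: float
    bin_count: int = 20
    bin_span: float = 9.0
    dva_per_px: float = DVA_PER_PX

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if abs(self.bin_count * self.bin_span - 180.0) > 1e-9:
            raise ValueError("bins must tile the curved edge: bin_count * bin_span == 180")


@dataclass(frozen=True)
class EmergencePrediction:
    """Where and when an arc reemerges from behind the occluder."""

    angle: float
    bin: int
    occluded_arclength: float
    occluded_duration: float


def bin_of_angle(angle: float, occ: OccluderGeometry) -> int:
    """Map an emergence angle (degrees) to its response bin (1-based).

    Bins are half-open intervals ``[-90 + span*(k-1), -90 + span*k)``
    with the final bin closed at +90.
    """
    if not -90.0 <= angle <= 90.0:
        raise GeometryError(
            f"angle {angle!r} outside [-90, 90]: trajectory did not emerge on the curved edge"
        )
    k = int(math.floor((angle + 90.0) / occ.bin_span)) + 1
    return min(k, occ.bin_count)


def bin_edges(b: int, occ: OccluderGeometry) -> tuple[float, float]:
    """Lower and upper angular edges of bin ``b``, degrees."""
    if not 1 <= b <= occ.bin_count:
        raise ValueError(f"bin {b} outside 1..{occ.bin_count}")
    lo = -90.0 + occ.bin_span * (b - 1)
    return lo, lo + occ.bin_span


def bin_center(b: int, occ: OccluderGeometry) -> float:
    """Angular center of bin ``b``, degrees."""
    lo, hi = bin_edges(b, occ)
    return 0.5 * (lo + hi)


def _deflection_deg(abs_curvature: float, radius: float) -> float:
    """Half the turn accumulated while crossing the occluder, degrees."""
    half_chord = abs_curvature * radius / 2.0
    if half_chord >= 1.0:
        raise GeometryError(
            f"no chord of length {radius} exists on a circle of curvature {abs_curvature}"
        )
    return math.degrees(math.asin(half_chord))


def emergence_angle(traj: ArcTrajectory, occ: OccluderGeometry | float) -> float:
    """Closed-form emergence position angle ``phi`` on the curved edge.

    The chord from the occlusion point to the emergence point subtends
    a central angle ``2*arcsin(|k|R/2)`` on the generating circle, and
    the chord's direction is the launch heading rotated by half the
    accumulated turn, giving

        ``phi = theta - sign(kappa) * deg(arcsin(|kappa| R / 2))``.
    """
    radius = occ.radius if isinstance(occ, OccluderGeometry) else float(occ)
    d = _deflection_deg(abs(traj.curvature), radius)
    return traj.orientation - math.copysign(d, traj.curvature)


def emergence_angles(
    curvatures: np.ndarray, orientations: np.ndarray, radius: float
) -> np.ndarray:
    """Vectorized :func:`emergence_angle` (degrees; no legality checks).

    Arguments of ``arcsin`` at or beyond 1 yield NaN, marking curvature
    too extreme for the occluder radius.
    """
    kappa = np.asarray(curvatures, dtype=float)
    theta = np.asarray(orientations, dtype=float)
    arg = np.abs(kappa) * radius / 2.0
    with np.errstate(invalid="ignore"):
        d = np.degrees(np.arcsin(np.where(arg < 1.0, arg, np.nan)))
    return theta - np.sign(kappa) * d


def is_legal(
    traj: ArcTrajectory,
    radii: list[float] | tuple[float, ...],
    curvature_min: float,
    curvature_max: float,
    orientation_max: float = 60.0,
) -> bool:
    """Whether a trajectory is admissible for every occluder radius.

    Legal trajectories have nonzero curvature inside the configured
    magnitude bounds, bounded orientation, a reachable curved edge
    (``|kappa| * max(R) < 2``), and an emergence angle within
    [-90, +90] at every radius -- i.e. they do not curve back toward
    the occlusion point before reaching the curved edge.
    """
    if not radii:
        raise ValueError("radii must be non-empty")
    k = traj.curvature
    if k == 0 or not curvature_min <= abs(k) <= curvature_max:
        return False
    if abs(traj.orientation) > orientation_max:
        return False
    if abs(k) * max(radii) >= 2.0:
        return False
    for r in radii:
        if abs(emergence_angle(traj, r)) > 90.0:
            return False
    return True


def occlusion_kinematics(
    traj: ArcTrajectory, occ: OccluderGeometry
) -> tuple[float, float]:
    """Arclength (px) and duration (s) of the occluded portion."""
    phi = emergence_angle(traj, occ)
    if abs(phi) > 90.0:
        raise GeometryError("illegal trajectory: emerges outside the curved edge")
    k = abs(traj.curvature)
    arclength = (2.0 / k) * math.asin(k * occ.radius / 2.0)
    return arclength, arclength / traj.speed


def arc_position(traj: ArcTrajectory, s: float) -> np.ndarray:
    """Position (px) of the dot at signed arclength ``s`` from occlusion.

    ``s = 0`` is the occlusion point; negative ``s`` is the visible
    approach, positive ``s`` is behind the occluder.  The point lies on
    the circle of radius ``1/|kappa|`` tangent at the origin to the
    launch heading.
    """
    if s < -traj.visible_length - 1e-9:
        raise ValueError(f"arclength {s} before the start of the visible arc")
    # The farthest meaningful point is half a turn around the
    # generating circle; past it the arc curves back toward the origin.
    if s > math.pi / abs(traj.curvature) + 1e-9:
        raise ValueError(f"arclength {s} beyond half a turn of the generating circle")
    pos, _, _ = arc_state(traj, s)
    return pos


def arc_state(traj: ArcTrajectory, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Position, velocity and acceleration at signed arclength ``s``.

    Velocity is tangent with magnitude ``speed``; acceleration is the
    centripetal term ``speed**2 * |kappa|`` pointing at the circle
    center.  Used as ground truth by the observer simulations.
    """
    c = _math_curvature(traj)
    a0 = _math_heading(traj)
    a = a0 + c * s
    if abs(c) < 1e-300:  # unreachable given kappa != 0, kept for safety
        pos = np.array([math.cos(a0) * s, math.sin(a0) * s])
    else:
        pos = np.array(
            [
                (math.sin(a) - math.sin(a0)) / c,
                -(math.cos(a) - math.cos(a0)) / c,
            ]
        )
    v = traj.speed * np.array([math.cos(a), math.sin(a)])
    acc = traj.speed**2 * c * np.array([-math.sin(a), math.cos(a)])
    return pos, v, acc


def _math_curvature(traj: ArcTrajectory) -> float:
    # Positive stimulus curvature turns the mathematical heading
    # counter-clockwise (upward, toward negative phi).
    return traj.curvature


def _math_heading(traj: ArcTrajectory) -> float:
    # Clockwise-positive degrees -> counter-clockwise-positive radians.
    return -math.radians(traj.orientation)


def math_angle_to_phi(xy: np.ndarray) -> float:
    """Convert a position (math coords) to the clockwise emergence angle."""
    return -math.degrees(math.atan2(xy[1], xy[0]))


def predict_emergence(traj: ArcTrajectory, occ: OccluderGeometry) -> EmergencePrediction:
    """Full emergence prediction: angle, bin, occluded arclength/duration."""
    phi = emergence_angle(traj, occ)
    if abs(phi) > 90.0:
        raise GeometryError("illegal trajectory: emerges outside the curved edge")
    arclength, duration = occlusion_kinematics(traj, occ)
    return EmergencePrediction(
        angle=phi,
        bin=bin_of_angle(phi, occ),
        occluded_arclength=arclength,
        occluded_duration=duration,
    )
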