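"""Planar angle conventions and the indirect (implicit) measure of felt hand direction.

Coordinate frame: the digitizer plane, ``x`` rightward and ``y`` away from the
participant (from the start position toward the first target T1), units cm.
Directions are expressed in degrees with 0° = straight ahead from T1 (the +y
axis) and counter-clockwise (CCW) positive, wrapped to the half-open interval
(−180, 180].  All public functions accept scalars or numpy arrays.

The implicit measure works on the endpoints of a three-stroke aiming movement:
the hand moves out from T1 to the stopper ring (2nd stroke, endpoint ``end2``)
and returns toward the remembered T1 without visual feedback (3rd stroke,
endpoint ``end3``).  If the felt hand position at the end of the 2nd stroke is
rotated relative to the actual one, the return stroke inherits that rotation;
shifting the return line in parallel so its endpoint coincides with T1 turns
the return stroke into an estimate of the felt hand position, and the signed
angle between the outward line and the shifted return line is the implicit
angular deviation α′.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Point2D",
    "StrokeEndpoints",
    "DegenerateGeometryError",
    "wrap_angle",
    "wrap_deviation",
    "direction_from",
    "implicit_angular_deviation",
    "implicit_deviation_from_xy",
    "rotate_about",
    "felt_position_endpoint",
]


class DegenerateGeometryError(ValueError):
    """Raised when a zero-length stroke makes a direction undefined."""


@dataclass(frozen=True)
class Point2D:
    """A point in the digitizer plane (cm)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("Point2D coordinates must be finite")


@dataclass(frozen=True)
class StrokeEndpoints:
    """Endpoints of the 2nd and 3rd strokes relative to the first target T1.

    ``end2`` lies on the 15-cm stopper ring; ``end3`` is wherever the unseen
    return stroke stopped.  Line A runs T1→end2, Line B runs end2→end3.
    """

    t1: Point2D
    end2: Point2D
    end3: Point2D


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the interval (−180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = np.mod(a - 180.0, -360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_deviation(judged, actual):
    """Signed angular deviation of a judged from an actual direction, degrees.

    Positive = counter-clockwise deviation of the judged direction, negative =
    clockwise, wrapped to (−180, 180].
    """
    j = np.asarray(judged, dtype=float)
    a = np.asarray(actual, dtype=float)
    if not (np.all(np.isfinite(j)) and np.all(np.isfinite(a))):
        raise ValueError("angles must be finite")
    return wrap_angle(j - a)


def _direction_xy(dx, dy):
    # 0° at +y, CCW positive: theta = atan2(-x, y)
    return np.degrees(np.arctan2(-np.asarray(dx, float), np.asarray(dy, float)))


def direction_from(origin: Point2D, target: Point2D) -> float:
    """Direction (degrees, 0° = +y axis, CCW positive) of the vector origin→target."""
    dx, dy = target.x - origin.x, target.y - origin.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("coincident points have no direction")
    return float(_direction_xy(dx, dy))


def rotate_about(point: Point2D, center: Point2D, angle_deg: float) -> Point2D:
    """Rotate ``point`` about ``center`` by ``angle_deg`` CCW."""
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    dx, dy = point.x - center.x, point.y - center.y
    return Point2D(center.x + c * dx - s * dy, center.y + s * dx + c * dy)


def implicit_angular_deviation(s: StrokeEndpoints) -> float:
    """Implicit angular deviation α′ (degrees, CCW positive) from stroke endpoints.

    α′ is the signed angle from the direction of Line A (T1→end2) to the
    direction of the reversed return stroke (end2→end3 reversed, i.e. the
    parallel-shifted Line B′ anchored at T1).  A positive α′ means the felt
    hand position was rotated counter-clockwise relative to the actual one.

    Raises :class:`DegenerateGeometryError` if either stroke has zero length.
    """
    a = implicit_deviation_from_xy(
        s.t1.x, s.t1.y, s.end2.x, s.end2.y, s.end3.x, s.end3.y
    )
    if np.isnan(a):
        raise DegenerateGeometryError("zero-length stroke in trial geometry")
    return float(a)


def implicit_deviation_from_xy(t1x, t1y, e2x, e2y, e3x, e3y):
    """Vectorised α′ over coordinate columns; degenerate trials yield NaN."""
    t1x, t1y, e2x, e2y, e3x, e3y = (
        np.asarray(v, dtype=float) for v in (t1x, t1y, e2x, e2y, e3x, e3y)
    )
    ax, ay = e2x - t1x, e2y - t1y  # Line A
    bx, by = e2x - e3x, e2y - e3y  # Line B reversed (end3→end2 == shifted B′)
    deg_a = (ax == 0) & (ay == 0)
    deg_b = (bx == 0) & (by == 0)
    alpha = wrap_angle(_direction_xy(bx, by) - _direction_xy(ax, ay))
    alpha = np.where(deg_a | deg_b, np.nan, alpha)
    return alpha if np.ndim(alpha) else float(alpha)


def felt_position_endpoint(
    t1: Point2D, end2: Point2D, alpha_deg: float, return_fraction: float = 1.0
) -> Point2D:
    """Construct the return-stroke endpoint implied by a felt-hand rotation α.

    The felt hand position is ``end2`` rotated by ``alpha_deg`` CCW about T1;
    the return stroke starts at the actual ``end2`` but aims at T1 *as felt*,
    i.e. along (T1 − felt).  ``return_fraction`` scales the stroke length
    (1.0 = a complete return); α′ recovery is invariant to it.
    """
    if return_fraction <= 0:
        raise ValueError("return_fraction must be positive")
    felt = rotate_about(end2, t1, alpha_deg)
    return Point2D(
        end2.x + return_fraction * (t1.x - felt.x),
        end2.y + return_fraction * (t1.y - felt.y),
    )
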