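"""Landmark coordinates and the three clinical foot angles.

A resolved patch start ``(Sx, Sy)`` maps to its landmark at
``(Sx + 50, Sy + 50)`` — the PoI sits at the exact patch center. Landmarks
are connected into lines, whose slopes feed the two-line angle formula

    tan(theta) = |m2 - m1| / |1 + m1 * m2|

giving the acute angle used for the Calcaneal Inclination Angle (CIA) and
Meary's Angle (MA). The Arch Angle (AA) is graded on intervals that reach
180 degrees and beyond (a collapsed, reflex arch), which an acute-angle
formula cannot express, so AA is measured with a signed directed angle
between the calcaneal and fifth-metatarsal inferior directions:

    AA = 180 - directed_angle(PoI5->PoI6, PoI3->PoI4)

with the sign convention (frozen in :data:`AA_SIGN`) chosen so a raised
arch — apex above the heel-toe chord, i.e. smaller raster ``y`` — gives
AA < 180 and a collapsed arch gives AA >= 180. The phantom generator uses
the same constant, so generated and measured arch angles agree by
construction.

Line definitions (PoI numbering in :mod:`flatfoot.template_matching`):
CIA = angle between the calcaneal inferior line (PoI5->PoI6) and the base
line to the sesamoid (PoI5->PoI9); MA = angle between the talar axis
(PoI7->PoI8) and the first-metatarsal axis (PoI1->PoI2); AA as above.
All coordinates are raster (x right, y down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


__all__ = [
    "FootAngleSet",
    "poi_center",
    "line_slope",
    "acute_angle",
    "directed_angle",
    "measure_cia",
    "measure_ma",
    "measure_aa",
    "measure_all",
    "ANGLE_LINES",
    "AA_SIGN",
    "DegenerateGeometryError",
]

#: Offset from a 100x100 patch start to the landmark at its center.
POI_CENTER_OFFSET = 50

#: Sign applied to the directed angle in the Arch Angle convention. +1 means
#: a raised arch (calcaneal line rotated counter-screen-clockwise into the
#: fifth-metatarsal line, apex at smaller y) yields AA below 180.
AA_SIGN = +1

#: Which landmark pairs form each measured line, frozen in one table so an
#: alternative pairing is a configuration change. Each entry is
#: (line1 = (poi_a, poi_b), line2 = (poi_c, poi_d)).
ANGLE_LINES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "CIA": ((5, 6), (5, 9)),  # calcaneal inferior line vs. sesamoid base line
    "MA": ((7, 8), (1, 2)),  # talar axis vs. first-metatarsal axis
    "AA": ((5, 6), (3, 4)),  # calcaneal vs. fifth-metatarsal inferior lines
}


class DegenerateGeometryError(ValueError):
    """Coincident landmarks or zero direction vectors."""


@dataclass(frozen=True)
class FootAngleSet:
    """The three measured angles in degrees."""

    cia_deg: float
    aa_deg: float
    ma_deg: float

    def as_dict(self) -> dict[str, float]:
        return {"CIA": self.cia_deg, "AA": self.aa_deg, "MA": self.ma_deg}


def poi_center(start: tuple[float, float]) -> tuple[float, float]:
    """Landmark coordinate of a patch: start plus 50 pixels on each axis."""
    return (start[0] + POI_CENTER_OFFSET, start[1] + POI_CENTER_OFFSET)


def line_slope(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Slope m = (y2 - y1) / (x2 - x1); vertical lines return ``math.inf``."""
    dx = p2[0] - p1[0]
    dy = p2[1] - p1[1]
    if dx == 0 and dy == 0:
        raise DegenerateGeometryError(f"coincident points {p1} and {p2} define no line")
    if dx == 0:
        return math.inf
    return dy / dx


def acute_angle(m1: float, m2: float) -> float:
    """Acute angle (degrees, in [0, 90]) between lines of slopes m1 and m2.

    Implements arctan(|m2 - m1| / |1 + m1 m2|); perpendicular slopes
    (1 + m1 m2 == 0) give exactly 90. Vertical lines (infinite slope) are
    folded in through the perpendicular complement: the angle between a
    vertical line and slope m equals 90 minus the inclination of m.
    """
    inf1, inf2 = math.isinf(m1), math.isinf(m2)
    if inf1 and inf2:
        return 0.0
    if inf1 or inf2:
        m = m2 if inf1 else m1
        return 90.0 - math.degrees(math.atan(abs(m)))
    denom = 1.0 + m1 * m2
    if denom == 0.0:
        return 90.0
    return math.degrees(math.atan(abs(m2 - m1) / abs(denom)))


def directed_angle(u: tuple[float, float], v: tuple[float, float]) -> float:
    """Signed angle (degrees, in (-180, 180]) from vector u to vector v.

    Computed as atan2(cross, dot) in raster coordinates, so a positive
    angle is a clockwise turn on screen (y grows downward).
    """
    ux, uy = u
    vx, vy = v
    if (ux == 0 and uy == 0) or (vx == 0 and vy == 0):
        raise DegenerateGeometryError("zero vector has no direction")
    ang = math.degrees(math.atan2(ux * vy - uy * vx, ux * vx + uy * vy))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _point(landmarks: dict[int, tuple[float, float]], poi_id: int, angle: str) -> tuple[float, float]:
    try:
        return landmarks[poi_id]
    except KeyError:
        raise DegenerateGeometryError(
            f"landmark PoI{poi_id} required for {angle} is missing"
        ) from None


def _vector(p: tuple[float, float], q: tuple[float, float], what: str) -> tuple[float, float]:
    v = (q[0] - p[0], q[1] - p[1])
    if v == (0.0, 0.0):
        raise DegenerateGeometryError(f"coincident landmarks for {what}")
    return v


def _as_landmark_dict(landmarks) -> dict[int, tuple[float, float]]:
    if isinstance(landmarks, dict):
        return {int(k): (float(v[0]), float(v[1])) for k, v in landmarks.items()}
    out = {}
    for lm in landmarks:  # sequence of PoILandmark-like objects
        out[int(lm.poi_id)] = (float(lm.point[0]), float(lm.point[1]))
    return out


def measure_cia(landmarks) -> float:
    """Calcaneal Inclination Angle: calcaneal inferior line vs. sesamoid base line."""
    lm = _as_landmark_dict(landmarks)
    (a, b), (c, d) = ANGLE_LINES["CIA"]
    m1 = line_slope(_point(lm, a, "CIA"), _point(lm, b, "CIA"))
    m2 = line_slope(_point(lm, c, "CIA"), _point(lm, d, "CIA"))
    return acute_angle(m1, m2)


def measure_ma(landmarks) -> float:
    """Meary's Angle: talar axis vs. first-metatarsal axis."""
    lm = _as_landmark_dict(landmarks)
    (a, b), (c, d) = ANGLE_LINES["MA"]
    m1 = line_slope(_point(lm, a, "MA"), _point(lm, b, "MA"))
    m2 = line_slope(_point(lm, c, "MA"), _point(lm, d, "MA"))
    return acute_angle(m1, m2)


def measure_aa(landmarks) -> float:
    """Arch Angle in (0, 360): 180 minus the signed calcaneal-to-metatarsal turn.

    Collinear same-direction inferior lines give exactly 180 (a flat
    arch); a raised arch gives AA < 180 and a collapsed (reflex) arch
    AA >= 180.
    """
    lm = _as_landmark_dict(landmarks)
    (a, b), (c, d) = ANGLE_LINES["AA"]
    u = _vector(_point(lm, a, "AA"), _point(lm, b, "AA"), "AA calcaneal line")
    v = _vector(_point(lm, c, "AA"), _point(lm, d, "AA"), "AA fifth-metatarsal line")
    return 180.0 - AA_SIGN * directed_angle(u, v)


def measure_all(landmarks) -> FootAngleSet:
    """Measure CIA, AA and MA from nine landmarks."""
    return FootAngleSet(
        cia_deg=measure_cia(landmarks),
        aa_deg=measure_aa(landmarks),
        ma_deg=measure_ma(landmarks),
    )
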