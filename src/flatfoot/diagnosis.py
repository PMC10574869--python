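"""Severity grading: per-angle interval classification and majority voting.

Each measured angle votes for one of three foot classes — normal, mild
flat foot, moderate flat foot — according to published clinical intervals:

    CIA:  normal 20 <= a <= 30   mild 10 <= a < 20    moderate a < 10
    AA:   normal 150 <= a <= 165 mild 165 < a < 180   moderate a >= 180
    MA:   normal 0 <= a < 4      mild 4 <= a < 15     moderate a >= 15

(The shipped table closes two small gaps in the published intervals:
AA mild spans the whole open interval (165, 180), and MA mild runs up to
but not including the moderate bound at 15.) Values on the healthy side of
every interval — e.g. a cavus-direction CIA above 30 or an AA below 150 —
are outside the method's scope; they are assigned the nearest interval's
class and flagged, never silently graded.

The final diagnosis is the class with the most votes. A three-way split
is broken by per-angle reliability, CIA > MA > AA (CIA grades most
reliably and AA least, mirroring their relative error rates), i.e. the
CIA's vote wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

__all__ = [
    "FootClass",
    "NORMAL",
    "MILD",
    "MODERATE",
    "AngleIntervalTable",
    "DEFAULT_INTERVALS",
    "TIE_BREAK_PRIORITY",
    "classify_angle",
    "majority_vote",
    "DiagnosisResult",
]

# Foot classes, ordered by severity.
NORMAL = "normal"
MILD = "mild"
MODERATE = "moderate"
FOOT_CLASSES: tuple[str, ...] = (NORMAL, MILD, MODERATE)
FootClass = str

#: Tie-break order for a 1-1-1 vote split: the most reliable angle wins.
TIE_BREAK_PRIORITY: tuple[str, ...] = ("CIA", "MA", "AA")


class DiagnosisError(ValueError):
    """Non-finite angles or incomplete vote sets."""


@dataclass(frozen=True)
class AngleIntervalTable:
    """Class boundaries per angle, as half-open interval edges.

    For each angle the table stores ``(severity_direction, edges)`` where
    ``edges = (normal_lo, normal_hi, mild_edge, moderate_edge)`` interpreted
    by :func:`classify_angle`. The default encodes the published intervals
    after gap resolution; an alternative table is a config file away.
    """

    intervals: dict[str, dict[str, tuple[float, float]]]

    def classes_for(self, name: str) -> dict[str, tuple[float, float]]:
        try:
            return self.intervals[name]
        except KeyError:
            raise DiagnosisError(f"no interval row for angle {name!r}") from None

    @classmethod
    def from_yaml(cls, path) -> "AngleIntervalTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            {
                angle: {c: (float(lo), float(hi)) for c, (lo, hi) in rows.items()}
                for angle, rows in raw.items()
            }
        )

    def to_yaml(self, path) -> None:
        raw = {
            angle: {c: [lo, hi] for c, (lo, hi) in rows.items()}
            for angle, rows in self.intervals.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


# Intervals are [lo, hi) half-open except where a closed upper bound is part
# of the published row (CIA normal <= 30, AA normal <= 165 — handled by
# making the neighbouring interval start strictly above).
_INF = math.inf
DEFAULT_INTERVALS = AngleIntervalTable(
    {
        # CIA: severity grows as the angle shrinks.
        "CIA": {
            NORMAL: (20.0, _INF),  # 20 <= a (<= 30 published; above 30 flagged)
            MILD: (10.0, 20.0),
            MODERATE: (-_INF, 10.0),
        },
        # AA: severity grows with the angle.
        "AA": {
            NORMAL: (-_INF, 165.0),  # 150 <= a <= 165 published; below 150 flagged
            MILD: (165.0, 180.0),  # strictly above 165 (normal owns 165)
            MODERATE: (180.0, _INF),
        },
        # MA: severity grows with the angle.
        "MA": {
            NORMAL: (-_INF, 4.0),  # 0 <= a < 4 published; below 0 flagged
            MILD: (4.0, 15.0),
            MODERATE: (15.0, _INF),
        },
    }
)

#: The published in-scope range per angle; values outside raise a flag.
_SCOPE_RANGE = {
    "CIA": (0.0, 30.0),
    "AA": (150.0, 360.0),
    "MA": (0.0, 90.0),
}


def classify_angle(
    name: str,
    value: float,
    table: AngleIntervalTable = DEFAULT_INTERVALS,
) -> tuple[FootClass, str | None]:
    """Grade one angle value; returns ``(foot_class, flag_or_None)``.

    Interval membership per angle follows the table; boundary ownership:
    CIA 20 -> normal, 10 -> mild; AA 165 -> normal, 180 -> moderate;
    MA 4 -> mild, 15 -> moderate. Out-of-scope values (healthy-side
    extremes) map to the class of the nearest interval and carry a flag.
    """
    if not math.isfinite(value):
        raise DiagnosisError(f"non-finite {name} value: {value!r}")
    rows = table.classes_for(name)
    cls = None
    if name == "AA":
        # AA 165 belongs to normal although normal's stored edge is open-ended
        # below: scan in severity order, upper edges inclusive for normal only.
        if value <= rows[NORMAL][1]:
            cls = NORMAL
        elif value < rows[MILD][1]:
            cls = MILD
        else:
            cls = MODERATE
    else:
        for c in FOOT_CLASSES:
            lo, hi = rows[c]
            if lo <= value < hi:
                cls = c
                break
    if cls is None:  # pragma: no cover - table rows always partition the line
        raise DiagnosisError(f"value {value} not covered by any {name} interval")
    flag = None
    lo, hi = _SCOPE_RANGE[name]
    if not lo <= value <= hi:
        flag = (
            f"{name}={value:g} lies outside the graded range [{lo:g}, {hi:g}]; "
            f"assigned nearest class {cls!r}"
        )
    return cls, flag


@dataclass(frozen=True)
class DiagnosisResult:
    """Votes, tallies and the final majority-vote foot class."""

    votes: dict[str, FootClass]
    counts: dict[FootClass, int]
    final: FootClass
    flags: tuple[str, ...] = ()
    tie_break_used: bool = False


def majority_vote(
    votes: dict[str, FootClass],
    flags: tuple[str, ...] = (),
    priority: tuple[str, ...] = TIE_BREAK_PRIORITY,
) -> DiagnosisResult:
    """Combine the three per-angle votes into the final estimation.

    The class with the maximum tally wins. With one vote per class
    (1-1-1), the vote of the highest-priority angle is taken. Tallies are
    literal vote counts.
    """
    missing = [a for a in ("CIA", "AA", "MA") if a not in votes]
    if missing:
        raise DiagnosisError(f"incomplete measurement; missing angle votes: {missing}")
    counts = {c: 0 for c in FOOT_CLASSES}
    for v in votes.values():
        if v not in counts:
            raise DiagnosisError(f"unknown foot class in votes: {v!r}")
        counts[v] += 1
    best = max(counts.values())
    winners = [c for c in FOOT_CLASSES if counts[c] == best]
    tie_break = len(winners) > 1
    if tie_break:
        for angle in priority:
            if votes[angle] in winners:
                final = votes[angle]
                break
    else:
        final = winners[0]
    return DiagnosisResult(
        votes=dict(votes),
        counts=counts,
        final=final,
        flags=tuple(flags),
        tie_break_used=tie_break,
    )


def diagnose_angles(angles, table: AngleIntervalTable = DEFAULT_INTERVALS) -> DiagnosisResult:
    """Grade a :class:`~flatfoot.angle_geometry.FootAngleSet` end to end."""
    votes: dict[str, FootClass] = {}
    flags: list[str] = []
    for name, value in angles.as_dict().items():
        cls, flag = classify_angle(name, value, table)
        votes[name] = cls
        if flag:
            flags.append(flag)
    return majority_vote(votes, flags=tuple(flags))
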