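"""Per-egg clutch-arrangement metrics and before/after change scores.

A photographed clutch is annotated with one point per egg pole (blunt and
sharp) plus the nest-cup center.  From these, four geometric features
describe the arrangement of the clutch:

* **blunt pole distance** — Euclidean distance from the nest center to the
  egg's blunt pole (px);
* **blunt pole angle** — polar angle of the vector from the nest center to
  the blunt pole, measured counter-clockwise from the positive x axis,
  directional data with period 360 deg;
* **blunt pole orientation** — orientation of the egg's long axis (the line
  through both poles), axial data with period 180 deg;
* **adjacent angles** — for eggs ordered clockwise around the cup, the axial
  angle from the long axis of egg N to that of egg N+1 (cyclic, so an
  N-egg clutch has N adjacent angles).

How much a manipulation changed the arrangement is summarised per nest by a
two-photograph standard deviation of each metric: for every host egg the SD
over its {before, after} pair — the ordinary two-point sample SD
``|delta| / sqrt(2)`` for distances, and the circular SD
``sqrt(-2 ln R)`` (Mardia) for directional angles, with the doubled-angle
half-period analogue for axial data — then averaged over host eggs.

Coordinate convention: annotation files and rendered images use image
coordinates (origin top-left, y down).  Angle computations flip to the
mathematical y-up frame when ``y_down=True`` so that "positive x axis" and
"counter-clockwise" keep their conventional meaning.  Plain (math, y-up)
points can be used directly with ``y_down=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import (
    InsufficientEggsError,
    InvalidInputError,
    PairingError,
    UndefinedAngleError,
)

Point = tuple[float, float]

PHASES = ("before", "after")

__all__ = [
    "EggAnnotation",
    "ClutchObservation",
    "ArrangementMetrics",
    "ArrangementChange",
    "blunt_pole_distance",
    "blunt_pole_angle",
    "blunt_pole_orientation",
    "clockwise_order",
    "adjacent_angles",
    "arrangement_metrics",
    "arrangement_change",
    "two_point_sd_linear",
    "two_point_sd_circular",
]


def _check_finite(*points: Point) -> None:
    for p in points:
        if len(p) != 2 or not all(math.isfinite(float(v)) for v in p):
            raise InvalidInputError(f"coordinates must be finite 2-D points, got {p!r}")


@dataclass(frozen=True)
class EggAnnotation:
    """One annotated egg: blunt- and sharp-pole image points.

    ``is_model_egg`` marks the experimentally added foreign egg; model eggs
    are rendered in masks but excluded from paired before/after metrics.
    """

    egg_id: str
    blunt_pole: Point
    sharp_pole: Point
    is_model_egg: bool = False

    def __post_init__(self) -> None:
        _check_finite(self.blunt_pole, self.sharp_pole)
        object.__setattr__(self, "blunt_pole", (float(self.blunt_pole[0]), float(self.blunt_pole[1])))
        object.__setattr__(self, "sharp_pole", (float(self.sharp_pole[0]), float(self.sharp_pole[1])))
        if self.blunt_pole == self.sharp_pole:
            raise InvalidInputError(f"egg {self.egg_id!r}: blunt and sharp poles coincide")

    @property
    def center(self) -> Point:
        bx, by = self.blunt_pole
        sx, sy = self.sharp_pole
        return ((bx + sx) / 2.0, (by + sy) / 2.0)

    @property
    def length(self) -> float:
        """Pole-to-pole (long axis) length in the annotation units."""
        return math.dist(self.blunt_pole, self.sharp_pole)


@dataclass
class ClutchObservation:
    """One photographed clutch state (a nest at a single phase).

    ``eggs`` is the ordered list of annotations; host clutches in this
    population hold 4 or 5 eggs (checked by :meth:`validate`, not by the
    constructor, so that small synthetic clutches remain usable in
    analyses of individual metrics).
    """

    nest_id: str
    phase: str
    nest_center: Point
    eggs: list[EggAnnotation]
    px_per_mm: float | None = None
    y_down: bool = True
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise InvalidInputError(f"phase must be one of {PHASES}, got {self.phase!r}")
        _check_finite(self.nest_center)
        ids = [e.egg_id for e in self.eggs]
        if len(ids) != len(set(ids)):
            raise InvalidInputError(f"nest {self.nest_id!r}: duplicate egg ids")

    @property
    def host_eggs(self) -> list[EggAnnotation]:
        return [e for e in self.eggs if not e.is_model_egg]

    @property
    def model_eggs(self) -> list[EggAnnotation]:
        return [e for e in self.eggs if e.is_model_egg]

    def validate(self) -> None:
        """Check the field invariants for a real observation."""
        n = len(self.host_eggs)
        if not 4 <= n <= 5:
            raise InvalidInputError(f"nest {self.nest_id!r}: {n} host eggs (expected 4-5)")
        if len(self.model_eggs) > 1:
            raise InvalidInputError(f"nest {self.nest_id!r}: more than one model egg")


def _delta(origin: Point, tip: Point, y_down: bool) -> tuple[float, float]:
    dx = tip[0] - origin[0]
    dy = tip[1] - origin[1]
    return (dx, -dy) if y_down else (dx, dy)


def blunt_pole_distance(egg: EggAnnotation, center: Point) -> float:
    """Euclidean distance from the nest center to the egg's blunt pole."""
    _check_finite(center)
    return math.dist(egg.blunt_pole, center)


def blunt_pole_angle(egg: EggAnnotation, center: Point, y_down: bool = False) -> float:
    """Polar angle (deg in [0, 360)) of the vector center -> blunt pole."""
    _check_finite(center)
    dx, dy = _delta(center, egg.blunt_pole, y_down)
    if dx == 0.0 and dy == 0.0:
        raise UndefinedAngleError(f"egg {egg.egg_id!r}: blunt pole coincides with nest center")
    return math.degrees(math.atan2(dy, dx)) % 360.0


def blunt_pole_orientation(egg: EggAnnotation, y_down: bool = False) -> float:
    """Long-axis orientation (axial deg in [0, 180))."""
    dx, dy = _delta(egg.sharp_pole, egg.blunt_pole, y_down)
    if dx == 0.0 and dy == 0.0:  # unreachable through the constructor; kept for raw use
        raise UndefinedAngleError(f"egg {egg.egg_id!r}: degenerate long axis")
    return math.degrees(math.atan2(dy, dx)) % 180.0


def clockwise_order(obs: ClutchObservation, eggs: list[EggAnnotation] | None = None) -> list[EggAnnotation]:
    """Eggs sorted clockwise (as seen in the displayed image) around the cup.

    Clockwise on screen corresponds to decreasing mathematical polar angle,
    so eggs are ordered by descending blunt-pole angle; ties are broken by
    blunt-pole distance, then egg id.
    """
    eggs = obs.eggs if eggs is None else eggs
    return sorted(
        eggs,
        key=lambda e: (
            -blunt_pole_angle(e, obs.nest_center, obs.y_down),
            blunt_pole_distance(e, obs.nest_center),
            e.egg_id,
        ),
    )


def _adjacent_from_sequence(seq: list[EggAnnotation], y_down: bool) -> np.ndarray:
    orient = [blunt_pole_orientation(e, y_down) for e in seq]
    n = len(orient)
    return np.array([(orient[(k + 1) % n] - orient[k]) % 180.0 for k in range(n)])


def adjacent_angles(obs: ClutchObservation) -> np.ndarray:
    """Axial angles (deg in [0, 180)) between long axes of adjacent egg pairs.

    Eggs are taken in clockwise order; the sequence is cyclic, so the last
    egg pairs with the first and an N-egg clutch yields N angles.
    """
    if len(obs.eggs) < 2:
        raise InsufficientEggsError(f"nest {obs.nest_id!r}: need >= 2 eggs for adjacent angles")
    return _adjacent_from_sequence(clockwise_order(obs), obs.y_down)


@dataclass
class ArrangementMetrics:
    """The four per-egg metric families for one observation.

    Arrays are aligned with ``egg_ids`` (clockwise order); ``adjacent_angle``
    entry k is the angle from egg k's long axis to egg k+1's (cyclic).
    """

    nest_id: str
    phase: str
    egg_ids: list[str]
    blunt_pole_distance: np.ndarray
    blunt_pole_angle: np.ndarray
    blunt_pole_orientation: np.ndarray
    adjacent_angle: np.ndarray


def arrangement_metrics(obs: ClutchObservation) -> ArrangementMetrics:
    """Compute all four metric families for one clutch observation."""
    seq = clockwise_order(obs)
    if len(seq) < 2:
        raise InsufficientEggsError(f"nest {obs.nest_id!r}: need >= 2 eggs")
    return ArrangementMetrics(
        nest_id=obs.nest_id,
        phase=obs.phase,
        egg_ids=[e.egg_id for e in seq],
        blunt_pole_distance=np.array([blunt_pole_distance(e, obs.nest_center) for e in seq]),
        blunt_pole_angle=np.array([blunt_pole_angle(e, obs.nest_center, obs.y_down) for e in seq]),
        blunt_pole_orientation=np.array([blunt_pole_orientation(e, obs.y_down) for e in seq]),
        adjacent_angle=_adjacent_from_sequence(seq, obs.y_down),
    )


# --- two-point standard deviations -------------------------------------------

_MIN_RESULTANT = 1e-12  # caps the circular SD for exactly antipodal pairs


def two_point_sd_linear(a: float, b: float) -> float:
    """Sample SD (ddof=1) of the two values {a, b}: |a - b| / sqrt(2)."""
    return abs(a - b) / math.sqrt(2.0)


def two_point_sd_circular(a: float, b: float, period: float = 360.0) -> float:
    """Circular SD (deg) of two angles with the given period.

    Angles are rescaled to the full circle (axial data are doubled), the
    Mardia circular SD ``sqrt(-2 ln R)`` of the two unit vectors is taken,
    and the result is scaled back.  For a two-point sample the mean
    resultant length is ``R = |cos(delta/2)|`` with ``delta`` the wrapped
    difference.  Antipodal pairs (R -> 0) are capped at a large finite SD.
    """
    f = 360.0 / period
    d = math.radians(((a - b) * f) % 360.0)
    r = abs(math.cos(d / 2.0))
    r = max(r, _MIN_RESULTANT)
    return math.degrees(math.sqrt(-2.0 * math.log(r))) / f


@dataclass
class ArrangementChange:
    """Nest-level before/after variability, one SD score per metric."""

    nest_id: str
    sd_blunt_pole_distance: float
    sd_blunt_pole_angle: float
    sd_blunt_pole_orientation: float
    sd_adjacent_angle: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sd_blunt_pole_distance": self.sd_blunt_pole_distance,
            "sd_blunt_pole_angle": self.sd_blunt_pole_angle,
            "sd_blunt_pole_orientation": self.sd_blunt_pole_orientation,
            "sd_adjacent_angle": self.sd_adjacent_angle,
        }


def _pair_host_eggs(
    before: ClutchObservation, after: ClutchObservation
) -> list[tuple[EggAnnotation, EggAnnotation]]:
    """Match host eggs across phases: by id when ids agree, else by
    nearest-centroid assignment (Hungarian algorithm)."""
    hb, ha = before.host_eggs, after.host_eggs
    if len(hb) != len(ha):
        raise PairingError(
            f"nest {before.nest_id!r}: {len(hb)} host eggs before vs {len(ha)} after"
        )
    ids_b = {e.egg_id for e in hb}
    ids_a = {e.egg_id for e in ha}
    if ids_b == ids_a:
        by_id = {e.egg_id: e for e in ha}
        return [(e, by_id[e.egg_id]) for e in hb]
    cost = np.array([[math.dist(b.center, a.center) for a in ha] for b in hb])
    rows, cols = linear_sum_assignment(cost)
    return [(hb[i], ha[j]) for i, j in zip(rows, cols)]


def arrangement_change(before: ClutchObservation, after: ClutchObservation) -> ArrangementChange:
    """Two-photograph change scores for one nest.

    For each host egg (model eggs have no "before" state and are excluded)
    the two-point SD of each metric over its before/after pair is taken,
    then averaged over eggs.  Adjacent angles are paired per egg pair: the
    clockwise sequence of the *before* observation is fixed and the same
    cyclic sequence of matched eggs is used in the after phase, so each
    before-pair compares against the same two eggs after manipulation.
    """
    if before.nest_id != after.nest_id:
        raise PairingError(f"nest ids differ: {before.nest_id!r} vs {after.nest_id!r}")
    pairs = _pair_host_eggs(before, after)
    if len(pairs) < 2:
        raise InsufficientEggsError(f"nest {before.nest_id!r}: need >= 2 paired host eggs")

    yd_b, yd_a = before.y_down, after.y_down
    sd_dist = [
        two_point_sd_linear(
            blunt_pole_distance(b, before.nest_center), blunt_pole_distance(a, after.nest_center)
        )
        for b, a in pairs
    ]
    sd_ang = [
        two_point_sd_circular(
            blunt_pole_angle(b, before.nest_center, yd_b),
            blunt_pole_angle(a, after.nest_center, yd_a),
            period=360.0,
        )
        for b, a in pairs
    ]
    sd_ori = [
        two_point_sd_circular(
            blunt_pole_orientation(b, yd_b), blunt_pole_orientation(a, yd_a), period=180.0
        )
        for b, a in pairs
    ]

    # adjacent angles: fix the before-phase clockwise sequence and reuse it
    # (through the matching) for the after phase
    match = {b.egg_id: a for b, a in pairs}
    seq_b = clockwise_order(before, [b for b, _ in pairs])
    seq_a = [match[e.egg_id] for e in seq_b]
    adj_b = _adjacent_from_sequence(seq_b, yd_b)
    adj_a = _adjacent_from_sequence(seq_a, yd_a)
    sd_adj = [two_point_sd_circular(x, y, period=180.0) for x, y in zip(adj_b, adj_a)]

    return ArrangementChange(
        nest_id=before.nest_id,
        sd_blunt_pole_distance=float(np.mean(sd_dist)),
        sd_blunt_pole_angle=float(np.mean(sd_ang)),
        sd_blunt_pole_orientation=float(np.mean(sd_ori)),
        sd_adjacent_angle=float(np.mean(sd_adj)),
    )
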