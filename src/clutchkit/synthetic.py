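"""Synthetic clutches, treatments, masks and behavioural outcomes.

Generates the full data that the measurement and analysis stages consume,
with the statistical structure of the three-treatment parasitism
experiment:

* **clutch geometry** — 4 or 5 host-egg ellipses placed without overlap in
  a circular nest cup, blunt poles biased outward (long axes roughly
  radial, sharp pole toward the cup center);
* **treatments** — *control*: each egg perturbed by photographic jitter
  only; *constant*: jitter plus handling noise, and one foreign model egg
  inserted at the cup perimeter, pushing aside any host egg in its way;
  *rearranged*: host positions and orientations redrawn (scaled by a
  shuffle intensity), then the model egg added — emulating a vigorous
  hand-shuffle of the clutch;
* **masks** — binary silhouettes rasterized from the egg ellipses;
* **behavioural outcomes** — desertion independent of treatment; for
  non-deserted parasitized nests, ejection from a logistic model with a
  treatment effect; for ejectors, latency (days, same-day = 0) from a
  negative-binomial model with a clutch-size effect, resampled into the
  0-6 day monitoring window.

All randomness flows through ``numpy.random.Generator`` seeds, so every
stage is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from shapely import affinity
from shapely.geometry import Point as ShapelyPoint

from .dissimilarity import ClutchMask
from .errors import (
    ConfigurationError,
    EmptyMaskError,
    FrameSizeError,
    InvalidInputError,
    InvalidParameterError,
    PlacementError,
)
from .geometry import ClutchObservation, EggAnnotation
from .stats import NestOutcome, PARASITIZED, TREATMENTS

__all__ = [
    "GeneratorConfig",
    "BehaviorConfig",
    "generate_clutch",
    "apply_treatment",
    "render_mask",
    "simulate_outcomes",
]


@dataclass
class GeneratorConfig:
    """Geometry and noise parameters of the synthetic experiment.

    Group sizes default to the field design (19 control, 30 constant,
    30 rearranged).  The model egg measures 22.40 x 16.89 mm; host eggs
    default to 29 x 21 mm, typical blackbird dimensions.  ``jitter_sd_mm``
    is the photographic/relocation noise every nest experiences between the
    two photographs; ``handling_sd_mm`` is the extra disturbance of
    physically inserting the model egg (parasitized treatments only).
    ``shuffle_intensity`` in [0, 1] scales how far the rearranged treatment
    moves host eggs toward a freshly drawn layout (1 = full redraw).
    """

    n_control: int = 19
    n_constant: int = 30
    n_rearranged: int = 30
    clutch_size_probs: dict = field(default_factory=lambda: {4: 0.5, 5: 0.5})
    cup_radius_mm: float = 50.0
    host_egg_length_mm: float = 29.0
    host_egg_breadth_mm: float = 21.0
    model_egg_length_mm: float = 22.40
    model_egg_breadth_mm: float = 16.89
    jitter_sd_mm: float = 1.0
    jitter_orient_sd_deg: float = 3.0
    handling_sd_mm: float = 0.8
    handling_orient_sd_deg: float = 4.0
    shuffle_intensity: float = 1.0
    px_per_mm: float = 2.0
    frame_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        lengths = (
            self.cup_radius_mm, self.host_egg_length_mm, self.host_egg_breadth_mm,
            self.model_egg_length_mm, self.model_egg_breadth_mm, self.px_per_mm,
        )
        if any(v <= 0 for v in lengths):
            raise ConfigurationError("all lengths and scales must be positive")
        probs = list(self.clutch_size_probs.values())
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9) or any(p < 0 for p in probs):
            raise ConfigurationError("clutch size probabilities must be >= 0 and sum to 1")
        if not 0.0 <= self.shuffle_intensity <= 1.0:
            raise ConfigurationError("shuffle_intensity must lie in [0, 1]")

    @property
    def frame_side_px(self) -> int:
        return int(round(2.0 * (self.cup_radius_mm + self.frame_margin_mm) * self.px_per_mm))


@dataclass
class BehaviorConfig:
    """Parameters of the behavioural outcome model.

    Defaults encode the observed study conditions: a treatment-independent
    desertion probability near the pooled observed rate (10/79), ejection
    log-odds with a constant-group baseline of logit(0.79) and a rearranged
    effect of 0.74, and a latency model (log link) whose clutch-size-5
    effect (-1.12) makes larger clutches eject faster and whose
    rearranged-treatment effect (0.74) mirrors the study's retained —
    though non-significant — latency term.  Latency draws are resampled
    into the 0-6 day monitoring window.
    """

    desertion_prob: float = 0.127
    ejection_logit_intercept: float = 1.34
    ejection_logit_treatment: float = 0.74
    latency_log_intercept: float = 0.37
    latency_log_treatment: float = 0.74
    latency_log_clutch5: float = -1.12
    latency_dispersion: float = 0.5
    max_latency_days: int = 6
    nest_age_mean: float = 4.65
    nest_age_sd: float = 3.7
    season_length_days: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.desertion_prob <= 1.0:
            raise ConfigurationError("desertion_prob must lie in [0, 1]")
        if self.latency_dispersion < 0:
            raise ConfigurationError("latency_dispersion must be >= 0")
        if self.max_latency_days < 0:
            raise ConfigurationError("max_latency_days must be >= 0")


# --- internal mm-frame egg representation ------------------------------------


_UNIT_CIRCLE = ShapelyPoint(0.0, 0.0).buffer(1.0, quad_segs=24)


@dataclass
class _Egg:
    """Egg ellipse in the nest frame (mm, y up, origin at the cup center).
    ``theta`` is the direction (deg) from the egg center toward the blunt
    pole along the long axis."""

    egg_id: str
    x: float
    y: float
    theta: float
    a: float  # semi-major, mm
    b: float  # semi-minor, mm
    is_model: bool = False

    def polygon(self):
        ell = affinity.scale(_UNIT_CIRCLE, self.a, self.b)
        ell = affinity.rotate(ell, self.theta, origin=(0.0, 0.0))
        return affinity.translate(ell, self.x, self.y)


def _overlap_area(e1: _Egg, e2: _Egg) -> float:
    if math.dist((e1.x, e1.y), (e2.x, e2.y)) > e1.a + e2.a:
        return 0.0
    return e1.polygon().intersection(e2.polygon()).area


@lru_cache(maxsize=8)
def _cup_polygon(cup_radius: float):
    return ShapelyPoint(0.0, 0.0).buffer(cup_radius, quad_segs=48)


def _inside_cup(egg: _Egg, cup_radius: float) -> bool:
    return egg.polygon().within(_cup_polygon(cup_radius))


def _clip_center(egg: _Egg, r_max: float) -> None:
    r = math.hypot(egg.x, egg.y)
    if r > r_max:
        egg.x *= r_max / r
        egg.y *= r_max / r


def _obs_from_eggs(
    eggs: list[_Egg], nest_id: str, phase: str, config: GeneratorConfig, treatment: str | None = None
) -> ClutchObservation:
    ppm = config.px_per_mm
    half = config.cup_radius_mm + config.frame_margin_mm

    def to_px(x: float, y: float) -> tuple[float, float]:
        return ((x + half) * ppm, (half - y) * ppm)

    annos = []
    for e in eggs:
        ux, uy = math.cos(math.radians(e.theta)), math.sin(math.radians(e.theta))
        annos.append(
            EggAnnotation(
                egg_id=e.egg_id,
                blunt_pole=to_px(e.x + e.a * ux, e.y + e.a * uy),
                sharp_pole=to_px(e.x - e.a * ux, e.y - e.a * uy),
                is_model_egg=e.is_model,
            )
        )
    return ClutchObservation(
        nest_id=nest_id,
        phase=phase,
        nest_center=to_px(0.0, 0.0),
        eggs=annos,
        px_per_mm=ppm,
        y_down=True,
        treatment=treatment,
    )


def _eggs_from_obs(obs: ClutchObservation, config: GeneratorConfig) -> list[_Egg]:
    ppm = obs.px_per_mm or config.px_per_mm
    half = config.cup_radius_mm + config.frame_margin_mm

    def to_mm(px: float, py: float) -> tuple[float, float]:
        return (px / ppm - half, half - py / ppm)

    eggs = []
    for anno in obs.eggs:
        bx, by = to_mm(*anno.blunt_pole)
        sx, sy = to_mm(*anno.sharp_pole)
        a = math.dist((bx, by), (sx, sy)) / 2.0
        b = (config.model_egg_breadth_mm if anno.is_model_egg else config.host_egg_breadth_mm) / 2.0
        eggs.append(
            _Egg(
                egg_id=anno.egg_id,
                x=(bx + sx) / 2.0,
                y=(by + sy) / 2.0,
                theta=math.degrees(math.atan2(by - sy, bx - sx)),
                a=a,
                b=b,
                is_model=anno.is_model_egg,
            )
        )
    return eggs


def _draw_layout(
    rng: np.random.Generator, config: GeneratorConfig, n: int, egg_ids: list[str] | None = None
) -> list[_Egg]:
    """Place ``n`` host eggs without overlap, blunt poles outward-biased."""
    a = config.host_egg_length_mm / 2.0
    b = config.host_egg_breadth_mm / 2.0
    r_eff = config.cup_radius_mm - a
    if r_eff <= 0:
        raise ConfigurationError("host eggs do not fit in the cup")
    ids = egg_ids or [f"egg{i + 1}" for i in range(n)]
    for _ in range(60):
        base = rng.uniform(0.0, 360.0)
        eggs: list[_Egg] = []
        for k in range(n):
            for _ in range(200):
                phi = base + 360.0 * k / n + rng.normal(0.0, 12.0)
                rc = rng.uniform(0.35, 0.75) * r_eff
                theta = phi + rng.normal(0.0, 18.0)
                cand = _Egg(
                    ids[k], rc * math.cos(math.radians(phi)), rc * math.sin(math.radians(phi)),
                    theta, a, b,
                )
                if _inside_cup(cand, config.cup_radius_mm) and all(
                    _overlap_area(cand, o) < 1e-9 for o in eggs
                ):
                    eggs.append(cand)
                    break
            else:
                break
        if len(eggs) == n:
            return eggs
    raise PlacementError(f"could not place {n} eggs without overlap")


def generate_clutch(
    config: GeneratorConfig,
    clutch_size: int | None = None,
    seed=None,
    nest_id: str = "nest",
) -> ClutchObservation:
    """Draw one pre-manipulation ("before") clutch observation."""
    rng = np.random.default_rng(seed)
    if clutch_size is None:
        sizes = list(config.clutch_size_probs)
        probs = [config.clutch_size_probs[s] for s in sizes]
        clutch_size = int(rng.choice(sizes, p=probs))
    eggs = _draw_layout(rng, config, clutch_size)
    return _obs_from_eggs(eggs, nest_id, "before", config)


def _jitter(
    eggs: list[_Egg], rng: np.random.Generator, pos_sd: float, orient_sd: float,
    config: GeneratorConfig,
) -> list[_Egg]:
    out = []
    r_eff = config.cup_radius_mm - config.host_egg_length_mm / 2.0
    for e in eggs:
        j = replace(
            e,
            x=e.x + rng.normal(0.0, pos_sd),
            y=e.y + rng.normal(0.0, pos_sd),
            theta=e.theta + rng.normal(0.0, orient_sd),
        )
        _clip_center(j, r_eff)
        out.append(j)
    return out


def _separate(eggs: list[_Egg], config: GeneratorConfig, iterations: int = 30) -> None:
    """Relax small post-jitter overlaps by nudging eggs apart (in place).
    Eggs that already do not overlap are never moved."""
    r_eff = config.cup_radius_mm - config.host_egg_length_mm / 2.0
    for _ in range(iterations):
        moved = False
        for i in range(len(eggs)):
            for j in range(i + 1, len(eggs)):
                if _overlap_area(eggs[i], eggs[j]) > 1e-6:
                    dx = eggs[i].x - eggs[j].x
                    dy = eggs[i].y - eggs[j].y
                    norm = math.hypot(dx, dy) or 1.0
                    step = 0.4
                    eggs[i].x += step * dx / norm
                    eggs[i].y += step * dy / norm
                    eggs[j].x -= step * dx / norm
                    eggs[j].y -= step * dy / norm
                    _clip_center(eggs[i], r_eff)
                    _clip_center(eggs[j], r_eff)
                    moved = True
        if not moved:
            return


def _insert_model_egg(
    hosts: list[_Egg], rng: np.random.Generator, config: GeneratorConfig
) -> list[_Egg]:
    """Add the foreign model egg at the cup perimeter, pushing aside any
    host egg it displaces (the physical act of parasitism)."""
    a_m = config.model_egg_length_mm / 2.0
    b_m = config.model_egg_breadth_mm / 2.0
    r_m = config.cup_radius_mm - a_m - 1.0
    best, best_overlap = None, math.inf
    for _ in range(16):
        phi = rng.uniform(0.0, 360.0)
        # edge-laid eggs tend to lie tangentially along the cup wall
        theta = phi + 90.0 + rng.normal(0.0, 10.0)
        cand = _Egg(
            "model", r_m * math.cos(math.radians(phi)), r_m * math.sin(math.radians(phi)),
            theta, a_m, b_m, is_model=True,
        )
        total = sum(_overlap_area(cand, h) for h in hosts)
        if total < best_overlap:
            best, best_overlap = cand, total
        if total == 0.0:
            break
    model = best
    r_eff = config.cup_radius_mm - config.host_egg_length_mm / 2.0
    for _ in range(60):
        collided = False
        for h in hosts:
            if _overlap_area(model, h) > 1e-6:
                dx, dy = h.x - model.x, h.y - model.y
                norm = math.hypot(dx, dy) or 1.0
                h.x += 0.8 * dx / norm
                h.y += 0.8 * dy / norm
                _clip_center(h, r_eff)
                collided = True
        if collided:
            _separate(hosts, config, iterations=5)
        else:
            break
    return hosts + [model]


def _interp_angle(old: float, new: float, s: float) -> float:
    d = (new - old + 180.0) % 360.0 - 180.0
    return old + s * d


def apply_treatment(
    before: ClutchObservation,
    treatment: str,
    config: GeneratorConfig,
    seed=None,
) -> ClutchObservation:
    """Produce the post-manipulation ("after") observation for one nest."""
    if treatment not in TREATMENTS:
        raise InvalidParameterError(f"unknown treatment {treatment!r}")
    if before.model_eggs:
        raise InvalidInputError("the before observation already contains a model egg")
    rng = np.random.default_rng(seed)
    hosts = [e for e in _eggs_from_obs(before, config) if not e.is_model]

    if treatment == "control":
        eggs = _jitter(hosts, rng, config.jitter_sd_mm, config.jitter_orient_sd_deg, config)
        _separate(eggs, config)
        return _obs_from_eggs(eggs, before.nest_id, "after", config, treatment)

    if treatment == "constant":
        pos_sd = math.hypot(config.jitter_sd_mm, config.handling_sd_mm)
        ori_sd = math.hypot(config.jitter_orient_sd_deg, config.handling_orient_sd_deg)
        eggs = _jitter(hosts, rng, pos_sd, ori_sd, config)
        _separate(eggs, config)
    else:  # rearranged
        s = config.shuffle_intensity
        fresh = _draw_layout(rng, config, len(hosts), egg_ids=[h.egg_id for h in hosts])
        perm = rng.permutation(len(hosts))
        eggs = []
        for k, h in enumerate(hosts):
            f = fresh[perm[k]]
            eggs.append(
                replace(
                    h,
                    x=(1.0 - s) * h.x + s * f.x,
                    y=(1.0 - s) * h.y + s * f.y,
                    theta=_interp_angle(h.theta, f.theta, s),
                )
            )
        eggs = _jitter(eggs, rng, config.jitter_sd_mm, config.jitter_orient_sd_deg, config)
        _separate(eggs, config)

    eggs = _insert_model_egg(eggs, rng, config)
    return _obs_from_eggs(eggs, before.nest_id, "after", config, treatment)


def render_mask(obs: ClutchObservation, config: GeneratorConfig) -> ClutchMask:
    """Rasterize a clutch observation into a binary silhouette mask."""
    if not obs.eggs:
        raise EmptyMaskError(f"nest {obs.nest_id!r}: no eggs to render")
    ppm = obs.px_per_mm or config.px_per_mm
    side = config.frame_side_px
    canvas = np.zeros((side, side), dtype=bool)
    for anno in obs.eggs:
        bx, by = anno.blunt_pole
        sx, sy = anno.sharp_pole
        cx, cy = (bx + sx) / 2.0, (by + sy) / 2.0
        a_px = math.dist((bx, by), (sx, sy)) / 2.0
        b_mm = config.model_egg_breadth_mm if anno.is_model_egg else config.host_egg_breadth_mm
        b_px = b_mm / 2.0 * ppm
        if not (
            a_px <= cx <= side - 1 - a_px and a_px <= cy <= side - 1 - a_px
        ):
            raise FrameSizeError(f"nest {obs.nest_id!r}: egg {anno.egg_id!r} outside the frame")
        # implicit ellipse equation in image coordinates, on the egg bbox only
        theta = math.atan2(by - sy, bx - sx)
        ct, st = math.cos(theta), math.sin(theta)
        r = max(a_px, b_px) + 1.0
        x0, x1 = max(0, int(cx - r)), min(side, int(cx + r) + 2)
        y0, y1 = max(0, int(cy - r)), min(side, int(cy + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        u = (dx * ct + dy * st) / a_px
        v = (-dx * st + dy * ct) / b_px
        canvas[y0:y1, x0:x1] |= u * u + v * v <= 1.0
    return ClutchMask(canvas, nest_id=obs.nest_id, phase=obs.phase)


def _nb_draw(rng: np.random.Generator, mu: float, alpha: float, cap: int) -> int:
    """Negative-binomial (gamma-Poisson) draw resampled into [0, cap]."""
    for _ in range(1000):
        lam = rng.gamma(1.0 / alpha, alpha * mu) if alpha > 0 else mu
        y = int(rng.poisson(lam))
        if y <= cap:
            return y
    return cap


def simulate_outcomes(assignments, behavior: BehaviorConfig, seed=None) -> list[NestOutcome]:
    """Simulate behavioural outcomes for assigned nests.

    ``assignments`` is an iterable of ``(nest_id, treatment, clutch_size)``
    tuples.  Control nests can only desert or accept; parasitized nests
    desert, eject or accept.  Covariates (nest age, laying date) are drawn
    from the population distributions and carry no effect on behaviour.
    """
    rng = np.random.default_rng(seed)
    out = []
    for nest_id, treatment, clutch_size in assignments:
        if treatment not in TREATMENTS:
            raise InvalidParameterError(f"unknown treatment {treatment!r}")
        nest_age = max(0.0, rng.normal(behavior.nest_age_mean, behavior.nest_age_sd))
        laying = rng.uniform(0.0, behavior.season_length_days)
        latency = None
        if rng.random() < behavior.desertion_prob:
            response = "desert"
        elif treatment == "control":
            response = "accept"
        else:
            logit = behavior.ejection_logit_intercept + behavior.ejection_logit_treatment * (
                treatment == "rearranged"
            )
            if rng.random() < 1.0 / (1.0 + math.exp(-logit)):
                response = "eject"
                mu = math.exp(
                    behavior.latency_log_intercept
                    + behavior.latency_log_treatment * (treatment == "rearranged")
                    + behavior.latency_log_clutch5 * (clutch_size == 5)
                )
                latency = _nb_draw(
                    rng, mu, behavior.latency_dispersion, behavior.max_latency_days
                )
            else:
                response = "accept"
        out.append(
            NestOutcome(
                nest_id=str(nest_id),
                treatment=treatment,
                response=response,
                latency_days=latency,
                clutch_size=int(clutch_size),
                nest_age_days=nest_age,
                laying_date=laying,
            )
        )
    return out
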