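import math

import numpy as np
import pytest

from clutchkit.errors import (
    InsufficientEggsError,
    InvalidInputError,
    PairingError,
    UndefinedAngleError,
)
from clutchkit.geometry import (
    EggAnnotation,
    adjacent_angles,
    arrangement_change,
    arrangement_metrics,
    blunt_pole_angle,
    blunt_pole_distance,
    blunt_pole_orientation,
    two_point_sd_circular,
    two_point_sd_linear,
)

from _oracles import (
    oracle_adjacent,
    oracle_angle,
    oracle_circular_sd_two,
    oracle_distance,
    oracle_orientation,
)
from conftest import make_obs, random_clutch


def egg(blunt, sharp=(999.0, 999.0), egg_id="e"):
    return EggAnnotation(egg_id, blunt, sharp)


class TestPerEggMetrics:
    @pytest.mark.parametrize(
        "blunt, center, expected",
        [((3.0, 4.0), (0.0, 0.0), 5.0), ((7.5, -2.0), (7.5, -2.0), 0.0)],
    )
    def test_distance_known_values(self, blunt, center, expected):
        assert blunt_pole_distance(egg(blunt), center) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "blunt, expected",
        [((1.0, 0.0), 0.0), ((0.0, 1.0), 90.0), ((-2.0, 0.0), 180.0), ((0.0, -3.0), 270.0)],
    )
    def test_angle_axis_cases(self, blunt, expected):
        assert blunt_pole_angle(egg(blunt), (0.0, 0.0)) == pytest.approx(expected)

    def test_angle_flips_sign_in_image_coordinates(self):
        # y-down data: a blunt pole "below" the center on screen is at 270 deg
        assert blunt_pole_angle(egg((0.0, 1.0)), (0.0, 0.0), y_down=True) == pytest.approx(270.0)

    def test_angle_undefined_at_center(self):
        with pytest.raises(UndefinedAngleError):
            blunt_pole_angle(egg((2.0, 2.0)), (2.0, 2.0))

    @pytest.mark.parametrize(
        "blunt, sharp, expected",
        [((1.0, 1.0), (0.0, 0.0), 45.0), ((0.0, 5.0), (0.0, 0.0), 90.0)],
    )
    def test_orientation_known_values(self, blunt, sharp, expected):
        assert blunt_pole_orientation(egg(blunt, sharp)) == pytest.approx(expected)

    def test_orientation_is_axial(self):
        a = egg((3.0, 7.0), (1.0, 2.0))
        b = egg((1.0, 2.0), (3.0, 7.0))  # poles swapped
        assert blunt_pole_orientation(a) == pytest.approx(blunt_pole_orientation(b))

    def test_coincident_poles_rejected(self):
        with pytest.raises(InvalidInputError):
            EggAnnotation("e", (1.0, 1.0), (1.0, 1.0))

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(InvalidInputError):
            EggAnnotation("e", (float("nan"), 0.0), (1.0, 1.0))


class TestOracleEquivalence:
    def test_metrics_match_brute_force_on_random_clutches(self, rng):
        """All four metric families agree with an independent implementation
        on 100 random clutches to 1e-9."""
        for _ in range(100):
            y_down = bool(rng.integers(2))
            obs = random_clutch(rng, y_down=y_down)
            m = arrangement_metrics(obs)
            blunts = {e.egg_id: e.blunt_pole for e in obs.eggs}
            sharps = {e.egg_id: e.sharp_pole for e in obs.eggs}
            for i, eid in enumerate(m.egg_ids):
                e = next(x for x in obs.eggs if x.egg_id == eid)
                assert m.blunt_pole_distance[i] == pytest.approx(
                    oracle_distance(blunts[eid], obs.nest_center), abs=1e-9
                )
                assert m.blunt_pole_angle[i] == pytest.approx(
                    oracle_angle(blunts[eid], obs.nest_center, y_down), abs=1e-9
                )
                assert m.blunt_pole_orientation[i] == pytest.approx(
                    oracle_orientation(blunts[eid], sharps[eid], y_down), abs=1e-9
                )
            expected_adj = oracle_adjacent(
                [blunts[e.egg_id] for e in obs.eggs],
                [sharps[e.egg_id] for e in obs.eggs],
                obs.nest_center,
                y_down,
            )
            np.testing.assert_allclose(m.adjacent_angle, expected_adj, atol=1e-9)

    def test_adjacent_angles_telescope_to_zero_mod_180(self, rng):
        for _ in range(50):
            obs = random_clutch(rng)
            total = float(np.sum(adjacent_angles(obs)))
            assert min(total % 180.0, 180.0 - total % 180.0) == pytest.approx(0.0, abs=1e-8)


class TestAdjacentAngles:
    def test_parallel_eggs(self):
        obs = make_obs(
            [("a", (10.0, 0.0), (5.0, 0.0)), ("b", (-10.0, 0.0), (-5.0, 0.0))]
        )
        np.testing.assert_allclose(adjacent_angles(obs), [0.0, 0.0])

    def test_perpendicular_eggs(self):
        obs = make_obs(
            [("a", (10.0, 0.0), (5.0, 0.0)), ("b", (0.0, 10.0), (0.0, 5.0))]
        )
        np.testing.assert_allclose(adjacent_angles(obs), [90.0, 90.0])

    def test_single_egg_rejected(self):
        obs = make_obs([("a", (10.0, 0.0), (5.0, 0.0))])
        with pytest.raises(InsufficientEggsError):
            adjacent_angles(obs)


class TestTwoPointSD:
    def test_linear_two_point_sd(self):
        assert two_point_sd_linear(10.0, 20.0) == pytest.approx(5 * math.sqrt(2))

    def test_circular_matches_unit_vector_oracle(self, rng):
        for _ in range(200):
            a, b = rng.uniform(0, 360, 2)
            period = 360.0 if rng.integers(2) else 180.0
            assert two_point_sd_circular(a, b, period) == pytest.approx(
                oracle_circular_sd_two(a % period, b % period, period), abs=1e-9
            )

    def test_circular_sd_handles_wraparound(self):
        # 359 vs 1 deg are 2 deg apart, not 358
        near = two_point_sd_circular(359.0, 1.0)
        far = two_point_sd_circular(0.0, 90.0)
        assert near < 2.0 < far


class TestArrangementChange:
    def test_identity_gives_all_zero(self, rng):
        before = random_clutch(rng, n=5)
        after = make_obs(
            [(e.egg_id, e.blunt_pole, e.sharp_pole) for e in before.eggs],
            nest_id=before.nest_id, phase="after", center=before.nest_center,
        )
        ch = arrangement_change(before, after)
        for v in ch.as_dict().values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_pure_distance_change(self):
        """One egg moved radially 10 -> 20 px: distance SD is 5*sqrt(2), all
        angular SDs stay 0 (axes and polar directions unchanged)."""
        before = make_obs(
            [("a", (10.0, 0.0), (4.0, 0.0)), ("b", (0.0, 10.0), (0.0, 4.0))]
        )
        after = make_obs(
            [("a", (20.0, 0.0), (14.0, 0.0)), ("b", (0.0, 10.0), (0.0, 4.0))],
            phase="after",
        )
        ch = arrangement_change(before, after)
        assert ch.sd_blunt_pole_distance == pytest.approx(10.0 / math.sqrt(2) / 2)
        assert ch.sd_blunt_pole_angle == pytest.approx(0.0, abs=1e-12)
        assert ch.sd_blunt_pole_orientation == pytest.approx(0.0, abs=1e-12)
        assert ch.sd_adjacent_angle == pytest.approx(0.0, abs=1e-12)

    @staticmethod
    def _rotate_obs(obs, theta_deg):
        t = math.radians(theta_deg)
        c, s = math.cos(t), math.sin(t)
        cx, cy = obs.nest_center

        def rot(p):
            x, y = p[0] - cx, p[1] - cy
            return (cx + c * x - s * y, cy + s * x + c * y)

        return make_obs(
            [(e.egg_id, rot(e.blunt_pole), rot(e.sharp_pole)) for e in obs.eggs],
            nest_id=obs.nest_id, phase="after", center=obs.nest_center,
        )

    def test_global_rotation_matches_circular_oracle(self, rng):
        """Rotating the whole after-clutch by theta keeps distance SD at 0,
        leaves relative adjacent angles unchanged, and shifts every egg's
        polar angle and orientation by exactly theta (circular oracle)."""
        for _ in range(25):
            theta = float(rng.uniform(5, 85))
            before = random_clutch(rng, n=5)
            after = self._rotate_obs(before, theta)
            ch = arrangement_change(before, after)
            assert ch.sd_blunt_pole_distance == pytest.approx(0.0, abs=1e-8)
            assert ch.sd_adjacent_angle == pytest.approx(0.0, abs=1e-8)
            assert ch.sd_blunt_pole_angle == pytest.approx(
                oracle_circular_sd_two(0.0, theta, 360.0), abs=1e-8
            )
            assert ch.sd_blunt_pole_orientation == pytest.approx(
                oracle_circular_sd_two(0.0, theta % 180.0, 180.0), abs=1e-8
            )

    def test_translation_and_scaling_invariances(self, rng):
        """Translating both observations (with their centers) leaves every
        score unchanged; uniform scaling about the center scales the
        distance SD linearly and leaves angular SDs unchanged."""
        before = random_clutch(rng, n=4)
        after = random_clutch(rng, n=4, phase="after")
        after = make_obs(
            [(e.egg_id, e.blunt_pole, e.sharp_pole) for e in after.eggs],
            nest_id=before.nest_id, phase="after", center=after.nest_center,
        )
        base = arrangement_change(before, after).as_dict()

        def shift(obs, dx, dy, scale=1.0):
            cx, cy = obs.nest_center

            def f(p):
                return ((p[0] - cx) * scale + cx + dx, (p[1] - cy) * scale + cy + dy)

            return make_obs(
                [(e.egg_id, f(e.blunt_pole), f(e.sharp_pole)) for e in obs.eggs],
                nest_id=obs.nest_id, phase=obs.phase, center=(cx + dx, cy + dy),
            )

        moved = arrangement_change(shift(before, 37.0, -12.0), shift(after, 37.0, -12.0))
        for k, v in moved.as_dict().items():
            assert v == pytest.approx(base[k], abs=1e-9)

        scaled = arrangement_change(shift(before, 0, 0, 3.0), shift(after, 0, 0, 3.0))
        assert scaled.sd_blunt_pole_distance == pytest.approx(
            3.0 * base["sd_blunt_pole_distance"], rel=1e-9
        )
        for k in ("sd_blunt_pole_angle", "sd_blunt_pole_orientation", "sd_adjacent_angle"):
            assert scaled.as_dict()[k] == pytest.approx(base[k], abs=1e-9)

    def test_model_egg_excluded_from_pairing(self, rng):
        before = random_clutch(rng, n=4)
        eggs_after = [(e.egg_id, e.blunt_pole, e.sharp_pole) for e in before.eggs]
        eggs_after.append(("model", (150.0, 150.0), (130.0, 130.0), True))
        after = make_obs(eggs_after, nest_id=before.nest_id, phase="after",
                         center=before.nest_center)
        ch = arrangement_change(before, after)
        for v in ch.as_dict().values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_unpairable_counts_raise(self, rng):
        before = random_clutch(rng, n=5)
        after = make_obs(
            [(e.egg_id, e.blunt_pole, e.sharp_pole) for e in before.eggs[:4]],
            nest_id=before.nest_id, phase="after", center=before.nest_center,
        )
        with pytest.raises(PairingError):
            arrangement_change(before, after)

    def test_nearest_centroid_pairing_when_ids_differ(self, rng):
        before = random_clutch(rng, n=4)
        after = make_obs(
            [(f"x{i}", e.blunt_pole, e.sharp_pole) for i, e in enumerate(before.eggs)],
            nest_id=before.nest_id, phase="after", center=before.nest_center,
        )
        ch = arrangement_change(before, after)
        for v in ch.as_dict().values():
            assert v == pytest.approx(0.0, abs=1e-12)
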