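"""Radiographic measures: hand-derived exact values and invariances."""
import math

import numpy as np
import pytest

from hipcov.radiograph2d import (
    RadiographLandmarks,
    acetabular_angle,
    acetabular_index,
    crossover_ratio,
    extrusion_index,
    lcea,
    measure_all,
    obturator_index,
    posterior_wall_distance,
)


def make_landmarks(**overrides):
    """A geometrically plausible right-hip landmark set; x lateral, y
    superior, head center at the origin, head radius 25 mm."""
    base = dict(
        head_center=(0.0, 0.0),
        head_radius=25.0,
        lateral_sourcil=(20.0, 0.0),
        medial_sourcil=(-10.0, 5.0),
        teardrop=(-30.0, -20.0),
        teardrop_contralateral=(-150.0, -20.0),
        lateral_rim=(24.0, 14.0),
        anterior_wall=[(20.0, 12.0), (0.0, -5.0), (-15.0, -18.0)],
        posterior_wall=[(23.0, 10.0), (8.0, -8.0), (-10.0, -22.0)],
        obturator_width_ipsi=30.0,
        obturator_width_contra=30.0,
        horizontal_ref=(1.0, 0.0),
        side="right",
    )
    base.update(overrides)
    return RadiographLandmarks(**base)


class TestExtrusionIndex:
    def test_five_over_fifty(self):
        lm = make_landmarks(lateral_sourcil=(20.0, 0.0))  # edge at 25
        assert extrusion_index(lm) == pytest.approx(0.10, abs=1e-12)

    def test_overhanging_sourcil_clamps_to_zero(self):
        lm = make_landmarks(lateral_sourcil=(30.0, 0.0))
        assert extrusion_index(lm) == 0.0

    def test_twenty_over_hundred(self):
        lm = make_landmarks(head_radius=50.0, lateral_sourcil=(30.0, 0.0))
        assert extrusion_index(lm) == pytest.approx(0.20, abs=1e-12)


class TestLcea:
    def test_thirty_degrees(self):
        s = (25.0 * math.sin(math.radians(30)), 25.0 * math.cos(math.radians(30)))
        assert lcea(make_landmarks(lateral_sourcil=s)) == pytest.approx(30.0, abs=1e-9)

    def test_directly_superior_is_zero(self):
        assert lcea(make_landmarks(lateral_sourcil=(0.0, 25.0))) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_medial_sourcil_negative(self):
        s = (-25.0 * math.sin(math.radians(10)), 25.0 * math.cos(math.radians(10)))
        assert lcea(make_landmarks(lateral_sourcil=s)) == pytest.approx(-10.0, abs=1e-9)

    def test_sourcil_at_center_rejected(self):
        with pytest.raises(ValueError):
            lcea(make_landmarks(lateral_sourcil=(0.0, 0.0)))


class TestRoofAngles:
    def test_horizontal_sourcil_zero_index(self):
        lm = make_landmarks(medial_sourcil=(0.0, 0.0), lateral_sourcil=(10.0, 0.0))
        assert acetabular_index(lm) == pytest.approx(0.0, abs=1e-12)

    def test_upsloping_ten_degrees(self):
        lm = make_landmarks(medial_sourcil=(0.0, 0.0), lateral_sourcil=(10.0, 1.763))
        expected = math.degrees(math.atan2(1.763, 10.0))
        assert acetabular_index(lm) == pytest.approx(expected, abs=1e-9)
        assert acetabular_index(lm) == pytest.approx(10.0, abs=0.01)

    def test_downsloping_negative(self):
        lm = make_landmarks(medial_sourcil=(0.0, 5.0), lateral_sourcil=(10.0, 0.0))
        assert acetabular_index(lm) < 0

    def test_acetabular_angle_forty(self):
        lm = make_landmarks(teardrop=(0.0, 0.0), lateral_sourcil=(20.0, 16.78))
        expected = math.degrees(math.atan2(16.78, 20.0))
        assert acetabular_angle(lm) == pytest.approx(expected, abs=1e-9)
        assert acetabular_angle(lm) == pytest.approx(40.0, abs=0.05)

    def test_acetabular_angle_vertical_is_ninety(self):
        lm = make_landmarks(teardrop=(0.0, 0.0), lateral_sourcil=(0.0, 10.0))
        assert acetabular_angle(lm) == pytest.approx(90.0, abs=1e-9)


class TestCrossover:
    def test_no_intersection_absent(self):
        assert crossover_ratio(make_landmarks()) is None

    def test_ratio_one_tenth(self):
        # walls cross at (5, 0); a = |(5,8)-(5,0)| = 8; b = |(5,8)-(5,-72)| = 80
        lm = make_landmarks(
            anterior_wall=[(0.0, 10.0), (10.0, -10.0)],
            posterior_wall=[(0.0, -10.0), (10.0, 10.0)],
            lateral_rim=(5.0, 8.0),
            teardrop=(5.0, -72.0),
        )
        assert crossover_ratio(lm) == pytest.approx(0.10, abs=1e-12)

    def test_crossover_at_rim_is_zero(self):
        lm = make_landmarks(
            anterior_wall=[(5.0, 8.0), (10.0, -10.0)],
            posterior_wall=[(0.0, 16.0), (10.0, 0.0)],
            lateral_rim=(5.0, 8.0),
            teardrop=(5.0, -72.0),
        )
        assert crossover_ratio(lm) == pytest.approx(0.0, abs=1e-9)

    def test_most_lateral_intersection_wins(self):
        # anterior wall descends across a zig-zag posterior wall twice;
        # the first crossing along the anterior wall from its lateral end
        lm = make_landmarks(
            anterior_wall=[(10.0, 10.0), (-10.0, -10.0)],
            posterior_wall=[(10.0, 2.0), (-2.0, 2.0), (-8.0, -6.0), (10.0, -6.0)],
            lateral_rim=(10.0, 10.0),
            teardrop=(-40.0, -40.0),
        )
        # crossings at (2, 2) and (-6, -6); the first along the anterior
        # wall from its lateral end is (2, 2)
        expected = np.linalg.norm([10.0 - 2.0, 10.0 - 2.0]) / np.linalg.norm(
            [50.0, 50.0]
        )
        assert crossover_ratio(lm) == pytest.approx(expected, abs=1e-12)


class TestPosteriorWallDistance:
    def test_lateral_positive(self):
        lm = make_landmarks(posterior_wall=[(3.4, 10.0), (3.4, -10.0)])
        assert posterior_wall_distance(lm) == pytest.approx(3.4, abs=1e-12)

    def test_medial_negative(self):
        lm = make_landmarks(posterior_wall=[(-5.9, 10.0), (-5.9, -10.0)])
        assert posterior_wall_distance(lm) == pytest.approx(-5.9, abs=1e-12)

    def test_through_center_zero(self):
        lm = make_landmarks(posterior_wall=[(0.0, 10.0), (0.0, -10.0)])
        assert posterior_wall_distance(lm) == pytest.approx(0.0, abs=1e-12)

    def test_no_crossing_rejected(self):
        lm = make_landmarks(posterior_wall=[(5.0, 10.0), (5.0, 2.0)])
        with pytest.raises(ValueError):
            posterior_wall_distance(lm)


class TestObturatorIndex:
    @pytest.mark.parametrize(
        "ipsi,contra,ratio,passes",
        [(30.0, 30.0, 1.0, True), (30.0, 40.0, 0.75, False), (36.0, 30.0, 1.2, True)],
    )
    def test_ratio_and_screen(self, ipsi, contra, ratio, passes):
        lm = make_landmarks(obturator_width_ipsi=ipsi, obturator_width_contra=contra)
        r, ok = obturator_index(lm)
        assert r == pytest.approx(ratio, abs=1e-12)
        assert ok is passes


class TestInvariance:
    def _transformed(self, lm: RadiographLandmarks, A: np.ndarray, t: np.ndarray):
        def tp(p):
            return A @ np.asarray(p, float) + t

        return RadiographLandmarks(
            head_center=tp(lm.head_center),
            head_radius=lm.head_radius,
            lateral_sourcil=tp(lm.lateral_sourcil),
            medial_sourcil=tp(lm.medial_sourcil),
            teardrop=tp(lm.teardrop),
            teardrop_contralateral=tp(lm.teardrop_contralateral),
            lateral_rim=tp(lm.lateral_rim),
            anterior_wall=np.array([tp(p) for p in lm.anterior_wall]),
            posterior_wall=np.array([tp(p) for p in lm.posterior_wall]),
            obturator_width_ipsi=lm.obturator_width_ipsi,
            obturator_width_contra=lm.obturator_width_contra,
            horizontal_ref=A @ lm.horizontal_ref,
            side=lm.side,
        )

    def _assert_measures_equal(self, a, b):
        ma, mb = measure_all(a), measure_all(b)
        for key, va in ma.as_dict().items():
            vb = mb.as_dict()[key]
            if va is None:
                assert vb is None
            elif isinstance(va, bool):
                assert va == vb
            else:
                assert va == pytest.approx(vb, abs=1e-9)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(12)
        lm = make_landmarks()
        for _ in range(5):
            ang = rng.uniform(0, 2 * np.pi)
            A = np.array(
                [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
            )
            t = rng.uniform(-50, 50, size=2)
            self._assert_measures_equal(lm, self._transformed(lm, A, t))

    def test_mirror_invariance(self):
        lm = make_landmarks()
        A = np.array([[-1.0, 0.0], [0.0, 1.0]])
        mirrored = self._transformed(lm, A, np.zeros(2))
        mirrored.side = "left"
        self._assert_measures_equal(lm, mirrored)


class TestInvarianceProperty:
    """Property-based check: any rigid in-plane motion applied jointly to
    landmarks and the horizontal reference leaves every measure fixed."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _rot(ang):
        return np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])

    @given(
        ang=st.floats(0.0, 2 * np.pi),
        tx=st.floats(-100.0, 100.0),
        ty=st.floats(-100.0, 100.0),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_rigid_motion_fixes_measures(self, ang, tx, ty):
        lm = make_landmarks()
        helper = TestInvariance()
        moved = helper._transformed(lm, self._rot(ang), np.array([tx, ty]))
        helper._assert_measures_equal(lm, moved)
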