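"""Rigid-body propagation, screw decomposition and ring/helix closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cartwheel import geometry as g
from conftest import random_screw


class TestCompose:
    def test_identity(self):
        I = np.eye(4)
        assert np.allclose(g.compose(I, I), I)

    def test_two_quarter_turns_make_a_half_turn(self):
        r45 = g.screw_transform_matrix(45.0, [0, 0, 1], [0, 0, 0], 0.0)
        r90 = g.screw_transform_matrix(90.0, [0, 0, 1], [0, 0, 0], 0.0)
        assert np.allclose(g.compose(r45, r45), r90, atol=1e-12)

    def test_inverse_composes_to_identity(self, rng):
        for _ in range(20):
            T = random_screw(rng).matrix()
            assert np.allclose(g.compose(T, np.linalg.inv(T)), np.eye(4), atol=1e-9)

    def test_associative(self, rng):
        A, B, C = (random_screw(rng).matrix() for _ in range(3))
        assert np.allclose(g.compose(g.compose(A, B), C),
                           g.compose(A, g.compose(B, C)), atol=1e-9)

    def test_rejects_non_orthonormal(self):
        bad = np.eye(4)
        bad[0, 0] = 2.0
        with pytest.raises(g.InvalidTransformError):
            g.compose(bad, np.eye(4))


class TestScrewDecompose:
    def test_pure_rotation_about_z(self):
        T = g.screw_transform_matrix(90.0, [0, 0, 1], [0, 0, 0], 0.0)
        s = g.screw_decompose(T)
        assert s.rotation_angle == pytest.approx(90.0)
        assert s.rise == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_with_rise_is_the_fourfold_helix_step(self):
        T = g.screw_transform_matrix(90.0, [0, 0, 1], [0, 0, 0], 6.5)
        s = g.screw_decompose(T)
        assert s.rotation_angle == pytest.approx(90.0)
        assert s.rise == pytest.approx(6.5)

    def test_round_trip_random_screws(self, rng):
        for _ in range(100):
            s0 = random_screw(rng)
            T = s0.matrix()
            s1 = g.screw_decompose(T)
            assert np.allclose(s1.matrix(), T, atol=1e-6)
            assert s1.residual_translation < 1e-9

    def test_round_trip_parameter_recovery(self, rng):
        for _ in range(50):
            s0 = random_screw(rng)
            s1 = g.screw_decompose(s0.matrix())
            # sign convention: axis may flip, angle is in [0, 180]
            sign = np.sign(s1.axis @ s0.axis)
            assert s1.rotation_angle == pytest.approx(s0.rotation_angle, abs=1e-6)
            assert sign * s1.rise == pytest.approx(s0.rise, abs=1e-6)
            assert np.allclose(sign * s1.axis, s0.axis, atol=1e-6)

    def test_pure_translation_special_case(self):
        T = g.make_transform(np.eye(3), [0, 0, 3.0])
        s = g.screw_decompose(T)
        assert s.rotation_angle == 0.0
        assert s.rise == pytest.approx(3.0)
        assert np.allclose(s.axis, [0, 0, 1])

    def test_half_turn_warns_and_keeps_rise_nonnegative(self):
        T = g.screw_transform_matrix(180.0, [0, 0, 1], [0, 0, 0], -2.0)
        with pytest.warns(RuntimeWarning, match="180"):
            s = g.screw_decompose(T)
        assert s.rise >= 0
        assert np.allclose(s.matrix(), T, atol=1e-6)

    def test_conjugation_invariance(self, rng):
        """Classification inputs (angle, |rise|) are frame-independent."""
        for _ in range(20):
            s0 = random_screw(rng)
            T = s0.matrix()
            C = random_screw(rng).matrix()
            Tc = C @ T @ np.linalg.inv(C)
            sc = g.screw_decompose(Tc)
            assert sc.rotation_angle == pytest.approx(s0.rotation_angle, abs=1e-6)
            assert abs(sc.rise) == pytest.approx(abs(s0.rise), abs=1e-6)


class TestClassify:
    def test_native_bend_closes_ninefold(self, ring_step):
        cls = g.classify_step(ring_step)
        assert cls.kind == "closed_ring"
        assert cls.n_units == 9

    def test_twist_with_rise_is_helix(self, helix_step):
        cls = g.classify_step(helix_step)
        assert cls.kind == "helix"
        assert cls.pitch == pytest.approx(26.0)
        assert cls.units_per_turn == pytest.approx(4.0)

    def test_non_divisor_angle_is_open_arc(self):
        cls = g.classify_step(g.interface_step(37.0, 0.0))
        assert cls.kind == "open_arc"

    def test_degenerate_step_raises(self):
        with pytest.raises(g.DegenerateStepError):
            g.classify_step(np.eye(4))

    def test_agrees_with_brute_force_closure(self):
        """Sweep 10..120 degrees; compare with explicit propagation.

        Closure means the frame one past unit n returns to the seed after a
        single turn (multi-wrap closure would run units through each other).
        """
        for angle in range(10, 121):
            step = g.interface_step(float(angle), 0.0)
            cls = g.classify_step(step)
            closed_n = None
            for n in range(3, 49):
                if abs(n * angle - 360.0) > g.CLOSURE_ANGLE_DEG:
                    continue
                Tn = np.linalg.matrix_power(step, n)
                gap = np.linalg.norm(Tn[:3, 3])
                mis = g.screw_decompose_angle_only(Tn)
                if gap <= g.CLOSURE_GAP_NM and mis <= g.CLOSURE_ANGLE_DEG:
                    closed_n = n
                    break
            if closed_n is not None:
                assert cls.kind == "closed_ring"
                assert cls.n_units == closed_n
            else:
                assert cls.kind != "closed_ring"


class TestPropagate:
    def test_ninefold_ring(self, ring_assembly):
        assert ring_assembly.classification.kind == "closed_ring"
        assert ring_assembly.classification.n_units == 9
        assert ring_assembly.closure_gap < 1e-9

    def test_partial_ring_is_an_arc(self, ring_step):
        asm = g.propagate(g.default_seed_unit(step=ring_step), ring_step, 4)
        assert asm.classification.kind == "open_arc"
        assert asm.classification.arc_angle == pytest.approx(120.0)

    def test_helix(self, helix_assembly):
        cls = helix_assembly.classification
        assert cls.kind == "helix"
        assert cls.pitch == pytest.approx(26.0)

    def test_straight_filament(self):
        step = g.interface_step(0.0, 0.0)
        asm = g.propagate(g.default_seed_unit(), step, 5)
        assert asm.classification.kind == "open_arc"
        assert asm.classification.arc_angle == 0.0
        d = np.linalg.norm(np.diff(asm.origins(), axis=0), axis=1)
        assert np.allclose(d, g.CHORD_NM)

    def test_unit_frames_are_step_powers(self, ring_step, ring_assembly):
        T3 = np.linalg.matrix_power(ring_step, 3)
        expected = g.apply_transform(T3, np.zeros(3))
        assert np.allclose(ring_assembly.units[3].frame_origin, expected)

    def test_size_limit(self, ring_step):
        with pytest.raises(ValueError, match="exceeds"):
            g.propagate(g.default_seed_unit(step=ring_step), ring_step, 500)


class TestClosedForms:
    def test_ninefold_diameter_is_23nm(self):
        assert g.ring_diameter(7.87, 9) == pytest.approx(23.0, abs=0.05)

    def test_eight_and_tenfold_windows(self):
        assert g.ring_diameter(7.87, 8) == pytest.approx(20.6, abs=0.05)
        assert g.ring_diameter(7.87, 10) == pytest.approx(25.5, abs=0.05)

    @given(st.floats(1.0, 50.0), st.integers(3, 48))
    @settings(max_examples=50, deadline=None)
    def test_diameter_round_trip(self, diameter, n):
        chord = diameter * math.sin(math.pi / n)
        assert g.ring_diameter(chord, n) == pytest.approx(diameter, rel=1e-12)

    def test_diameter_linearity_and_domain(self):
        assert g.ring_diameter(2 * 7.87, 9) == pytest.approx(2 * g.ring_diameter(7.87, 9))
        with pytest.raises(ValueError):
            g.ring_diameter(7.87, 2)

    def test_helix_parameters(self, helix_step):
        pitch, upt, radius = g.helix_parameters(helix_step)
        assert (pitch, upt) == (pytest.approx(26.0), pytest.approx(4.0))
        assert radius > 0

    def test_pitch_identity_over_random_screws(self, rng):
        for _ in range(30):
            s = random_screw(rng)
            pitch, upt, _ = g.helix_parameters(s)
            assert pitch == pytest.approx(s.rise * 360.0 / s.rotation_angle, rel=1e-12)

    def test_ring_limit_pitch_zero(self):
        pitch, upt, _ = g.helix_parameters(g.interface_step(40.0, 0.0))
        assert pitch == pytest.approx(0.0, abs=1e-9)

    def test_sixty_degree_twist(self):
        pitch, upt, _ = g.helix_parameters(
            g.ScrewTransform(60.0, np.array([0, 0, 1.0]), np.zeros(3), 2.0))
        assert (pitch, upt) == (pytest.approx(12.0), pytest.approx(6.0))


class TestLandingSpokes:
    def test_max_same_side_spacing_is_one_pitch(self, helix_assembly):
        pattern = g.landing_spoke_pattern(helix_assembly, visible_sector=30.0)
        assert g.max_same_side_spacing(pattern) == pytest.approx(26.0)

    def test_opposite_sides_offset_half_pitch(self, helix_assembly):
        pattern = g.landing_spoke_pattern(helix_assembly, visible_sector=30.0)
        left = sorted(p for p, s in pattern if s == "left")
        right = sorted(p for p, s in pattern if s == "right")
        assert min(abs(l - r) for l in left for r in right) == pytest.approx(13.0)

    def test_zero_sector_is_empty(self, helix_assembly):
        assert g.landing_spoke_pattern(helix_assembly, visible_sector=0.0) == []

    def test_ring_input_rejected(self, ring_assembly):
        with pytest.raises(ValueError, match="helix"):
            g.landing_spoke_pattern(ring_assembly)


class TestHomodimerUnit:
    def test_orientation_must_be_proper(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(g.InvalidTransformError):
            g.HomodimerUnit(np.zeros(3), R, np.array([1.0, 0, 0]))

    def test_spoke_normalised(self):
        u = g.HomodimerUnit(np.zeros(3), np.eye(3), np.array([3.0, 0, 0]), 10.0)
        assert np.allclose(u.spoke_direction, [1, 0, 0])
        assert np.allclose(u.spoke_tip(), [10, 0, 0])
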