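import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camptokin.io_formats import Anthropometry
from camptokin.kinematics import (
    ca_malleolus,
    ca_perpendicular,
    classify_camptocormia,
    knee_angle,
    leg_angle,
    leg_inclination,
    trunk_inclination,
)
from conftest import forward_leg_oracle

ANTHRO = Anthropometry(u=0.45, l=0.45)


class TestInclinations:
    @pytest.mark.parametrize(
        "accel, expected",
        [
            ((-1.0, 0.0, 0.0), 0.0),     # upright
            ((0.0, 0.0, 1.0), 90.0),     # horizontal, no division blow-up
            ((-0.7071, 0.0, 0.7071), 45.0),
        ],
    )
    def test_trunk_examples(self, accel, expected):
        assert trunk_inclination(*accel) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize(
        "accel, expected",
        [
            ((-1.0, 0.0, 0.0), 0.0),  # vertical segment
            ((-np.cos(np.radians(10)), -np.sin(np.radians(10)), 0.0), 10.0),
            ((-np.cos(np.radians(10)), np.sin(np.radians(10)), 0.0), -10.0),
        ],
    )
    def test_leg_examples_and_sign_antisymmetry(self, accel, expected):
        assert leg_inclination(*accel) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_masked_not_raised(self):
        assert np.isnan(trunk_inclination(0.0, 0.0, 0.0))
        assert np.isnan(leg_inclination(0.0, 0.0, 0.0))

    @settings(derandomize=True, max_examples=200)
    @given(alpha=st.floats(0.0, 80.0), azimuth=st.floats(0.0, 360.0))
    def test_trunk_round_trip_from_rotated_gravity(self, alpha, azimuth):
        # rotate the gravity unit vector by alpha about a horizontal axis at
        # arbitrary azimuth and project onto the sensor axes
        ar = np.radians(alpha)
        az = np.radians(azimuth)
        a_x = -np.cos(ar)
        a_y = np.sin(ar) * np.sin(az)
        a_z = np.sin(ar) * np.cos(az)
        assert trunk_inclination(a_x, a_y, a_z) == pytest.approx(alpha, abs=1e-9)


class TestSpineModel:
    @pytest.mark.parametrize(
        "phi_l5, phi_c7, expected",
        [
            (0.0, 0.0, 0.3856),
            (10.0, 10.0, 10.3856),  # coefficients sum to one
            (20.0, 0.0, 9.4696),
        ],
    )
    def test_worked_values(self, phi_l5, phi_c7, expected):
        assert ca_perpendicular(phi_l5, phi_c7) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(-60, 60), dx=st.floats(0.1, 10))
    def test_monotone_in_each_argument(self, x, dx):
        assert ca_perpendicular(x + dx, 0) > ca_perpendicular(x, 0)
        assert ca_perpendicular(0, x + dx) > ca_perpendicular(0, x)

    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(-80, 80))
    def test_equal_inputs_add_constant_intercept(self, x):
        assert ca_perpendicular(x, x) - x == pytest.approx(0.3856, abs=1e-9)


class TestLegGeometry:
    @pytest.mark.parametrize(
        "phi_th, phi_sh, expected",
        [(0.0, 0.0, 180.0), (30.0, 0.0, 150.0), (10.0, -10.0, 180.0)],
    )
    def test_knee_angle(self, phi_th, phi_sh, expected):
        assert knee_angle(phi_th, phi_sh) == expected

    def test_vertical_straight_leg(self):
        phi, theta, h, z_u, z_l, invalid = leg_angle(0.0, 0.0, ANTHRO)
        assert phi == pytest.approx(0.0, abs=1e-12)
        assert h == pytest.approx(0.90, abs=1e-12)
        assert not invalid

    def test_straight_leg_tilted_keeps_full_length(self):
        phi, theta, h, *_, invalid = leg_angle(10.0, -10.0, ANTHRO)
        assert phi == pytest.approx(10.0, abs=1e-9)
        assert h == pytest.approx(0.90, abs=1e-12)
        assert theta == 180.0

    def test_bent_knee_against_oracle(self):
        phi, theta, h, *_ , invalid = leg_angle(30.0, 0.0, ANTHRO)
        assert theta == 150.0
        assert h == pytest.approx(0.86933, abs=1e-4)
        assert phi == pytest.approx(forward_leg_oracle(30.0, 0.0, 0.45, 0.45), abs=1e-9)
        assert phi == pytest.approx(15.0, abs=1e-9)

    def test_invalid_knee_flagged(self):
        *_, invalid = leg_angle(100.0, 100.0, ANTHRO)  # theta = -20
        assert invalid

    @settings(derandomize=True, max_examples=300)
    @given(
        phi_th=st.floats(-60, 60),
        phi_sh=st.floats(-60, 60),
        u=st.floats(0.3, 0.6),
        l=st.floats(0.3, 0.6),
    )
    def test_oracle_equivalence_over_valid_postures(self, phi_th, phi_sh, u, l):
        theta = 180.0 - phi_th - phi_sh
        if not 90.0 < theta <= 180.0:
            return
        phi, *_ , invalid = leg_angle(phi_th, phi_sh, Anthropometry(u=u, l=l))
        assert not invalid
        assert phi == pytest.approx(forward_leg_oracle(phi_th, phi_sh, u, l), abs=1e-9)

    def test_straight_leg_identity_whenever_collinear(self):
        # collinear configurations: phi_sh = -phi_th, any segment lengths
        for tilt in np.linspace(-45, 45, 19):
            anthro = Anthropometry(u=0.41, l=0.47)
            phi, theta, h, *_ = leg_angle(tilt, -tilt, anthro)
            assert phi == pytest.approx(tilt, abs=1e-9)
            assert h == pytest.approx(anthro.u + anthro.l, abs=1e-12)


class TestMalleolusComposition:
    @pytest.mark.parametrize(
        "ca_per, phi_leg, expected",
        [(20.0, 10.0, 30.0), (15.0, -5.0, 10.0), (0.3856, 0.0, 0.3856)],
    )
    def test_sum(self, ca_per, phi_leg, expected):
        assert ca_malleolus(ca_per, phi_leg) == pytest.approx(expected, abs=1e-12)

    def test_cutoff_is_strict(self):
        series = np.array([29.9, 30.0, 30.1, 0.0])
        np.testing.assert_array_equal(
            classify_camptocormia(series), [False, False, True, False]
        )

    def test_all_zero_series_never_flagged(self):
        assert not classify_camptocormia(np.zeros(100)).any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_camptocormia(np.zeros(3), threshold=-1.0)

    def test_trunk_angle_beyond_model_range_flagged_suspicious(self):
        from camptokin.kinematics import InclinationSet, compute_camptocormia

        angles = {
            "phi_C7": np.array([10.0, 95.0]),
            "phi_L5": np.array([10.0, 95.0]),
            "phi_TH": np.array([0.0, 0.0]),
            "phi_SH": np.array([0.0, 0.0]),
        }
        incl = InclinationSet(sample_rate=128.0, angles=angles)
        series = compute_camptocormia(incl, ANTHRO)
        assert series.invalid.tolist() == [False, True]
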