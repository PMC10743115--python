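"""Polar-value algebra: conversions, DA, classification, radius->power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astigvec.core import (
    AxisClass,
    NetAstigmatism,
    PolarValues,
    classify_axis,
    compute_da,
    net_to_polar,
    normalize_meridian,
    polar_to_net,
    radius_to_power,
)

TOL = 1e-9


class TestNetToPolar:
    @pytest.mark.parametrize(
        "mag,alpha,phi,kp,kp45",
        [
            (1.0, 90.0, 90.0, 1.0, 0.0),  # phi = alpha: cos term saturates
            (1.0, 0.0, 90.0, -1.0, 0.0),  # meridians 90 deg apart negate KP(phi)
            (2.0, 45.0, 0.0, 0.0, 2.0),  # 2(alpha - phi) = 90 deg
        ],
    )
    def test_reference_cases(self, mag, alpha, phi, kp, kp45):
        pv = net_to_polar(NetAstigmatism(mag, alpha), phi)
        assert pv.kp_phi == pytest.approx(kp, abs=TOL)
        assert pv.kp_phi45 == pytest.approx(kp45, abs=TOL)

    def test_rejects_out_of_range_reference(self):
        with pytest.raises(ValueError):
            net_to_polar(NetAstigmatism(1.0, 0.0), 180.0)


class TestPolarToNet:
    def test_345_triangle(self):
        # oracle: atan2(0.4, 0.3) / 2 = 26.565...; also the printed half-angle
        # form arctan((0.5 - 0.3) / 0.4)
        net = polar_to_net(PolarValues(0.3, 0.4, 0.0))
        assert net.magnitude == pytest.approx(0.5, abs=TOL)
        assert net.meridian == pytest.approx(math.degrees(math.atan2(0.4, 0.3)) / 2, abs=TOL)
        assert net.meridian == pytest.approx(26.56505117707799, abs=1e-9)

    def test_round_trip_of_aligned_case(self):
        assert polar_to_net(PolarValues(1.0, 0.0, 90.0)) == NetAstigmatism(1.0, 90.0)

    def test_zero_magnitude_degenerate_convention(self):
        net = polar_to_net(PolarValues(0.0, 0.0, 57.0))
        assert (net.magnitude, net.meridian) == (0.0, 0.0)


class TestComputeDA:
    def test_identical_cylinders_give_zero(self):
        da = compute_da(NetAstigmatism(1.0, 90.0), NetAstigmatism(1.0, 90.0))
        assert da.delta_kp_phi == pytest.approx(0.0, abs=TOL)
        assert da.delta_kp_phi45 == pytest.approx(0.0, abs=TOL)
        assert da.magnitude == pytest.approx(0.0, abs=TOL)

    def test_overestimation_is_negative(self):
        # corneal cylinder reads 1.0 D where refraction shows 0.5 D
        da = compute_da(NetAstigmatism(0.5, 90.0), NetAstigmatism(1.0, 90.0))
        assert da.delta_kp_phi == pytest.approx(-0.5, abs=TOL)
        assert da.delta_kp_phi45 == pytest.approx(0.0, abs=TOL)
        assert da.magnitude == pytest.approx(0.5, abs=TOL)

    def test_oblique_pair_matches_power_vector_subtraction(self):
        # oracle: subtraction in double-angle space about phi = 0:
        # RA 1.0 @ 45 -> (0, 1); CA 1.0 @ 0 -> (1, 0); difference (-1, 1)
        da = compute_da(NetAstigmatism(1.0, 45.0), NetAstigmatism(1.0, 0.0))
        assert da.delta_kp_phi == pytest.approx(-1.0, abs=TOL)
        assert da.delta_kp_phi45 == pytest.approx(1.0, abs=TOL)
        assert da.magnitude == pytest.approx(math.sqrt(2.0), abs=TOL)

    def test_perpendicular_pair(self):
        # RA 1.0 @ 90 vs CA 1.0 @ 0: double-angle points (-1, 0) and (1, 0)
        da = compute_da(NetAstigmatism(1.0, 90.0), NetAstigmatism(1.0, 0.0))
        assert da.delta_kp_phi == pytest.approx(-2.0, abs=TOL)
        assert da.magnitude == pytest.approx(2.0, abs=TOL)
        assert da.angle == pytest.approx(90.0, abs=TOL)  # along phi + 90


class TestClassifyAxis:
    @pytest.mark.parametrize(
        "meridian,label",
        [
            (90, AxisClass.WTR),
            (0, AxisClass.ATR),
            (45, AxisClass.OBLIQUE),
            (61, AxisClass.WTR),
            (120, AxisClass.WTR),
            (60, AxisClass.OBLIQUE),
            (121, AxisClass.OBLIQUE),
            (30, AxisClass.ATR),
            (31, AxisClass.OBLIQUE),
            (150, AxisClass.OBLIQUE),
            (151, AxisClass.ATR),
            (180, AxisClass.ATR),  # 180 normalizes to 0
        ],
    )
    def test_boundaries(self, meridian, label):
        assert classify_axis(meridian) is label

    def test_total_partition_of_integer_degrees(self):
        counts = {c: 0 for c in AxisClass}
        for m in range(180):
            counts[classify_axis(m)] += 1
        assert sum(counts.values()) == 180
        assert counts[AxisClass.WTR] == 60
        assert counts[AxisClass.ATR] == 60  # 0-30 plus 151-179
        assert counts[AxisClass.OBLIQUE] == 60

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_axis(185.0)


class TestRadiusToPower:
    @pytest.mark.parametrize(
        "radius,index,power",
        [(7.5, 1.3375, 45.0), (6.75, 1.3375, 50.0), (8.0, 1.3315, 41.4375)],
    )
    def test_closed_form(self, radius, index, power):
        assert radius_to_power(radius, index) == pytest.approx(power, abs=TOL)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            radius_to_power(0.0)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    mag=st.floats(1e-6, 6.0),
    alpha=st.floats(0.0, 180.0, exclude_max=True),
    phi=st.floats(0.0, 180.0, exclude_max=True),
)
def test_round_trip_recovers_net(mag, alpha, phi):
    net = NetAstigmatism(mag, alpha)
    back = polar_to_net(net_to_polar(net, phi))
    assert back.magnitude == pytest.approx(mag, abs=1e-9)
    # meridian agreement modulo the 0/180 wrap
    diff = abs(back.meridian - alpha)
    assert min(diff, 180.0 - diff) < 1e-6 * max(1.0, 1.0 / mag)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    mag=st.floats(0.0, 6.0),
    alpha=st.floats(0.0, 180.0, exclude_max=True),
    phi=st.floats(0.0, 180.0, exclude_max=True),
)
def test_norm_preserved_for_every_reference(mag, alpha, phi):
    pv = net_to_polar(NetAstigmatism(mag, alpha), phi)
    assert math.hypot(pv.kp_phi, pv.kp_phi45) == pytest.approx(mag, abs=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    m1=st.floats(0.1, 4.0),
    a1=st.floats(0.0, 180.0, exclude_max=True),
    m2=st.floats(0.1, 4.0),
    a2=st.floats(0.0, 180.0, exclude_max=True),
    offset=st.floats(-180.0, 180.0),
)
def test_da_magnitude_invariant_under_joint_rotation(m1, a1, m2, a2, offset):
    base = compute_da(NetAstigmatism(m1, a1), NetAstigmatism(m2, a2))
    rot = compute_da(
        NetAstigmatism(m1, normalize_meridian(a1 + offset)),
        NetAstigmatism(m2, normalize_meridian(a2 + offset)),
    )
    assert rot.magnitude == pytest.approx(base.magnitude, abs=1e-9)


@pytest.mark.parametrize(
    "dkp,dkp45",
    [(0.3, 0.4), (-0.3, 0.4), (0.3, -0.4), (-0.3, -0.4), (-0.5, 0.0), (0.0, 0.7)],
)
def test_half_angle_form_matches_atan2_oracle(dkp, dkp45):
    """The printed half-angle arctan form agrees with the two-argument
    arctangent in every sign quadrant (and at its removable singularities)."""
    da = compute_da  # reconstruct angle through polar_to_net
    net = polar_to_net(PolarValues(dkp, dkp45, 0.0))
    expected = (math.degrees(math.atan2(dkp45, dkp)) / 2.0) % 180.0
    assert net.meridian == pytest.approx(expected, abs=1e-9)
    if dkp45 != 0.0:
        m = math.hypot(dkp, dkp45)
        printed = math.degrees(math.atan((m - dkp) / dkp45)) % 180.0
        assert net.meridian == pytest.approx(printed, abs=1e-9)
    else:
        assert net.meridian == pytest.approx(90.0 if dkp < 0 else 0.0, abs=1e-9)
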