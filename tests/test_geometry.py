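"""Box/angle geometry: conversions, diagonal selection, arctangent, categories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plantarfpa.errors import (
    DegenerateBoxError,
    InvalidConfigError,
    InvalidInputError,
)
from plantarfpa.geometry import (
    AngleBoxGeometry,
    FootProfile,
    ImageDims,
    NormalizedBox,
    PixelCornerPair,
    acquire_axis_points,
    angle_geometry,
    classify_fpa,
    compute_theta,
    signed_fpa,
    to_normalized,
    to_pixel_corners,
)

D = ImageDims(120, 400)


class TestToPixelCorners:
    @pytest.mark.parametrize(
        "box, expected",
        [
            ((0.5, 0.5, 1.0, 1.0), (0.0, 0.0, 120.0, 400.0)),
            ((0.5, 0.5, 0.0, 0.0), (60.0, 200.0, 60.0, 200.0)),
            # independent hand arithmetic: (0.4-0.1)*120, (0.3-0.25)*400, ...
            ((0.4, 0.3, 0.2, 0.5), (36.0, 20.0, 60.0, 220.0)),
        ],
    )
    def test_examples(self, box, expected):
        c = to_pixel_corners(NormalizedBox(*box), D)
        assert (c.p1x, c.p1y, c.p2x, c.p2y) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_box_names_field(self):
        with pytest.raises(InvalidInputError, match="x"):
            NormalizedBox(1.5, 0.3, 0.2, 0.5)
        with pytest.raises(InvalidInputError, match="height"):
            NormalizedBox(0.5, 0.05, 0.2, 0.5)

    def test_zero_dims_rejected(self):
        with pytest.raises(InvalidInputError):
            ImageDims(0, 400)

    def test_inverse_examples(self):
        n = to_normalized(PixelCornerPair(36.0, 20.0, 60.0, 220.0), D)
        assert (n.x, n.y, n.w, n.h) == pytest.approx((0.4, 0.3, 0.2, 0.5), abs=1e-9)
        n = to_normalized(PixelCornerPair(60.0, 200.0, 60.0, 200.0), D)
        assert (n.x, n.y, n.w, n.h) == pytest.approx((0.5, 0.5, 0.0, 0.0), abs=1e-9)

    def test_round_trip_random(self, random_boxes):
        for x, y, w, h in random_boxes[:500]:
            box = NormalizedBox(x, y, w, h)
            back = to_normalized(to_pixel_corners(box, D), D)
            assert (back.x, back.y, back.w, back.h) == pytest.approx(
                (box.x, box.y, box.w, box.h), abs=1e-9
            )


class TestDiagonalSelection:
    CORNERS = PixelCornerPair(36.0, 20.0, 60.0, 220.0)

    @pytest.mark.parametrize(
        "side, toeing, front, rear",
        [
            ("left", "out", (36.0, 20.0), (60.0, 220.0)),
            ("right", "out", (60.0, 20.0), (36.0, 220.0)),
            ("left", "in", (60.0, 20.0), (36.0, 220.0)),
            ("right", "in", (36.0, 20.0), (60.0, 220.0)),
        ],
    )
    def test_profile_rules(self, side, toeing, front, rear):
        axis = acquire_axis_points(self.CORNERS, FootProfile(side, toeing))
        assert axis.front == front
        assert axis.rear == rear

    def test_front_is_top_corner(self):
        for side in ("left", "right"):
            axis = acquire_axis_points(self.CORNERS, FootProfile(side, "out"))
            assert axis.front[1] == self.CORNERS.p1y
            assert axis.front[1] <= axis.rear[1]

    def test_unknown_toeing_rejected(self):
        with pytest.raises(InvalidInputError):
            acquire_axis_points(self.CORNERS, FootProfile("left", "unknown"))


class TestAngleGeometry:
    def test_hand_example(self):
        g = angle_geometry(PixelCornerPair(36.0, 20.0, 60.0, 220.0))
        assert (g.a1, g.a2) == (200.0, 24.0)
        assert g.a3 == pytest.approx(math.sqrt(200**2 + 24**2), abs=1e-9)

    @pytest.mark.parametrize(
        "corners, a3",
        [((0, 0, 0, 0), 0.0), ((0, 0, 3, 4), 5.0)],
    )
    def test_degenerate_and_345(self, corners, a3):
        assert angle_geometry(PixelCornerPair(*corners)).a3 == a3

    def test_pythagoras_invariant_random(self):
        rng = np.random.default_rng(5)
        for a1, a2 in rng.uniform(0, 400, size=(200, 2)):
            g = angle_geometry(PixelCornerPair(0.0, 0.0, a2, a1))
            assert g.a3**2 == pytest.approx(g.a1**2 + g.a2**2, rel=1e-6)


class TestComputeTheta:
    @pytest.mark.parametrize(
        "a1, a2, expected",
        [(10, 10, 45.0), (10, 0, 0.0), (0, 10, 90.0),
         (336, 24, math.degrees(math.atan(24 / 336)))],
    )
    def test_examples(self, a1, a2, expected):
        g = AngleBoxGeometry(a1, a2, math.hypot(a1, a2))
        assert compute_theta(g) == pytest.approx(expected, abs=1e-9)

    def test_matches_arctangent_oracle(self):
        rng = np.random.default_rng(99)
        for a1, a2 in rng.uniform(0.01, 500, size=(1000, 2)):
            g = AngleBoxGeometry(a1, a2, math.hypot(a1, a2))
            assert compute_theta(g) == pytest.approx(
                math.degrees(math.atan(a2 / a1)), abs=1e-9
            )

    def test_zero_area_raises(self):
        with pytest.raises(DegenerateBoxError):
            compute_theta(AngleBoxGeometry(0.0, 0.0, 0.0))


class TestClassifyFPA:
    @pytest.mark.parametrize(
        "theta, expected",
        [(-1.0, "in_toeing"), (25.0, "out_toeing"), (0.0, "normal"),
         (20.0, "normal"), (10.0, "normal")],
    )
    def test_adult_thresholds(self, theta, expected):
        assert classify_fpa(theta) == expected

    def test_child_preset(self):
        assert classify_fpa(4.0, thresholds=(5.0, 13.0)) == "in_toeing"

    def test_invalid_thresholds(self):
        with pytest.raises(InvalidConfigError):
            classify_fpa(5.0, thresholds=(20.0, 0.0))


class TestSignedFPA:
    CORNERS = PixelCornerPair(36.0, 20.0, 60.0, 220.0)

    def test_out_positive_in_negative(self):
        expected = math.degrees(math.atan(24 / 200))
        m_out = signed_fpa(self.CORNERS, FootProfile("left", "out"), "img")
        m_in = signed_fpa(self.CORNERS, FootProfile("left", "in"), "img")
        assert m_out.theta == pytest.approx(expected, abs=1e-9)
        assert m_in.theta == pytest.approx(-expected, abs=1e-9)
        assert m_out.category == "normal"
        assert m_in.category == "in_toeing"

    def test_zero_area_box_is_missing(self):
        m = signed_fpa(PixelCornerPair(5.0, 5.0, 5.0, 5.0), FootProfile("left"), "img")
        assert m.missing and math.isnan(m.theta) and m.category is None


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    w=st.floats(1e-6, 1.0), h=st.floats(1e-6, 1.0),
    fx=st.floats(0.0, 1.0), fy=st.floats(0.0, 1.0),
    side=st.sampled_from(["left", "right"]),
    toeing=st.sampled_from(["out", "in"]),
)
def test_mirror_symmetry_property(w, h, fx, fy, side, toeing):
    """Reflecting about the vertical midline and swapping sides preserves |theta|."""
    x = w / 2 + fx * (1 - w)
    y = h / 2 + fy * (1 - h)
    box = NormalizedBox(x, y, w, h)
    c = to_pixel_corners(box, D)
    mirrored = PixelCornerPair(D.width - c.p2x, c.p1y, D.width - c.p1x, c.p2y)
    m1 = signed_fpa(c, FootProfile(side, toeing))
    m2 = signed_fpa(mirrored, FootProfile(side, toeing).mirrored())
    if m1.missing:
        assert m2.missing
    else:
        # corner rounding (~ulp of the image width) is amplified by 1/box-size
        assert m2.theta == pytest.approx(m1.theta, abs=1e-6)
        # category flips only on the knife edge of a threshold
        if min(abs(m1.theta - t) for t in (0.0, 20.0)) > 1e-6:
            assert m1.category == m2.category
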