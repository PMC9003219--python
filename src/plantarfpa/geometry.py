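"""Box and angle geometry for foot-progression-angle (FPA) measurement.

A plantar pressure image carries two detection boxes: a *profile-box*
covering the whole footprint (used to classify left vs right foot) and an
*angle-box* spanning the foot axis from the heel to the metatarsal head.
The angle-box diagonal is the foot axis; which diagonal depends on the foot
profile.  The FPA is the angle between that diagonal and the direction of
progression (the vertical image axis):

    theta = arctan(A2 / A1)

where ``A1`` is the angle-box height and ``A2`` its width.

Coordinate conventions
----------------------
Image origin at the top-left; ``x`` increases rightward, ``y`` downward.
The forefoot sits at smaller row indices (top of the image), the heel at
larger ones.  Detection boxes arrive in normalized center/size form
(fractions of image width/height); corners are continuous pixel
coordinates, never rounded.

Sign convention
---------------
Out-toeing angles are positive, in-toeing angles negative.  The angle-box
alone cannot disambiguate the diagonal, so the sign is determined by the
profile's toeing class.  An adult FPA in the closed interval [0, 20]
degrees is classified normal; below 0 is in-toeing, above 20 out-toeing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import DegenerateBoxError, InvalidConfigError, InvalidInputError

_TOL = 1e-9

#: Adult normal range of the foot progression angle, degrees (closed interval).
DEFAULT_THRESHOLDS: Tuple[float, float] = (0.0, 20.0)
#: Paediatric normal range preset (children aged ~4-16), degrees.
CHILD_THRESHOLDS: Tuple[float, float] = (5.0, 13.0)

SIDES = ("left", "right")
TOEINGS = ("out", "in", "unknown")
CATEGORIES = ("in_toeing", "normal", "out_toeing")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageDims:
    """Pixel dimensions (W, H) of a pressure image."""

    width: int
    height: int

    def __post_init__(self) -> None:
        for name in ("width", "height"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise InvalidInputError(f"ImageDims.{name} must be an integer, got {v!r}")
            if v <= 0:
                raise InvalidInputError(f"ImageDims.{name} must be positive, got {v}")


@dataclass(frozen=True)
class NormalizedBox:
    """Detection box in fractional center/size coordinates.

    ``x``/``y`` locate the box center as fractions of image width/height;
    ``w``/``h`` are the box width/height as fractions.  The box must lie
    inside the unit square (to 1e-9).
    """

    x: float
    y: float
    w: float
    h: float
    class_label: str = ""
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v) or not (0.0 - _TOL <= v <= 1.0 + _TOL):
                raise InvalidInputError(
                    f"NormalizedBox.{name} must be a fraction in [0, 1], got {v!r}"
                )
        if self.x - self.w / 2 < -_TOL or self.x + self.w / 2 > 1 + _TOL:
            raise InvalidInputError(
                f"NormalizedBox extends beyond image width: x={self.x}, w={self.w}"
            )
        if self.y - self.h / 2 < -_TOL or self.y + self.h / 2 > 1 + _TOL:
            raise InvalidInputError(
                f"NormalizedBox extends beyond image height: y={self.y}, h={self.h}"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise InvalidInputError(
                f"NormalizedBox.confidence must be in [0, 1], got {self.confidence!r}"
            )


@dataclass(frozen=True)
class PixelCornerPair:
    """Top-left (P1) and bottom-right (P2) box corners in continuous pixels."""

    p1x: float
    p1y: float
    p2x: float
    p2y: float

    def __post_init__(self) -> None:
        if self.p1x > self.p2x + _TOL:
            raise InvalidInputError(f"PixelCornerPair requires P1x <= P2x ({self.p1x} > {self.p2x})")
        if self.p1y > self.p2y + _TOL:
            raise InvalidInputError(f"PixelCornerPair requires P1y <= P2y ({self.p1y} > {self.p2y})")

    @property
    def width(self) -> float:
        return self.p2x - self.p1x

    @property
    def height(self) -> float:
        return self.p2y - self.p1y

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class FootProfile:
    """Foot side (left/right) and toeing direction (out/in/unknown)."""

    side: str
    toeing: str = "out"

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise InvalidInputError(f"FootProfile.side must be one of {SIDES}, got {self.side!r}")
        if self.toeing not in TOEINGS:
            raise InvalidInputError(
                f"FootProfile.toeing must be one of {TOEINGS}, got {self.toeing!r}"
            )

    def mirrored(self) -> "FootProfile":
        """Profile of the horizontally mirrored foot (same toeing class)."""
        return FootProfile("right" if self.side == "left" else "left", self.toeing)


@dataclass(frozen=True)
class AxisPointPair:
    """Front (metatarsal) and rear (heel) endpoints of the foot axis, pixels."""

    front: Tuple[float, float]
    rear: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.front[1] > self.rear[1] + _TOL:
            raise InvalidInputError(
                "AxisPointPair requires front.y <= rear.y (forefoot at top of image); "
                f"got front={self.front}, rear={self.rear}"
            )


@dataclass(frozen=True)
class AngleBoxGeometry:
    """Angle-box height A1, width A2 and diagonal length A3, in pixels."""

    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise InvalidInputError(f"AngleBoxGeometry sides must be >= 0, got A1={self.a1}, A2={self.a2}")
        if abs(self.a3 - math.hypot(self.a1, self.a2)) > 1e-9 * max(1.0, self.a3):
            raise InvalidInputError("AngleBoxGeometry.a3 must equal hypot(a1, a2)")


@dataclass(frozen=True)
class GroundTruthPoints:
    """Annotated front (G1) and rear (G2) foot-axis points, pixels."""

    g1: Tuple[float, float]
    g2: Tuple[float, float]


@dataclass(frozen=True)
class FPAMeasurement:
    """A signed FPA measurement for one image.

    ``theta`` is in degrees, positive for out-toeing; ``missing`` flags
    images where no measurement could be made (degenerate or absent
    detection), in which case ``theta`` is NaN and ``category`` is None.
    """

    image_id: str
    profile: FootProfile
    theta: float
    category: Optional[str]
    axis: Optional[AxisPointPair] = None
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if not math.isfinite(self.theta) or not (-90.0 < self.theta < 90.0):
                raise InvalidInputError(
                    f"FPAMeasurement.theta must lie in (-90, 90) degrees, got {self.theta!r}"
                )
            if self.category not in CATEGORIES:
                raise InvalidInputError(f"Unknown FPA category {self.category!r}")


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def to_pixel_corners(box: NormalizedBox, dims: ImageDims) -> PixelCornerPair:
    """Convert a normalized center/size box to continuous pixel corners.

    P1x = (x - w/2) W,  P2x = (x + w/2) W,
    P1y = (y - h/2) H,  P2y = (y + h/2) H.
    """
    return PixelCornerPair(
        p1x=(box.x - box.w / 2.0) * dims.width,
        p1y=(box.y - box.h / 2.0) * dims.height,
        p2x=(box.x + box.w / 2.0) * dims.width,
        p2y=(box.y + box.h / 2.0) * dims.height,
    )


def to_normalized(
    corners: PixelCornerPair,
    dims: ImageDims,
    class_label: str = "",
    confidence: Optional[float] = None,
) -> NormalizedBox:
    """Inverse of :func:`to_pixel_corners` (round-trips to 1e-9)."""
    if corners.p1x < -_TOL * dims.width or corners.p2x > dims.width * (1 + _TOL):
        raise InvalidInputError(
            f"corners exceed image width {dims.width}: [{corners.p1x}, {corners.p2x}]"
        )
    if corners.p1y < -_TOL * dims.height or corners.p2y > dims.height * (1 + _TOL):
        raise InvalidInputError(
            f"corners exceed image height {dims.height}: [{corners.p1y}, {corners.p2y}]"
        )
    return NormalizedBox(
        x=(corners.p1x + corners.p2x) / (2.0 * dims.width),
        y=(corners.p1y + corners.p2y) / (2.0 * dims.height),
        w=(corners.p2x - corners.p1x) / dims.width,
        h=(corners.p2y - corners.p1y) / dims.height,
        class_label=class_label,
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# Diagonal selection (point benchmark acquisition)
# ---------------------------------------------------------------------------

def acquire_axis_points(corners: PixelCornerPair, profile: FootProfile) -> AxisPointPair:
    """Select the angle-box diagonal matching the foot profile.

    Out-toeing: the left foot axis runs top-left -> bottom-right, the right
    foot axis top-right -> bottom-left.  In-toeing mirrors the diagonal for
    each side (a left in-toeing foot uses the right-out pattern and vice
    versa).  The front point is always a top corner, the rear a bottom one.
    """
    if profile.toeing == "unknown":
        raise InvalidInputError("cannot select a diagonal for profile with toeing='unknown'")
    # Main-diagonal (TL->BR) profiles vs anti-diagonal (TR->BL) ones.
    main_diagonal = (profile.side == "left") == (profile.toeing == "out")
    if main_diagonal:
        front = (corners.p1x, corners.p1y)
        rear = (corners.p2x, corners.p2y)
    else:
        front = (corners.p2x, corners.p1y)
        rear = (corners.p1x, corners.p2y)
    return AxisPointPair(front=front, rear=rear)


def angle_geometry(corners: PixelCornerPair) -> AngleBoxGeometry:
    """Angle-box height A1, width A2 and diagonal A3 = sqrt(A1^2 + A2^2)."""
    a1 = corners.p2y - corners.p1y
    a2 = corners.p2x - corners.p1x
    return AngleBoxGeometry(a1=a1, a2=a2, a3=math.hypot(a1, a2))


def compute_theta(geom: AngleBoxGeometry) -> float:
    """Unsigned FPA in degrees: theta = arctan(A2 / A1), in [0, 90].

    A zero-height box with positive width gives 90 degrees; a zero-area box
    raises :class:`DegenerateBoxError`.
    """
    if geom.a1 == 0.0 and geom.a2 == 0.0:
        raise DegenerateBoxError("angle-box has zero area; FPA undefined")
    return math.degrees(math.atan2(geom.a2, geom.a1))


def classify_fpa(theta: float, thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Clinical FPA category: in_toeing (< low), normal ([low, high]), out_toeing (> high)."""
    low, high = thresholds
    if low >= high:
        raise InvalidConfigError(f"thresholds must satisfy low < high, got {thresholds}")
    if not math.isfinite(theta):
        raise InvalidInputError(f"theta must be finite, got {theta!r}")
    if theta < low:
        return "in_toeing"
    if theta > high:
        return "out_toeing"
    return "normal"


def signed_fpa(
    corners: PixelCornerPair,
    profile: FootProfile,
    image_id: str = "",
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
) -> FPAMeasurement:
    """Full per-image measurement: diagonal selection, arctangent, sign, category.

    The magnitude comes from the angle-box arctangent; the sign from the
    profile's toeing class (out positive, in negative).  A degenerate
    (zero-area) box yields a measurement with ``missing=True`` rather than
    an exception, mirroring the pipeline's missing-value exclusion.
    """
    axis = acquire_axis_points(corners, profile)
    try:
        theta = compute_theta(angle_geometry(corners))
    except DegenerateBoxError:
        theta = 90.0  # handled below: not a usable axis either
    if theta >= 90.0:  # zero-height box: no heel-to-forefoot axis exists
        return FPAMeasurement(
            image_id=image_id, profile=profile, theta=math.nan,
            category=None, axis=axis, missing=True,
        )
    if profile.toeing == "in":
        theta = -theta
    return FPAMeasurement(
        image_id=image_id,
        profile=profile,
        theta=theta,
        category=classify_fpa(theta, thresholds),
        axis=axis,
        missing=False,
    )


def theta_from_points(front: Tuple[float, float], rear: Tuple[float, float]) -> float:
    """Unsigned axis angle (degrees) of the segment front->rear vs vertical."""
    a2 = abs(front[0] - rear[0])
    a1 = rear[1] - front[1]
    return compute_theta(AngleBoxGeometry(a1=a1, a2=a2, a3=math.hypot(a1, a2)))
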