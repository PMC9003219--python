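"""Classical baseline detector for plantar pressure images.

Stands in for the trained object-detection networks so the measurement
pipeline runs end-to-end with no model weights: it segments the footprint
by relative thresholding, classifies the side from midfoot (arch)
asymmetry, and estimates the two foot-axis points as pressure-weighted
centroids of the metatarsal and heel bands.  Any component producing
:class:`DetectionResult` records — including files exported from an
external detector — can be swapped in; see :func:`detection_from_labels`.

All band parameters are fractions of the segmented footprint's row extent,
measured from its top (toe) edge, and are deliberately config-exposed:
real annotation protocols differ and these defaults are heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import io as pio
from .errors import InvalidInputError
from .geometry import (
    AxisPointPair,
    FootProfile,
    ImageDims,
    NormalizedBox,
    PixelCornerPair,
    to_normalized,
    to_pixel_corners,
)

#: Fraction of the maximum pressure below which a pixel is background.
DEFAULT_THRESHOLD_FRAC = 0.1
#: Pixel radius used to absorb satellite components near the main footprint.
DEFAULT_DILATION_RADIUS = 25.0
#: Gaussian pre-smoothing (pixels) applied before thresholding only; keeps
#: the support connected under sensor noise.  Centroids use raw pressures.
DEFAULT_SMOOTH_SIGMA = 2.0
#: Rows (fractions of foot extent from the top) excluded as toe region.
DEFAULT_TOE_CUT = 0.15
#: Metatarsal band: fractions of foot row extent from the top.
DEFAULT_MET_BAND = (0.15, 0.45)
#: Heel band.
DEFAULT_HEEL_BAND = (0.65, 1.0)
#: Midfoot band used for side classification.
DEFAULT_SIDE_BAND = (0.45, 0.65)
#: Minimum row/column extent ratio for a segment to count as a full foot.
DEFAULT_MIN_ASPECT = 2.0


@dataclass(frozen=True)
class DetectionResult:
    """Profile-box + angle-box detection for one image.

    ``missing=True`` means no usable detection (blank image or empty band);
    boxes and profile are then absent.
    """

    image_id: str
    profile_box: Optional[NormalizedBox]
    angle_box: Optional[NormalizedBox]
    profile: Optional[FootProfile]
    confidence: float = 0.0
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and (self.profile_box is not None or self.angle_box is not None):
            raise InvalidInputError("missing detection must not carry boxes")
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError(f"confidence must be in [0, 1], got {self.confidence}")


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InvalidInputError(f"pressure image must be 2-D, got shape {image.shape}")
    if (image < 0).any():
        raise InvalidInputError("pressure image must be non-negative")
    return image


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_foot(
    image: np.ndarray,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    dilation_radius: float = DEFAULT_DILATION_RADIUS,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
) -> Tuple[Optional[np.ndarray], Optional[NormalizedBox]]:
    """Segment the footprint and return (mask, normalized profile box).

    The image is lightly Gaussian-smoothed (``smooth_sigma`` pixels, for
    thresholding only) and pixels at or above ``threshold_frac`` of its
    maximum are foreground.  The largest connected component (by pressure
    mass) is kept, together with any component within ``dilation_radius``
    pixels of it — toes and noise speckle adjacent to the sole.  An
    all-zero image yields ``(None, None)`` (missing), not an exception.
    """
    image = _validate_image(image)
    if float(image.max()) <= 0.0:
        return None, None
    raw_mask = image >= threshold_frac * float(image.max())
    # connectivity is decided on a lightly smoothed image so sensor noise
    # cannot fracture the sole; the reported mask stays raw-thresholded
    smooth = ndimage.gaussian_filter(image, smooth_sigma) if smooth_sigma > 0 else image
    support = smooth >= threshold_frac * float(smooth.max())
    labels, n = ndimage.label(support | raw_mask)
    if n == 0:
        return None, None
    masses = ndimage.sum_labels(image, labels, index=np.arange(1, n + 1))
    main = int(np.argmax(masses)) + 1
    if n > 1:
        # components whose pixels fall within dilation_radius of the main one
        dist = ndimage.distance_transform_edt(labels != main)
        near = np.unique(labels[(dist <= dilation_radius) & (labels > 0)])
        keep = np.isin(labels, near)
    else:
        keep = labels == main
    keep &= raw_mask
    if not keep.any():
        return None, None
    rows = np.flatnonzero(keep.any(axis=1))
    cols = np.flatnonzero(keep.any(axis=0))
    dims = ImageDims(image.shape[1], image.shape[0])
    corners = PixelCornerPair(
        p1x=float(cols[0]), p1y=float(rows[0]),
        p2x=float(cols[-1] + 1), p2y=float(rows[-1] + 1),
    )
    return keep, to_normalized(corners, dims)


# ---------------------------------------------------------------------------
# Side classification
# ---------------------------------------------------------------------------

def classify_side(
    image: np.ndarray,
    mask: np.ndarray,
    side_band: Tuple[float, float] = DEFAULT_SIDE_BAND,
    tie_tol: float = 1e-9,
) -> Tuple[str, float]:
    """Classify left vs right foot from arch asymmetry; returns (side, confidence).

    Within the midfoot band of the footprint, the half of the foot box with
    the lower pressure mass is the medial (arch) side.  In this package's
    image convention the left foot's medial side is the image-right half.
    Confidence is 0.5 + 0.5 * |mass difference| / total; an exactly
    symmetric band ties to ``left`` with confidence 0.5.
    """
    image = _validate_image(image)
    if mask is None or not mask.any():
        raise InvalidInputError("classify_side requires a non-empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    top, extent = rows[0], rows[-1] + 1 - rows[0]
    r0 = top + int(round(side_band[0] * extent))
    r1 = top + int(round(side_band[1] * extent))
    mid = (cols[0] + cols[-1] + 1) / 2.0
    band = (image * mask)[r0:r1, :]
    col_idx = np.arange(image.shape[1]) + 0.5
    mass_left = float(band[:, col_idx < mid].sum())
    mass_right = float(band[:, col_idx >= mid].sum())
    total = mass_left + mass_right
    if total <= 0 or abs(mass_left - mass_right) <= tie_tol * max(total, 1.0):
        return "left", 0.5
    margin = abs(mass_left - mass_right) / total
    # lower-mass half is medial: medial-right => left foot
    side = "left" if mass_right < mass_left else "right"
    return side, 0.5 + 0.5 * margin


# ---------------------------------------------------------------------------
# Axis-point estimation
# ---------------------------------------------------------------------------

def estimate_axis_points(
    image: np.ndarray,
    mask: np.ndarray,
    toe_cut: float = DEFAULT_TOE_CUT,
    met_band: Tuple[float, float] = DEFAULT_MET_BAND,
    heel_band: Tuple[float, float] = DEFAULT_HEEL_BAND,
    min_aspect: float = DEFAULT_MIN_ASPECT,
) -> Optional[AxisPointPair]:
    """Estimate the foot-axis endpoints from pressure structure.

    Rows above ``toe_cut`` of the footprint extent are discarded (the
    angle-box excludes toes); the front point is the pressure-weighted
    centroid of the metatarsal band, the rear point that of the heel band.
    Returns None (missing) when a band holds no pressure or when the
    segment is not elongated enough to be a full footprint (row extent
    below ``min_aspect`` times the column extent — an isolated heel or
    forefoot fragment has no metatarsal-to-heel axis).
    """
    image = _validate_image(image)
    if mask is None or not mask.any():
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    top, extent = rows[0], rows[-1] + 1 - rows[0]
    if extent < min_aspect * (cols[-1] + 1 - cols[0]):
        return None

    def band_centroid(band: Tuple[float, float]) -> Optional[Tuple[float, float]]:
        r0 = top + int(round(max(band[0], toe_cut) * extent))
        r1 = top + int(round(band[1] * extent))
        sub = (image * mask)[r0:r1, :]
        total = float(sub.sum())
        if r1 <= r0 or total <= 0.0:
            return None
        ys, xs = np.mgrid[r0:r1, 0 : image.shape[1]]
        cx = float((sub * (xs + 0.5)).sum() / total)
        cy = float((sub * (ys + 0.5)).sum() / total)
        return (cx, cy)

    front = band_centroid(met_band)
    rear = band_centroid(heel_band)
    if front is None or rear is None:
        return None
    return AxisPointPair(front=front, rear=rear)


# ---------------------------------------------------------------------------
# Full detection
# ---------------------------------------------------------------------------

def detect(
    image: np.ndarray,
    image_id: str = "",
    mode: str = "two_class",
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    dilation_radius: float = DEFAULT_DILATION_RADIUS,
    toe_cut: float = DEFAULT_TOE_CUT,
    met_band: Tuple[float, float] = DEFAULT_MET_BAND,
    heel_band: Tuple[float, float] = DEFAULT_HEEL_BAND,
    side_band: Tuple[float, float] = DEFAULT_SIDE_BAND,
) -> DetectionResult:
    """Segment, classify and estimate boxes for one image.

    In ``four_class`` mode the toeing direction is read from the horizontal
    offset of the front point relative to the rear one (left foot: front
    left of rear means out-toeing); ``two_class`` mode fixes toeing=out.
    Any failed stage yields ``missing=True``.
    """
    if mode not in ("two_class", "four_class"):
        raise InvalidInputError(f"mode must be 'two_class' or 'four_class', got {mode!r}")
    image = _validate_image(image)
    dims = ImageDims(image.shape[1], image.shape[0])

    mask, profile_box = segment_foot(image, threshold_frac, dilation_radius)
    if mask is None:
        return DetectionResult(image_id, None, None, None, missing=True)
    side, confidence = classify_side(image, mask, side_band)
    axis = estimate_axis_points(image, mask, toe_cut, met_band, heel_band)
    if axis is None:
        return DetectionResult(image_id, None, None, None, missing=True)

    if mode == "two_class":
        toeing = "out"
    else:
        dx = axis.front[0] - axis.rear[0]
        outward = dx <= 0 if side == "left" else dx >= 0
        toeing = "out" if outward else "in"
    profile = FootProfile(side=side, toeing=toeing)

    corners = PixelCornerPair(
        p1x=min(axis.front[0], axis.rear[0]), p1y=axis.front[1],
        p2x=max(axis.front[0], axis.rear[0]), p2y=axis.rear[1],
    )
    angle_box = to_normalized(corners, dims, class_label="angle")
    profile_box = NormalizedBox(
        x=profile_box.x, y=profile_box.y, w=profile_box.w, h=profile_box.h,
        class_label=pio.profile_class_label(profile), confidence=confidence,
    )
    return DetectionResult(
        image_id=image_id,
        profile_box=profile_box,
        angle_box=angle_box,
        profile=profile,
        confidence=confidence,
        missing=False,
    )


# ---------------------------------------------------------------------------
# External detection adapters
# ---------------------------------------------------------------------------

def detection_from_labels(
    records: Sequence[pio.LabelRecord],
    mode: str = "two_class",
    image_id: Optional[str] = None,
) -> DetectionResult:
    """Adapt label records (one image) from an external detector.

    Expects at most one profile-class record and one angle-class record;
    the highest-confidence record wins per class.  An empty record list
    maps to a missing detection.
    """
    if not records:
        return DetectionResult(image_id or "", None, None, None, missing=True)
    if image_id is None:
        image_id = records[0].image_id
    angle_id = pio.angle_class_id(mode)

    def best(recs):
        return max(recs, key=lambda r: -1.0 if r.confidence is None else r.confidence, default=None)

    profile_rec = best([r for r in records if r.class_id != angle_id])
    angle_rec = best([r for r in records if r.class_id == angle_id])
    if profile_rec is None or angle_rec is None:
        return DetectionResult(image_id, None, None, None, missing=True)
    profile = pio.class_id_to_profile(profile_rec.class_id, mode)
    conf = profile_rec.confidence if profile_rec.confidence is not None else 1.0
    return DetectionResult(
        image_id=image_id,
        profile_box=profile_rec.box,
        angle_box=angle_rec.box,
        profile=profile,
        confidence=conf,
        missing=False,
    )


def detection_to_labels(result: DetectionResult, mode: str = "two_class") -> Sequence[pio.LabelRecord]:
    """Serialize a detection as label records ('class_id conf x y w h')."""
    if result.missing:
        return []
    return [
        pio.LabelRecord(
            image_id=result.image_id,
            class_id=pio.profile_class_id(result.profile, mode),
            box=result.profile_box,
            confidence=result.confidence,
        ),
        pio.LabelRecord(
            image_id=result.image_id,
            class_id=pio.angle_class_id(mode),
            box=result.angle_box,
            confidence=result.confidence,
        ),
    ]
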