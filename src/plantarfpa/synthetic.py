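"""Synthetic plantar-pressure images with a known foot-progression angle.

The generator renders a stylised single-foot pressure distribution as a sum
of anisotropic Gaussian blobs on the standard 120x400 canvas: a heel blob,
a low-pressure sole ridge running along the foot axis (keeping the
footprint contiguous, as real stance images are), a lateral midfoot blob
(the medial arch carries little load), a metatarsal band, and hallux plus
lesser-toe blobs strictly distal to the band.  It is a geometric phantom,
not a biomechanical simulation: its purpose is to exercise detection and
angle recovery with exact ground truth.

The foot axis runs from the heel-blob centre (rear point, G2) to the
metatarsal-band centre (front point, G1).  To impose a foot-progression
angle theta, everything distal to the heel is rigidly rotated about the
heel centre, so the rear ground-truth point is invariant under theta and
the angle recomputed from (G1, G2) equals the request exactly.  For a left
foot, positive (out-toeing) theta swings the forefoot toward the image
left; a right foot is the pixel-exact mirror of the left one about the
vertical midline.

Every sample carries four label artifacts: the ground-truth axis points,
the angle-box (tight box of the two points), the profile-box (tight box of
the noiseless footprint at 10% of peak pressure) and the profile class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .errors import InvalidConfigError, InvalidInputError
from .geometry import (
    AxisPointPair,
    FootProfile,
    GroundTruthPoints,
    ImageDims,
    NormalizedBox,
    PixelCornerPair,
    to_normalized,
)

#: Canvas of the pressure plates emulated here (width x height, pixels).
DEFAULT_DIMS = ImageDims(120, 400)

#: Hard bound on the supported rotation magnitude, degrees.
MAX_ABS_THETA = 30.0

#: Default ground-truth FPA distribution for out-toeing datasets: mean 5.58
#: degrees, SD 1.9 degrees, truncated to the adult normal range [0, 20].
DEFAULT_THETA_MEAN = 5.58
DEFAULT_THETA_SD = 1.9
THETA_TRUNCATION = (0.0, 20.0)

#: Default additive sensor noise, pressure units (5% of the heel peak).
DEFAULT_NOISE_SD = 5.0


# ---------------------------------------------------------------------------
# Template parameters
# ---------------------------------------------------------------------------

# Each blob is (lateral, axial, sigma_lateral, sigma_axial, peak) where the
# positional fields are fractions of foot_width (lateral; +u is the medial
# side of a left foot) and foot_length (axial, measured up from the heel
# centre); sigmas likewise; peak in arbitrary pressure units.
Blob = Tuple[float, float, float, float, float]


@dataclass(frozen=True)
class FootTemplateParams:
    """Geometry and peak pressures of the stylised foot, in canvas pixels.

    Defaults draw a ~260 px foot (heel centre to hallux centre) of ~64 px
    width on the 120x400 canvas, heel centre at 80% of image height.
    """

    foot_length: float = 240.0
    foot_width: float = 56.0
    heel_center: Tuple[float, float] = (0.5, 0.78)  # fractions of canvas (W, H)
    heel: Blob = (0.0, 0.0, 0.22, 0.070, 100.0)
    sole: Blob = (0.0, 0.45, 0.18, 0.260, 28.0)
    arch: Blob = (-0.25, 0.33, 0.17, 0.054, 25.0)
    metatarsal: Blob = (0.0, 0.58, 0.25, 0.046, 90.0)
    hallux: Blob = (0.22, 0.79, 0.125, 0.038, 80.0)
    lesser_toes: Tuple[Blob, ...] = (
        (-0.06, 0.775, 0.090, 0.022, 40.0),
        (-0.22, 0.760, 0.080, 0.020, 35.0),
        (-0.34, 0.750, 0.070, 0.019, 30.0),
    )

    def __post_init__(self) -> None:
        if self.foot_length <= 0 or self.foot_width <= 0:
            raise InvalidConfigError("foot_length and foot_width must be positive")
        for blob in self.blobs():
            if blob[2] <= 0 or blob[3] <= 0:
                raise InvalidConfigError(f"blob radii must be positive: {blob}")
            if blob[4] <= 0:
                raise InvalidConfigError(f"blob peak pressures must be positive: {blob}")
        # "strictly distal" for overlapping Gaussians: >= 1 sigma separation
        band_top = self.metatarsal[1] + self.metatarsal[3]
        for toe in (self.hallux, *self.lesser_toes):
            if toe[1] - toe[3] <= band_top - 1e-9:
                raise InvalidConfigError(
                    "toe blobs must lie strictly distal to the metatarsal band"
                )

    def blobs(self) -> Tuple[Blob, ...]:
        return (self.heel, self.sole, self.arch, self.metatarsal, self.hallux, *self.lesser_toes)

    @property
    def heel_peak(self) -> float:
        return self.heel[4]

    @property
    def axis_length(self) -> float:
        """Heel centre to metatarsal-band centre distance, pixels."""
        return self.metatarsal[1] * self.foot_length


DEFAULT_PARAMS = FootTemplateParams()


@dataclass(frozen=True)
class SyntheticSample:
    """One generated image with its full ground truth."""

    image: np.ndarray               # (H, W) non-negative pressure grid
    ground_truth: GroundTruthPoints
    profile: FootProfile
    angle_box: NormalizedBox
    profile_box: NormalizedBox
    theta: float                    # requested signed FPA, degrees
    seed: int
    dims: ImageDims = DEFAULT_DIMS


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_left(
    params: FootTemplateParams, dims: ImageDims, theta: float
) -> Tuple[np.ndarray, Tuple[float, float], Tuple[float, float]]:
    """Render the left-foot field at signed theta; return (grid, front, rear).

    Pressure is evaluated at pixel centres (col + 0.5, row + 0.5).  Blobs
    distal to the heel are rigidly rotated about the heel centre; positive
    theta swings the forefoot toward image-left.
    """
    w, h = dims.width, dims.height
    hx, hy = params.heel_center[0] * w, params.heel_center[1] * h
    t = math.radians(theta)
    cos_t, sin_t = math.cos(t), math.sin(t)

    xs = np.arange(w, dtype=np.float64) + 0.5
    ys = np.arange(h, dtype=np.float64) + 0.5
    gx, gy = np.meshgrid(xs, ys)  # (H, W)

    # The heel amplitude is solved so the total pressure at the heel centre
    # equals the configured heel peak despite overlapping neighbours.
    heel_amp = params.heel_peak
    for u_f, a_f, su_f, sa_f, peak in params.blobs()[1:]:
        u = u_f * params.foot_width
        a = a_f * params.foot_length
        heel_amp -= peak * math.exp(
            -0.5 * ((u / (su_f * params.foot_width)) ** 2 + (a / (sa_f * params.foot_length)) ** 2)
        )
    if heel_amp <= 0:
        raise InvalidConfigError("neighbouring blobs exceed the heel peak at the heel centre")

    grid = np.zeros((h, w), dtype=np.float64)
    for (u_f, a_f, su_f, sa_f, peak), amp in zip(
        params.blobs(), (heel_amp,) + tuple(b[4] for b in params.blobs()[1:])
    ):
        u = u_f * params.foot_width
        a = a_f * params.foot_length
        su = su_f * params.foot_width
        sa = sa_f * params.foot_length
        # rotate blob centre about the heel centre
        u_rot = u * cos_t - a * sin_t
        a_rot = u * sin_t + a * cos_t
        cx, cy = hx + u_rot, hy - a_rot
        dx, dy = gx - cx, gy - cy
        # project displacement onto the rotated lateral/axial blob axes
        lu = dx * cos_t - dy * sin_t
        la = -dx * sin_t - dy * cos_t
        grid += amp * np.exp(-0.5 * ((lu / su) ** 2 + (la / sa) ** 2))

    length = params.axis_length
    front = (hx - length * sin_t, hy - length * cos_t)
    rear = (hx, hy)
    # Gaussian tails may clip at the canvas edge (real plates truncate feet
    # the same way), but both axis landmarks must stay on the canvas.
    margin = 2.0
    for px, py in (front, rear):
        if not (margin <= px <= w - margin and margin <= py <= h - margin):
            raise InvalidConfigError(
                f"foot axis point ({px:.1f}, {py:.1f}) leaves the {w}x{h} canvas "
                f"at theta={theta:.2f} deg; shrink the template or the angle"
            )
    return grid, front, rear


def _support_box(grid: np.ndarray, dims: ImageDims, threshold_frac: float = 0.1) -> NormalizedBox:
    """Tight normalized box of pixels at or above threshold_frac * max."""
    mask = grid >= threshold_frac * float(grid.max())
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    corners = PixelCornerPair(
        p1x=float(cols[0]), p1y=float(rows[0]),
        p2x=float(cols[-1] + 1), p2y=float(rows[-1] + 1),
    )
    return to_normalized(corners, dims)


def make_template(
    side: str,
    params: FootTemplateParams = DEFAULT_PARAMS,
    dims: ImageDims = DEFAULT_DIMS,
) -> Tuple[np.ndarray, AxisPointPair]:
    """Unrotated (vertical-axis) foot template for one side.

    The right template is the pixel-exact mirror of the left about the
    vertical midline; the heel and metatarsal centroids share one x.
    """
    grid, front, rear = _render_left(params, dims, theta=0.0)
    if side == "right":
        grid = grid[:, ::-1].copy()
        front = (dims.width - front[0], front[1])
        rear = (dims.width - rear[0], rear[1])
    elif side != "left":
        raise InvalidInputError(f"side must be 'left' or 'right', got {side!r}")
    return grid, AxisPointPair(front=front, rear=rear)


# ---------------------------------------------------------------------------
# Sample and dataset generation
# ---------------------------------------------------------------------------

def generate_sample(
    profile: FootProfile,
    theta: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    dims: ImageDims = DEFAULT_DIMS,
    params: FootTemplateParams = DEFAULT_PARAMS,
) -> SyntheticSample:
    """Generate one labelled pressure image at the requested signed FPA.

    ``theta`` follows the package sign convention (out-toeing positive,
    in-toeing negative) and must be consistent with ``profile.toeing``.
    Gaussian noise of standard deviation ``noise_sd`` (pressure units) is
    added after rendering and clipped at zero.  Identical arguments and
    seed reproduce the grid bit-for-bit.
    """
    if not math.isfinite(theta) or abs(theta) > MAX_ABS_THETA:
        raise InvalidInputError(f"|theta| must be <= {MAX_ABS_THETA} degrees, got {theta!r}")
    if noise_sd < 0:
        raise InvalidInputError(f"noise_sd must be >= 0, got {noise_sd}")
    if profile.toeing == "unknown":
        raise InvalidInputError("generate_sample needs a resolved toeing class (out or in)")
    if theta > 0 and profile.toeing == "in" or theta < 0 and profile.toeing == "out":
        raise InvalidInputError(
            f"theta={theta} is inconsistent with toeing={profile.toeing!r} "
            "(out-toeing angles are positive, in-toeing negative)"
        )

    # Render in the canonical left-foot frame, then mirror for the right
    # side so left/right pairs are pixel-exact mirrors.
    grid, front, rear = _render_left(params, dims, theta)
    if profile.side == "right":
        grid = grid[:, ::-1].copy()
        front = (dims.width - front[0], front[1])
        rear = (dims.width - rear[0], rear[1])

    profile_box = _support_box(grid, dims)
    corners = PixelCornerPair(
        p1x=min(front[0], rear[0]), p1y=front[1],
        p2x=max(front[0], rear[0]), p2y=rear[1],
    )
    angle_box = to_normalized(corners, dims, class_label="angle")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = np.clip(grid + rng.normal(0.0, noise_sd, grid.shape), 0.0, None)

    return SyntheticSample(
        image=grid,
        ground_truth=GroundTruthPoints(g1=front, g2=rear),
        profile=profile,
        angle_box=angle_box,
        profile_box=replace(profile_box, class_label=pio.profile_class_label(profile)),
        theta=theta,
        seed=seed,
        dims=dims,
    )


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, bounds: Tuple[float, float]
) -> np.ndarray:
    """Truncated-normal magnitudes by rejection (exact, seed-deterministic)."""
    if sd == 0:
        lo, hi = bounds
        if not (lo <= mean <= hi):
            raise InvalidConfigError(f"theta_mean {mean} outside truncation bounds {bounds}")
        return np.full(n, float(mean))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        keep = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_dataset(
    n: int,
    out_dir: Optional[Path] = None,
    theta_mean: float = DEFAULT_THETA_MEAN,
    theta_sd: float = DEFAULT_THETA_SD,
    side_mix: float = 0.5,
    toeing_mix: float = 0.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    dims: ImageDims = DEFAULT_DIMS,
    params: FootTemplateParams = DEFAULT_PARAMS,
    write_png: bool = True,
) -> pd.DataFrame:
    """Generate a labelled dataset; returns (and optionally writes) its manifest.

    ``side_mix`` is the expected fraction of right feet, ``toeing_mix`` the
    expected fraction of in-toeing samples (0 reproduces the two-class,
    out-toeing-only setting).  FPA magnitudes are drawn from
    Normal(theta_mean, theta_sd) truncated to [0, 20] degrees; in-toeing
    samples carry the negative sign.  Everything is deterministic under
    ``seed``.  When ``out_dir`` is given, per-image pressure grids (CSV and
    optionally PNG), label files, a ground-truth point table and the
    manifest are written beneath it.
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    for name, frac in (("side_mix", side_mix), ("toeing_mix", toeing_mix)):
        if not 0.0 <= frac <= 1.0:
            raise InvalidConfigError(f"{name} must be in [0, 1], got {frac}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rights = rng.random(n) < side_mix
    intoes = rng.random(n) < toeing_mix
    magnitudes = _truncated_normal(rng, n, theta_mean, theta_sd, THETA_TRUNCATION)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    mode = "four_class" if toeing_mix > 0 else "two_class"
    samples = []
    rows = []
    for i in range(n):
        image_id = f"s{i:04d}"
        profile = FootProfile(
            side="right" if rights[i] else "left",
            toeing="in" if intoes[i] else "out",
        )
        theta = float(magnitudes[i]) * (-1.0 if profile.toeing == "in" else 1.0)
        sample = generate_sample(
            profile, theta, noise_sd=noise_sd, seed=int(child_seeds[i]),
            dims=dims, params=params,
        )
        samples.append((image_id, sample))
        rows.append(
            {
                "image_id": image_id,
                "side": profile.side,
                "toeing": profile.toeing,
                "theta": theta,
                "noise_sd": noise_sd,
                "seed": int(child_seeds[i]),
            }
        )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        write_dataset(samples, manifest, Path(out_dir), mode=mode, write_png=write_png)
    return manifest


def write_dataset(
    samples: Sequence[Tuple[str, SyntheticSample]],
    manifest: pd.DataFrame,
    out_dir: Path,
    mode: str = "two_class",
    write_png: bool = True,
) -> Dict[str, Path]:
    """Write grids, label files, ground-truth points and manifest to disk."""
    out_dir = Path(out_dir)
    images = out_dir / "images"
    labels = out_dir / "labels"
    images.mkdir(parents=True, exist_ok=True)
    labels.mkdir(parents=True, exist_ok=True)

    gt_points: Dict[str, GroundTruthPoints] = {}
    for image_id, sample in samples:
        pio.write_pressure_grid(sample.image, images / f"{image_id}.csv")
        if write_png:
            pio.write_pressure_grid(sample.image, images / f"{image_id}.png")
        records = [
            pio.LabelRecord(
                image_id=image_id,
                class_id=pio.profile_class_id(sample.profile, mode),
                box=sample.profile_box,
            ),
            pio.LabelRecord(
                image_id=image_id,
                class_id=pio.angle_class_id(mode),
                box=sample.angle_box,
            ),
        ]
        pio.write_labels(records, labels / f"{image_id}.txt")
        gt_points[image_id] = sample.ground_truth

    paths = {
        "images": images,
        "labels": labels,
        "gt_points": out_dir / "gt_points.csv",
        "manifest": out_dir / "manifest.csv",
    }
    pio.write_ground_truth_points(gt_points, paths["gt_points"])
    manifest.to_csv(paths["manifest"], index=False, float_format="%.17g")
    return paths
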