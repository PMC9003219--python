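"""Run orchestration: simulate -> measure -> evaluate.

The five-stage measurement procedure per image is: detect the foot profile,
detect the angle-box, convert it to pixel corners, select the
profile-appropriate diagonal and take the arctangent, then (when annotated
points are available) score the predicted axis points by their distance to
the ground truth.  This module wires those stages over directories of
images, with one top-level seed feeding every random stage and a
:class:`RunConfig` validated before anything runs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import detector, evaluation, synthetic
from . import io as pio
from .errors import EmptyEvaluationError, FormatError, InvalidConfigError
from .geometry import (
    DEFAULT_THRESHOLDS,
    FootProfile,
    ImageDims,
    signed_fpa,
    to_pixel_corners,
)

logger = logging.getLogger("plantarfpa")

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_IO = 3
EXIT_EMPTY_EVAL = 4


@dataclass
class RunConfig:
    """Validated configuration for every pipeline stage."""

    mode: str = "two_class"
    width: int = 120
    height: int = 400
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS
    # detector
    threshold_frac: float = detector.DEFAULT_THRESHOLD_FRAC
    dilation_radius: float = detector.DEFAULT_DILATION_RADIUS
    toe_cut: float = detector.DEFAULT_TOE_CUT
    met_band: Tuple[float, float] = detector.DEFAULT_MET_BAND
    heel_band: Tuple[float, float] = detector.DEFAULT_HEEL_BAND
    side_band: Tuple[float, float] = detector.DEFAULT_SIDE_BAND
    # AP
    iou_threshold: float = evaluation.DEFAULT_IOU_THRESHOLD
    ap_interpolation: str = "all_point"
    # statistics
    alpha: float = evaluation.DEFAULT_ALPHA
    # simulation
    n: int = 20
    theta_mean: float = synthetic.DEFAULT_THETA_MEAN
    theta_sd: float = synthetic.DEFAULT_THETA_SD
    side_mix: float = 0.5
    toeing_mix: float = 0.0
    noise_sd: float = synthetic.DEFAULT_NOISE_SD
    write_png: bool = True
    seed: int = 0
    # paths
    data_dir: Optional[Path] = None
    detections_dir: Optional[Path] = None
    out_dir: Path = Path("plantarfpa_run")

    def __post_init__(self) -> None:
        self.validate()

    @property
    def dims(self) -> ImageDims:
        return ImageDims(self.width, self.height)

    def validate(self) -> None:
        if self.mode not in ("two_class", "four_class"):
            raise InvalidConfigError(f"mode must be two_class or four_class, got {self.mode!r}")
        if self.width <= 0 or self.height <= 0:
            raise InvalidConfigError(f"image dims must be positive, got {self.width}x{self.height}")
        low, high = self.thresholds
        if low >= high:
            raise InvalidConfigError(f"thresholds must satisfy low < high, got {self.thresholds}")
        if not 0.0 < self.threshold_frac < 1.0:
            raise InvalidConfigError(f"threshold_frac must be in (0, 1), got {self.threshold_frac}")
        for name in ("met_band", "heel_band", "side_band"):
            b = getattr(self, name)
            if not (0.0 <= b[0] < b[1] <= 1.0):
                raise InvalidConfigError(f"{name} must be an increasing pair in [0, 1], got {b}")
        if not 0.0 <= self.toe_cut < 1.0:
            raise InvalidConfigError(f"toe_cut must be in [0, 1), got {self.toe_cut}")
        if not 0.0 < self.iou_threshold <= 1.0:
            raise InvalidConfigError(f"iou_threshold must be in (0, 1], got {self.iou_threshold}")
        if self.ap_interpolation not in ("all_point", "11_point"):
            raise InvalidConfigError(f"unknown ap_interpolation {self.ap_interpolation!r}")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n < 1:
            raise InvalidConfigError(f"n must be >= 1, got {self.n}")
        if self.theta_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigError("theta_sd and noise_sd must be >= 0")
        lo, hi = synthetic.THETA_TRUNCATION
        if not lo <= self.theta_mean <= hi:
            raise InvalidConfigError(
                f"theta_mean must lie in the truncation range {synthetic.THETA_TRUNCATION}"
            )
        for frac_name in ("side_mix", "toeing_mix"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{frac_name} must be in [0, 1], got {v}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise InvalidConfigError(f"seed must be a non-negative integer, got {self.seed!r}")

    @classmethod
    def from_yaml(cls, path: Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidConfigError(f"config file {path} must hold a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("data_dir", "detections_dir", "out_dir"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        for key in ("thresholds", "met_band", "heel_band", "side_band"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("data_dir", "detections_dir", "out_dir"):
            out[key] = None if out[key] is None else str(out[key])
        for key in ("thresholds", "met_band", "heel_band", "side_band"):
            out[key] = list(out[key])
        return out

    def dump(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _derived_seed(seed: int, stage: str) -> int:
    """Stage seed derived from the top-level one (documented, stable)."""
    stage_offsets = {"simulate": 0, "measure": 1, "evaluate": 2}
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=(stage_offsets[stage],)).generate_state(1)[0]
        & 0x7FFFFFFF
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig) -> Dict[str, Path]:
    """Generate a labelled synthetic dataset under ``out_dir/dataset``."""
    out = Path(config.out_dir) / "dataset"
    out.mkdir(parents=True, exist_ok=True)
    config.dump(Path(config.out_dir) / "config.yaml")
    synthetic.generate_dataset(
        n=config.n,
        out_dir=out,
        theta_mean=config.theta_mean,
        theta_sd=config.theta_sd,
        side_mix=config.side_mix,
        toeing_mix=config.toeing_mix,
        noise_sd=config.noise_sd,
        seed=_derived_seed(config.seed, "simulate"),
        dims=config.dims,
        write_png=config.write_png,
    )
    logger.info("simulated %d samples; manifest at %s", config.n, out / "manifest.csv")
    return {
        "dataset": out,
        "images": out / "images",
        "labels": out / "labels",
        "gt_points": out / "gt_points.csv",
        "manifest": out / "manifest.csv",
    }


def run_measure(
    config: RunConfig,
    images_dir: Optional[Path] = None,
    gt_points_path: Optional[Path] = None,
    manifest_path: Optional[Path] = None,
) -> Dict[str, object]:
    """Measure the FPA for every image; write the measurement table.

    Each image runs detect (or loads an external detection file from
    ``config.detections_dir``) -> pixel corners -> diagonal selection ->
    signed arctangent -> clinical category.  Missing detections are kept as
    flagged rows.  With ground-truth points, per-image front/rear distances
    are appended; manifest thetas populate ``gt_theta``.
    """
    t0 = time.perf_counter()
    data_dir = Path(config.data_dir) if config.data_dir else Path(config.out_dir) / "dataset"
    images_dir = Path(images_dir) if images_dir else data_dir / "images"
    if not images_dir.is_dir():
        raise FileNotFoundError(f"images directory not found: {images_dir}")
    if gt_points_path is None:
        candidate = data_dir / "gt_points.csv"
        gt_points_path = candidate if candidate.exists() else None
    if manifest_path is None:
        candidate = data_dir / "manifest.csv"
        manifest_path = candidate if candidate.exists() else None

    gt_points = pio.read_ground_truth_points(gt_points_path) if gt_points_path else {}
    gt_theta: Dict[str, float] = {}
    if manifest_path:
        man = pd.read_csv(manifest_path)
        if {"image_id", "theta"} <= set(man.columns):
            gt_theta = dict(zip(man["image_id"].astype(str), man["theta"].astype(float)))

    image_paths = sorted(images_dir.glob("*.csv"))
    if not image_paths:
        raise FileNotFoundError(f"no grid CSVs found in {images_dir}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    det_out = out_dir / "detections"
    det_out.mkdir(exist_ok=True)

    rows = []
    skipped_gt = []
    n_missing = 0
    for path in image_paths:
        image_id = path.stem
        if config.detections_dir is not None:
            det_path = Path(config.detections_dir) / f"{image_id}.txt"
            records = pio.read_labels(det_path, with_confidence=True, image_id=image_id)
            result = detector.detection_from_labels(records, mode=config.mode, image_id=image_id)
        else:
            grid = pio.read_pressure_grid(path)
            result = detector.detect(
                grid,
                image_id=image_id,
                mode=config.mode,
                threshold_frac=config.threshold_frac,
                dilation_radius=config.dilation_radius,
                toe_cut=config.toe_cut,
                met_band=config.met_band,
                heel_band=config.heel_band,
                side_band=config.side_band,
            )
            pio.write_labels(detector.detection_to_labels(result, config.mode), det_out / f"{image_id}.txt")

        row: Dict[str, object] = {"image_id": image_id}
        if result.missing:
            n_missing += 1
            row.update(
                side="", toeing="", theta=np.nan, category="",
                front_x=np.nan, front_y=np.nan, rear_x=np.nan, rear_y=np.nan,
                missing=True,
            )
        else:
            corners = to_pixel_corners(result.angle_box, config.dims)
            m = signed_fpa(corners, result.profile, image_id, config.thresholds)
            row.update(
                side=result.profile.side,
                toeing=result.profile.toeing,
                theta=m.theta,
                category=m.category or "",
                front_x=m.axis.front[0], front_y=m.axis.front[1],
                rear_x=m.axis.rear[0], rear_y=m.axis.rear[1],
                missing=m.missing,
            )
            if m.missing:
                n_missing += 1
        if image_id in gt_theta:
            row["gt_theta"] = gt_theta[image_id]
        if gt_points:
            if image_id in gt_points and not row["missing"]:
                g = gt_points[image_id]
                row["d_front"] = evaluation.point_distance(g.g1, (row["front_x"], row["front_y"]))
                row["d_rear"] = evaluation.point_distance(g.g2, (row["rear_x"], row["rear_y"]))
            elif image_id not in gt_points:
                skipped_gt.append(image_id)
        rows.append(row)

    if skipped_gt:
        logger.warning(
            "%d image(s) without ground-truth points, excluded from distances: %s",
            len(skipped_gt), ", ".join(skipped_gt),
        )

    table = pd.DataFrame(rows)
    measurements_path = out_dir / "measurements.csv"
    pio.write_measurements(table, measurements_path)

    summary = {
        "counts": {"total": len(rows), "measured": len(rows) - n_missing, "missing": n_missing},
        "no_ground_truth": skipped_gt,
        "outputs": {
            "measurements": str(measurements_path),
            "detections": str(det_out),
        },
        "timings": {"measure_s": time.perf_counter() - t0},
    }
    pio.write_report({k: v for k, v in summary.items() if k != "tables"}, out_dir / "run_summary.json")
    return {"table": table, "measurements_path": measurements_path, "summary": summary}


def run_evaluate(
    config: RunConfig,
    measurement_paths: Mapping[str, Path],
    gt_points_path: Optional[Path] = None,
    manifest_path: Optional[Path] = None,
    labels_dir: Optional[Path] = None,
    detections_dirs: Optional[Mapping[str, Path]] = None,
) -> dict:
    """Score one or more measurement tables against ground truth.

    Emits the distance and FPA statistics of :func:`evaluation.evaluate_run`
    plus, when label and detection files are on disk, per-class AP and mAP
    of profile- and angle-boxes.
    """
    data_dir = Path(config.data_dir) if config.data_dir else Path(config.out_dir) / "dataset"
    gt_points_path = Path(gt_points_path) if gt_points_path else data_dir / "gt_points.csv"
    if not Path(gt_points_path).exists():
        raise FileNotFoundError(f"ground-truth point table not found: {gt_points_path}")
    if manifest_path is None:
        candidate = data_dir / "manifest.csv"
        manifest_path = candidate if candidate.exists() else None

    gt_points = pio.read_ground_truth_points(gt_points_path)
    gt_angles = None
    if manifest_path:
        man = pd.read_csv(manifest_path)
        if {"image_id", "theta"} <= set(man.columns):
            gt_angles = dict(zip(man["image_id"].astype(str), man["theta"].astype(float)))

    measurements = {
        name: pio.read_measurements(Path(p)) for name, p in measurement_paths.items()
    }
    report = evaluation.evaluate_run(measurements, gt_points, gt_angles, alpha=config.alpha)

    if labels_dir is None:
        candidate = data_dir / "labels"
        labels_dir = candidate if candidate.is_dir() else None
    if detections_dirs is None:
        candidate = Path(config.out_dir) / "detections"
        detections_dirs = {"baseline": candidate} if candidate.is_dir() else {}
    if labels_dir is not None and detections_dirs:
        report["detection_metrics"] = {
            name: _detection_metrics(config, Path(labels_dir), Path(det_dir))
            for name, det_dir in detections_dirs.items()
        }

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "report.json"
    pio.write_report(report, report_path)
    report["report_path"] = str(report_path)
    return report


def _detection_metrics(config: RunConfig, labels_dir: Path, det_dir: Path) -> dict:
    """AP per class and mAP of detections against ground-truth label files."""
    names = pio.class_names(config.mode)
    gts: Dict[int, Dict[str, object]] = {i: {} for i in range(len(names))}
    dets: Dict[int, list] = {i: [] for i in range(len(names))}
    for lp in sorted(labels_dir.glob("*.txt")):
        for rec in pio.read_labels(lp):
            gts[rec.class_id][rec.image_id] = to_pixel_corners(rec.box, config.dims)
    for dp in sorted(det_dir.glob("*.txt")):
        for rec in pio.read_labels(dp, with_confidence=True):
            dets[rec.class_id].append(
                evaluation.Detection(
                    image_id=rec.image_id,
                    confidence=rec.confidence if rec.confidence is not None else 1.0,
                    corners=to_pixel_corners(rec.box, config.dims),
                )
            )
    per_class = {}
    for class_id, name in enumerate(names):
        if gts[class_id]:
            per_class[name] = evaluation.average_precision(
                dets[class_id], gts[class_id],
                iou_threshold=config.iou_threshold,
                interpolation=config.ap_interpolation,
            )
    profile_aps = {n: ap for n, ap in per_class.items() if n != "angle"}
    out = {"per_class_ap": per_class}
    if profile_aps:
        out["map_profile"] = evaluation.mean_average_precision(profile_aps)
    if "angle" in per_class:
        out["ap_angle"] = per_class["angle"]
    return out


def run_all(config: RunConfig) -> dict:
    """simulate -> measure -> evaluate in one output directory."""
    paths = run_simulate(config)
    measure = run_measure(config, images_dir=paths["images"],
                          gt_points_path=paths["gt_points"], manifest_path=paths["manifest"])
    report = run_evaluate(
        config,
        measurement_paths={"baseline": measure["measurements_path"]},
        gt_points_path=paths["gt_points"],
        manifest_path=paths["manifest"],
        labels_dir=paths["labels"],
    )
    return {"paths": paths, "measure": measure, "report": report}
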