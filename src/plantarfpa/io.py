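"""Readers and writers for every on-disk artifact.

Formats
-------
* Pressure grids: plain CSV matrices (full precision) or 8-bit grayscale
  PNG (scaled so the grid maximum maps to 255).
* Detection/label files: whitespace-delimited, one object per line,
  ``class_id x y w h`` with fractional center/size coordinates, optionally
  ``class_id conf x y w h`` for detector output.  Blank lines and ``#``
  comments are skipped.  Class ids are 0-based against a declared class
  list: two-class mode uses (left, right, angle); four-class mode
  (left_in, left_out, right_in, right_out, angle).
* Ground-truth axis points: CSV with header ``image_id,G1x,G1y,G2x,G2y``.
* Measurement tables: CSV at full precision plus a fixed-width display
  companion with angles shown to 2 decimals.
* Run reports: JSON (sorted keys) plus one CSV per embedded table.

Parsers never coerce invalid records; they raise :class:`FormatError`
naming the file and line.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError
from .geometry import FootProfile, GroundTruthPoints, NormalizedBox

TWO_CLASS_NAMES = ("left", "right", "angle")
FOUR_CLASS_NAMES = ("left_in", "left_out", "right_in", "right_out", "angle")

_GT_COLUMNS = ["image_id", "G1x", "G1y", "G2x", "G2y"]

MEASUREMENT_COLUMNS = [
    "image_id", "side", "toeing", "theta", "category",
    "front_x", "front_y", "rear_x", "rear_y", "missing",
    "gt_theta", "d_front", "d_rear",
]


# ---------------------------------------------------------------------------
# Class lists
# ---------------------------------------------------------------------------

def class_names(mode: str) -> Sequence[str]:
    if mode == "two_class":
        return TWO_CLASS_NAMES
    if mode == "four_class":
        return FOUR_CLASS_NAMES
    raise InvalidInputError(f"mode must be 'two_class' or 'four_class', got {mode!r}")


def profile_class_label(profile: FootProfile) -> str:
    return profile.side if profile.toeing == "out" else f"{profile.side}_{profile.toeing}"


def profile_class_id(profile: FootProfile, mode: str) -> int:
    names = class_names(mode)
    if mode == "two_class":
        return names.index(profile.side)
    return names.index(f"{profile.side}_{profile.toeing}")


def angle_class_id(mode: str) -> int:
    return len(class_names(mode)) - 1


def class_id_to_profile(class_id: int, mode: str) -> FootProfile:
    """Profile encoded by a profile-box class id (angle class is invalid here)."""
    names = class_names(mode)
    if not 0 <= class_id < len(names) - 1:
        raise InvalidInputError(f"class id {class_id} is not a profile class in {mode}")
    name = names[class_id]
    if "_" in name:
        side, toeing = name.split("_")
        return FootProfile(side=side, toeing=toeing)
    return FootProfile(side=name, toeing="out")


# ---------------------------------------------------------------------------
# Pressure grids
# ---------------------------------------------------------------------------

def read_pressure_grid(path: Path) -> np.ndarray:
    """Read a pressure grid from a CSV matrix or a grayscale image file."""
    path = Path(path)
    if not path.exists():
        raise FormatError("pressure grid file not found", path=path)
    if path.suffix.lower() in {".png", ".tif", ".tiff"}:
        arr = np.asarray(iio.imread(path), dtype=np.float64)
        if arr.ndim == 3:  # collapse an unexpected colour axis only if grayscale
            if not (arr == arr[..., :1]).all():
                raise FormatError("image is not grayscale", path=path)
            arr = arr[..., 0]
        if arr.ndim != 2:
            raise FormatError(f"expected a 2-D image, got shape {arr.shape}", path=path)
        return arr

    rows: List[List[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            try:
                values = [float(c) for c in cells]
            except ValueError as exc:
                raise FormatError(f"non-numeric cell: {exc}", path=path, line=lineno) from None
            for col, v in enumerate(values):
                if not math.isfinite(v) or v < 0:
                    raise FormatError(
                        f"pressure must be finite and non-negative, got {v} at column {col + 1}",
                        path=path, line=lineno,
                    )
            if rows and len(values) != len(rows[0]):
                raise FormatError(
                    f"ragged row: {len(values)} cells, expected {len(rows[0])}",
                    path=path, line=lineno,
                )
            rows.append(values)
    if not rows:
        raise FormatError("empty pressure grid", path=path)
    return np.asarray(rows, dtype=np.float64)


def write_pressure_grid(grid: np.ndarray, path: Path) -> None:
    """Write a grid as CSV (full precision) or 8-bit grayscale PNG by suffix."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2:
        raise InvalidInputError(f"pressure grid must be 2-D, got shape {grid.shape}")
    path = Path(path)
    if path.suffix.lower() == ".png":
        peak = float(grid.max())
        scaled = (grid / peak * 255.0) if peak > 0 else grid
        iio.imwrite(path, np.round(scaled).astype(np.uint8))
        return
    with open(path, "w", encoding="utf-8") as fh:
        for row in grid:
            fh.write(",".join(format(v, ".17g") for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Label / detection files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelRecord:
    """One object annotation or detection in normalized box coordinates."""

    image_id: str
    class_id: int
    box: NormalizedBox
    confidence: Optional[float] = None


def read_labels(
    path: Path,
    with_confidence: bool = False,
    image_id: Optional[str] = None,
) -> List[LabelRecord]:
    """Parse a label file; ``with_confidence`` selects the 6-token dialect."""
    path = Path(path)
    if not path.exists():
        raise FormatError("label file not found", path=path)
    if image_id is None:
        image_id = path.stem
    n_tokens = 6 if with_confidence else 5
    records: List[LabelRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != n_tokens:
                raise FormatError(
                    f"expected {n_tokens} fields, got {len(tokens)}", path=path, line=lineno
                )
            try:
                class_id = int(tokens[0])
                values = [float(t) for t in tokens[1:]]
            except ValueError as exc:
                raise FormatError(f"unparsable field: {exc}", path=path, line=lineno) from None
            conf = values[0] if with_confidence else None
            x, y, w, h = values[-4:]
            try:
                box = NormalizedBox(x=x, y=y, w=w, h=h, confidence=conf)
            except InvalidInputError as exc:
                raise FormatError(str(exc), path=path, line=lineno) from None
            if class_id < 0:
                raise FormatError(f"negative class id {class_id}", path=path, line=lineno)
            records.append(
                LabelRecord(image_id=image_id, class_id=class_id, box=box, confidence=conf)
            )
    return records


def write_labels(records: Sequence[LabelRecord], path: Path) -> None:
    """Write label records; emits the confidence column iff any record has one."""
    with_conf = any(r.confidence is not None for r in records)
    with open(Path(path), "w", encoding="utf-8") as fh:
        for r in records:
            fields = [str(r.class_id)]
            if with_conf:
                conf = 0.0 if r.confidence is None else r.confidence
                fields.append(format(conf, ".17g"))
            fields += [format(v, ".17g") for v in (r.box.x, r.box.y, r.box.w, r.box.h)]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Ground-truth axis points
# ---------------------------------------------------------------------------

def read_ground_truth_points(path: Path) -> Dict[str, GroundTruthPoints]:
    path = Path(path)
    if not path.exists():
        raise FormatError("ground-truth point table not found", path=path)
    df = pd.read_csv(path)
    missing_cols = [c for c in _GT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing columns {missing_cols}", path=path)
    ids = df["image_id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicate image_id(s): {sorted(set(dup))}", path=path)
    out: Dict[str, GroundTruthPoints] = {}
    for _, row in df.iterrows():
        out[str(row["image_id"])] = GroundTruthPoints(
            g1=(float(row["G1x"]), float(row["G1y"])),
            g2=(float(row["G2x"]), float(row["G2y"])),
        )
    return out


def write_ground_truth_points(points: Mapping[str, GroundTruthPoints], path: Path) -> None:
    rows = [
        {"image_id": image_id, "G1x": p.g1[0], "G1y": p.g1[1], "G2x": p.g2[0], "G2y": p.g2[1]}
        for image_id, p in points.items()
    ]
    pd.DataFrame(rows, columns=_GT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def write_measurements(table: pd.DataFrame, path: Path) -> None:
    """Write a measurement table: full-precision CSV plus a display companion.

    The CSV retains full float precision; ``<stem>_display.txt`` shows
    angles and distances to 2 decimals for reading.  Missing rows keep an
    explicit ``missing`` flag and are never dropped.
    """
    path = Path(path)
    cols = [c for c in MEASUREMENT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table = table[cols + extra]
    table.to_csv(path, index=False, float_format="%.17g")

    display = table.copy()
    for col in ("theta", "gt_theta", "d_front", "d_rear",
                "front_x", "front_y", "rear_x", "rear_y"):
        if col in display.columns:
            display[col] = display[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.2f}"
            )
    with open(path.with_name(path.stem + "_display.txt"), "w", encoding="utf-8") as fh:
        fh.write(display.to_string(index=False))
        fh.write("\n")


def read_measurements(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError("measurement table not found", path=path)
    df = pd.read_csv(path)
    if "image_id" not in df.columns or "missing" not in df.columns:
        raise FormatError("not a measurement table (needs image_id and missing columns)", path=path)
    df["image_id"] = df["image_id"].astype(str)
    df["missing"] = df["missing"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Run reports
# ---------------------------------------------------------------------------

def write_report(report: Mapping, path: Path) -> None:
    """Serialize a run report as JSON; embedded tables also land as CSVs.

    ``report['tables']``, when present, maps table names to lists of row
    dicts; each is written to ``<stem>_<table>.csv`` next to the JSON.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, rows in (report.get("tables") or {}).items():
        pd.DataFrame(rows).to_csv(
            path.with_name(f"{path.stem}_{name}.csv"), index=False, float_format="%.17g"
        )


def read_report(path: Path) -> dict:
    with open(Path(path), "r", encoding="utf-8") as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
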