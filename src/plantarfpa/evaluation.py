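"""Comparison machinery: point distances, detection AP/mAP, and statistics.

Predicted foot-axis points are scored against annotated ones with the
Euclidean two-point distance (front |G1P1| and rear |G2P2| separately).
Detection quality uses IoU-matched average precision with all-point
precision-recall interpolation by default (an 11-point mode is available).
The statistical battery mirrors common gait-lab practice: mean +/- SE per
group, paired t-tests within model, one-way ANOVA across models and
Fisher's LSD post hoc (unadjusted pairwise t using the pooled ANOVA error
variance) at alpha = 0.01.

Test statistics are computed from their defining formulas; only the t- and
F-distribution tail probabilities come from scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTestError,
    EmptyEvaluationError,
    InvalidInputError,
    UndefinedAPError,
)
from .geometry import GroundTruthPoints, PixelCornerPair

DEFAULT_ALPHA = 0.01
DEFAULT_IOU_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Distances and IoU
# ---------------------------------------------------------------------------

def point_distance(g: Tuple[float, float], p: Tuple[float, float]) -> float:
    """Euclidean distance between an annotated and a predicted point, pixels."""
    for pt in (g, p):
        if not all(math.isfinite(v) for v in pt):
            raise InvalidInputError(f"points must have finite coordinates, got {pt}")
    return math.hypot(g[0] - p[0], g[1] - p[1])


def iou(a: PixelCornerPair, b: PixelCornerPair) -> float:
    """Intersection-over-union of two corner boxes; 0 for disjoint or zero union."""
    ix = max(0.0, min(a.p2x, b.p2x) - max(a.p1x, b.p1x))
    iy = max(0.0, min(a.p2y, b.p2y) - max(a.p1y, b.p1y))
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Detection:
    """One scored detection of a single class."""

    image_id: str
    confidence: float
    corners: PixelCornerPair


def average_precision(
    detections: Sequence[Detection],
    ground_truths: Mapping[str, PixelCornerPair],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    interpolation: str = "all_point",
) -> float:
    """AP of one class against at most one ground-truth box per image.

    Detections are ranked by descending confidence (ties broken by
    image_id for determinism); a detection is a true positive when its IoU
    with the image's still-unmatched ground truth reaches the threshold.
    AP integrates the interpolated precision-recall curve: ``all_point``
    (continuous) or ``11_point``.
    """
    if not ground_truths:
        raise UndefinedAPError("AP is undefined without ground-truth boxes")
    if interpolation not in ("all_point", "11_point"):
        raise InvalidInputError(f"unknown interpolation {interpolation!r}")
    n_gt = len(ground_truths)
    if not detections:
        return 0.0

    order = sorted(detections, key=lambda d: (-d.confidence, d.image_id))
    matched: set = set()
    tp = np.zeros(len(order))
    for i, det in enumerate(order):
        gt = ground_truths.get(det.image_id)
        if gt is not None and det.image_id not in matched and iou(det.corners, gt) >= iou_threshold:
            tp[i] = 1.0
            matched.add(det.image_id)
    cum_tp = np.cumsum(tp)
    precision = cum_tp / (np.arange(len(order)) + 1.0)
    recall = cum_tp / n_gt

    if interpolation == "11_point":
        ap = 0.0
        for r in np.linspace(0.0, 1.0, 11):
            mask = recall >= r - 1e-12
            ap += (precision[mask].max() if mask.any() else 0.0) / 11.0
        return float(ap)

    # all-point: integrate the running-max precision envelope over recall
    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([0.0], precision, [0.0]))
    p = np.maximum.accumulate(p[::-1])[::-1]
    steps = np.flatnonzero(np.diff(r) > 0)
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def mean_average_precision(per_class_ap: Mapping[str, float]) -> float:
    """Unweighted mean of per-class APs."""
    if not per_class_ap:
        raise UndefinedAPError("mAP is undefined without per-class APs")
    return float(np.mean(list(per_class_ap.values())))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatReport:
    """Outcome of one statistical test at significance level alpha."""

    test: str
    statistic: float
    df: Tuple[float, ...]
    p_value: float
    alpha: float
    significant: bool
    group_labels: Tuple[str, ...] = ()
    group_means: Tuple[float, ...] = ()
    group_ses: Tuple[float, ...] = ()
    pairwise: Tuple["PairwiseComparison", ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PairwiseComparison:
    """One LSD pairwise contrast (unadjusted two-sided p)."""

    label_a: str
    label_b: str
    mean_diff: float
    statistic: float
    df: float
    p_value: float
    significant: bool


def mean_se(values: Sequence[float]) -> Tuple[float, float]:
    """Mean and standard error (sample SD with n-1 denominator over sqrt n)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise InvalidInputError(f"mean_se needs at least 2 values, got {v.size}")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def paired_t_test(
    a: Sequence[float], b: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> StatReport:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InvalidInputError("paired_t_test needs two equal-length 1-D samples, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateTestError("paired differences have zero variance")
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return StatReport(
        test="paired_t",
        statistic=t,
        df=(float(df),),
        p_value=p,
        alpha=alpha,
        significant=p < alpha,
        group_labels=("a", "b"),
        group_means=(float(a.mean()), float(b.mean())),
        group_ses=(mean_se(a)[1], mean_se(b)[1]),
    )


def _group_arrays(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise InvalidInputError("need >= 2 groups, each with n >= 2")
    return arrs


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> StatReport:
    """One-way ANOVA: F = (SSB/(k-1)) / (SSW/(N-k))."""
    arrs = _group_arrays(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    all_values = np.concatenate(arrs)
    grand = all_values.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    k = len(arrs)
    n_total = all_values.size
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0 and ssb == 0.0:
        raise DegenerateTestError("all values identical; ANOVA undefined")
    if ssw == 0.0:
        raise DegenerateTestError("zero within-group variance; ANOVA undefined")
    f_stat = float((ssb / df_b) / (ssw / df_w))
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return StatReport(
        test="one_way_anova",
        statistic=f_stat,
        df=(float(df_b), float(df_w)),
        p_value=p,
        alpha=alpha,
        significant=p < alpha,
        group_labels=tuple(labels),
        group_means=tuple(float(a.mean()) for a in arrs),
        group_ses=tuple(mean_se(a)[1] for a in arrs),
    )


def fisher_lsd(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> StatReport:
    """Fisher's least-significant-difference post hoc.

    Pairwise t = (m_i - m_j) / sqrt(MSE (1/n_i + 1/n_j)) with the pooled
    within-group mean square from the ANOVA and df = N - k; p-values are
    unadjusted by definition.
    """
    arrs = _group_arrays(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    anova = one_way_anova(groups, labels=labels, alpha=alpha)
    df_w = anova.df[1]
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    mse = ssw / df_w
    comparisons = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            diff = float(arrs[i].mean() - arrs[j].mean())
            se = math.sqrt(mse * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), df_w))
            comparisons.append(
                PairwiseComparison(
                    label_a=labels[i], label_b=labels[j], mean_diff=diff,
                    statistic=float(t), df=float(df_w), p_value=p,
                    significant=p < alpha,
                )
            )
    return StatReport(
        test="fisher_lsd",
        statistic=anova.statistic,
        df=anova.df,
        p_value=anova.p_value,
        alpha=alpha,
        significant=anova.significant,
        group_labels=tuple(labels),
        group_means=anova.group_means,
        group_ses=anova.group_ses,
        pairwise=tuple(comparisons),
    )


# ---------------------------------------------------------------------------
# Run-level evaluation
# ---------------------------------------------------------------------------

def _stat_or_degenerate(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs).to_dict()
    except DegenerateTestError as exc:
        return {"degenerate": True, "reason": str(exc)}


def evaluate_run(
    measurements: Mapping[str, pd.DataFrame],
    gt_points: Mapping[str, GroundTruthPoints],
    gt_angles: Optional[Mapping[str, float]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Compare one or more models' measurement tables against ground truth.

    Missing measurements are excluded pairwise (the ids dropped from every
    joint comparison are the union of each model's missing rows) and the
    exclusion counts are always reported.  The report carries, per model,
    the FPA mean +/- SE with ANOVA + LSD against the ground-truth angles;
    the front/rear point-distance means +/- SE with ANOVA + LSD across
    models; and a paired t-test of front vs rear distance within model.

    ``gt_angles`` maps image_id to the signed ground-truth FPA; when
    absent, the angle is recomputed from the ground-truth points with the
    sign taken from each model's toeing label.
    """
    if not measurements:
        raise InvalidInputError("evaluate_run needs at least one measurement table")

    tables: Dict[str, pd.DataFrame] = {}
    excluded_per_model: Dict[str, int] = {}
    missing_ids: set = set()
    for name, df in measurements.items():
        df = df.copy()
        df["image_id"] = df["image_id"].astype(str)
        df = df.set_index("image_id")
        tables[name] = df
        model_missing = set(df.index[df["missing"].astype(bool)])
        excluded_per_model[name] = len(model_missing)
        missing_ids |= model_missing

    common = set(str(k) for k in gt_points)
    for df in tables.values():
        common &= set(df.index)
    used = sorted(common - missing_ids)
    if not used:
        raise EmptyEvaluationError("no overlapping non-missing images to evaluate")

    def signed_gt_theta(image_id: str, toeing: str) -> float:
        if gt_angles is not None and image_id in gt_angles:
            return float(gt_angles[image_id])
        g = gt_points[image_id]
        a2 = abs(g.g1[0] - g.g2[0])
        a1 = g.g2[1] - g.g1[1]
        magnitude = math.degrees(math.atan2(a2, a1))
        return -magnitude if toeing == "in" else magnitude

    model_names = sorted(tables)
    report: dict = {
        "n_total": int(len(set(str(k) for k in gt_points))),
        "n_used": len(used),
        "n_excluded": len(missing_ids),
        "excluded_per_model": excluded_per_model,
        "alpha": alpha,
        "models": model_names,
        "tables": {},
    }

    # --- FPA per model vs ground truth -------------------------------------
    first = model_names[0]
    gt_thetas = [
        signed_gt_theta(i, str(tables[first].loc[i, "toeing"])) for i in used
    ]
    fpa_groups = [gt_thetas]
    fpa_labels = ["ground_truth"]
    fpa_rows = [{"model": "ground_truth", **_mean_se_row(gt_thetas)}]
    for name in model_names:
        thetas = [float(tables[name].loc[i, "theta"]) for i in used]
        fpa_groups.append(thetas)
        fpa_labels.append(name)
        fpa_rows.append({"model": name, **_mean_se_row(thetas)})
    report["fpa"] = {
        "per_group": fpa_rows,
        "anova_lsd": _stat_or_degenerate(fisher_lsd, fpa_groups, labels=fpa_labels, alpha=alpha),
    }
    report["tables"]["fpa"] = fpa_rows

    # --- point distances ----------------------------------------------------
    dist_front: Dict[str, List[float]] = {}
    dist_rear: Dict[str, List[float]] = {}
    for name in model_names:
        df = tables[name]
        fronts, rears = [], []
        for i in used:
            g = gt_points[i]
            fronts.append(point_distance(g.g1, (float(df.loc[i, "front_x"]), float(df.loc[i, "front_y"]))))
            rears.append(point_distance(g.g2, (float(df.loc[i, "rear_x"]), float(df.loc[i, "rear_y"]))))
        dist_front[name] = fronts
        dist_rear[name] = rears

    dist_rows = []
    front_vs_rear = {}
    for name in model_names:
        dist_rows.append(
            {
                "model": name,
                "d_front_mean": float(np.mean(dist_front[name])),
                "d_front_se": mean_se(dist_front[name])[1] if len(used) > 1 else math.nan,
                "d_rear_mean": float(np.mean(dist_rear[name])),
                "d_rear_se": mean_se(dist_rear[name])[1] if len(used) > 1 else math.nan,
            }
        )
        if len(used) > 1:
            front_vs_rear[name] = _stat_or_degenerate(
                paired_t_test, dist_front[name], dist_rear[name], alpha=alpha
            )
    report["distances"] = {"per_model": dist_rows}
    report["tables"]["distances"] = dist_rows
    report["front_vs_rear"] = front_vs_rear

    if len(model_names) >= 2 and len(used) > 1:
        report["distances"]["anova_lsd_front"] = _stat_or_degenerate(
            fisher_lsd, [dist_front[m] for m in model_names], labels=model_names, alpha=alpha
        )
        report["distances"]["anova_lsd_rear"] = _stat_or_degenerate(
            fisher_lsd, [dist_rear[m] for m in model_names], labels=model_names, alpha=alpha
        )
    return report


def _mean_se_row(values: Sequence[float]) -> dict:
    v = np.asarray(values, dtype=np.float64)
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "se": mean_se(v)[1] if v.size > 1 else math.nan,
    }
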