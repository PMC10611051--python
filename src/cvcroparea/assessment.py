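"""Accuracy assessment: polygon-majority labeling, confusion matrices,
ROC threshold selection, pixel-wise map agreement and report tables.

Polygon-level assessment follows the field-classification convention:
keep the map pixels whose center falls inside a ground-truth polygon,
take the mean of their {0,1} labels, and call the polygon crop when that
mean exceeds 0.5 (strictly) and non-crop otherwise.  Crop polygons
predicted crop are true positives; built-up and forest polygons
predicted non-crop are true negatives.  Overall accuracy is

    OA = (TP + TN) / (TP + FP + FN + TN) * 100.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import shapely

from .containers import MASK, BinaryCropMap, CVRaster, TruthPolygon
from .grid import validate_grid_alignment

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "extract_polygon_pixels",
    "polygon_majority_classify",
    "confusion_from_polygons",
    "accuracy_metrics",
    "pixelwise_agreement",
    "roc_sweep",
    "select_threshold_apriori",
    "recover_count",
    "summarize_report",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching how report tables are printed."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion matrix: model rows (crop/non-crop) vs reference columns."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    """Derived accuracy metrics; undefined quantities are None, never 0."""

    oa_percent: float
    sensitivity: float | None
    specificity: float | None
    youden_j: float | None
    kappa: float | None


def accuracy_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """OA, sensitivity, specificity, Youden J and Cohen's kappa.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), J = sens + spec - 1,
    kappa = (p_o - p_e)/(1 - p_e) with p_o the observed agreement and p_e
    the chance agreement from the marginals.  A metric whose denominator
    is zero is reported as None (not available), never as 0.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    oa = 100.0 * (cm.TP + cm.TN) / n
    sens = cm.TP / (cm.TP + cm.FN) if (cm.TP + cm.FN) > 0 else None
    spec = cm.TN / (cm.TN + cm.FP) if (cm.TN + cm.FP) > 0 else None
    j = sens + spec - 1.0 if (sens is not None and spec is not None) else None
    p_o = (cm.TP + cm.TN) / n
    p_e = ((cm.TP + cm.FP) * (cm.TP + cm.FN) + (cm.FN + cm.TN) * (cm.FP + cm.TN)) / (
        n * n
    )
    kappa = (p_o - p_e) / (1.0 - p_e) if abs(1.0 - p_e) > 1e-15 else None
    return MetricsReport(oa, sens, spec, j, kappa)


def extract_polygon_pixels(
    cmap: BinaryCropMap, polygon: TruthPolygon
) -> tuple[np.ndarray, int]:
    """Labels of pixels whose center lies inside the polygon.

    Pixel centers exactly on the boundary count as inside (closed-boundary
    containment).  Returns ``(labels, n_masked)`` where MASK labels are
    excluded from ``labels`` but counted in ``n_masked``.  A polygon
    outside the raster extent yields an empty result.
    """
    grid = cmap.grid
    minx, miny, maxx, maxy = polygon.geometry.bounds
    # candidate pixel window from the polygon bounds (pixel-center registration)
    c0 = max(int(math.floor((minx - grid.origin_x) / grid.pixel_size_x - 0.5)), 0)
    c1 = min(int(math.ceil((maxx - grid.origin_x) / grid.pixel_size_x + 0.5)), grid.width)
    r0 = max(int(math.floor((maxy - grid.origin_y) / grid.pixel_size_y - 0.5)), 0)
    r1 = min(int(math.ceil((miny - grid.origin_y) / grid.pixel_size_y + 0.5)), grid.height)
    if c0 >= c1 or r0 >= r1:
        return np.empty(0, dtype=np.uint8), 0
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xs = grid.origin_x + (cols + 0.5) * grid.pixel_size_x
    ys = grid.origin_y + (rows + 0.5) * grid.pixel_size_y
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.covers(polygon.geometry, shapely.points(xx.ravel(), yy.ravel()))
    inside = inside.reshape(xx.shape)
    window = cmap.labels[r0:r1, c0:c1]
    labels = window[inside]
    n_masked = int((labels == MASK).sum())
    return labels[labels != MASK].astype(np.uint8), n_masked


def polygon_majority_classify(
    cmap: BinaryCropMap, polygons: list[TruthPolygon]
) -> pd.DataFrame:
    """Per-polygon majority classification.

    Returns a table with one row per polygon: field_id, category, pixel
    counts, the mean {0,1} value of its non-masked pixels, the predicted
    label (``crop`` when mean > 0.5, else ``non-crop``) and a ``flagged``
    column for polygons with no usable pixel (excluded from metrics).
    """
    rows = []
    for poly in polygons:
        labels, n_masked = extract_polygon_pixels(cmap, poly)
        flagged = labels.size == 0
        mean_value = float(labels.mean()) if labels.size else float("nan")
        predicted = "crop" if (labels.size and mean_value > 0.5) else "non-crop"
        rows.append(
            {
                "field_id": poly.field_id,
                "category": poly.category,
                "n_pixels": int(labels.size),
                "n_masked": n_masked,
                "mean_value": mean_value,
                "predicted": predicted if not flagged else None,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def confusion_from_polygons(
    predictions: pd.DataFrame | list[str], polygons: list[TruthPolygon] | None = None
) -> ConfusionMatrix:
    """Tally the polygon confusion matrix.

    Crop polygons predicted crop are TP (otherwise FN); built-up and
    forest polygons predicted non-crop are TN (otherwise FP).  Accepts
    the `polygon_majority_classify` table, or a plain list of predicted
    labels aligned with ``polygons``.  Flagged polygons are excluded.
    """
    if isinstance(predictions, pd.DataFrame):
        table = predictions[~predictions["flagged"]]
        pairs = zip(table["category"], table["predicted"])
    else:
        if polygons is None or len(predictions) != len(polygons):
            raise ValueError("need one prediction per polygon")
        pairs = zip((p.category for p in polygons), predictions)
    tp = fp = fn = tn = 0
    for category, predicted in pairs:
        if category == "crop":
            if predicted == "crop":
                tp += 1
            else:
                fn += 1
        else:
            if predicted == "non-crop":
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def pixelwise_agreement(map_a: BinaryCropMap, map_b: BinaryCropMap) -> float:
    """Percent of non-MASK pixels on which two maps agree.

    Masks are harmonized first (union), so pixels masked in either map
    are excluded from the comparison.
    """
    from .binarize import harmonize_masks

    if not validate_grid_alignment([map_a.grid, map_b.grid]):
        raise ValueError("maps are not on the same grid")
    a, b = harmonize_masks(map_a, map_b)
    valid = a.labels != MASK
    if not valid.any():
        raise ValueError("no unmasked pixels to compare")
    return 100.0 * float((a.labels[valid] == b.labels[valid]).mean())


def roc_sweep(
    cvr: CVRaster,
    truth: BinaryCropMap,
    thr_min: float = 0.0,
    thr_max: float = 1.0,
    step: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Confusion metrics at each CV threshold; returns (table, best threshold).

    The sweep covers ``thr_min`` to ``thr_max`` in ``step`` increments,
    classifying CV >= threshold as crop against pixel truth (MASK and
    invalid-CV pixels excluded).  The optimal threshold maximizes the
    Youden J statistic; ties break toward the smallest threshold.
    """
    if not validate_grid_alignment([cvr.grid, truth.grid]):
        raise ValueError("CV raster and truth are not on the same grid")
    usable = (truth.labels != MASK) & np.isfinite(cvr.cv)
    cv_crop = np.sort(cvr.cv[usable & (truth.labels == 1)])
    cv_noncrop = np.sort(cvr.cv[usable & (truth.labels == 0)])
    if cv_crop.size == 0 or cv_noncrop.size == 0:
        raise ValueError("ROC needs both crop and non-crop truth pixels")

    n_steps = int(round((thr_max - thr_min) / step))
    thresholds = np.round(thr_min + step * np.arange(n_steps + 1), 10)
    # CV >= thr counts as crop
    tp = cv_crop.size - np.searchsorted(cv_crop, thresholds, side="left")
    fp = cv_noncrop.size - np.searchsorted(cv_noncrop, thresholds, side="left")
    fn = cv_crop.size - tp
    tn = cv_noncrop.size - fp

    records = []
    for i, thr in enumerate(thresholds):
        rep = accuracy_metrics(ConfusionMatrix(int(tp[i]), int(fp[i]), int(fn[i]), int(tn[i])))
        records.append(
            {
                "threshold": float(thr),
                "TP": int(tp[i]), "FP": int(fp[i]), "FN": int(fn[i]), "TN": int(tn[i]),
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "youden_j": rep.youden_j,
                "kappa": rep.kappa,
                "oa_percent": rep.oa_percent,
            }
        )
    table = pd.DataFrame(records)
    best_idx = int(np.argmax(table["youden_j"].to_numpy()))  # first max -> smallest thr
    return table, float(table["threshold"].iloc[best_idx])


def _max_youden_j(cv_crop: np.ndarray, cv_noncrop: np.ndarray,
                  thresholds: np.ndarray) -> float:
    tp = cv_crop.size - np.searchsorted(cv_crop, thresholds, side="left")
    fp = cv_noncrop.size - np.searchsorted(cv_noncrop, thresholds, side="left")
    sens = tp / cv_crop.size
    spec = 1.0 - fp / cv_noncrop.size
    return float(np.max(sens + spec - 1.0))


def max_j_permutation_pvalue(
    cv_values: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 199,
    step: float = 0.01,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the maximum Youden J of a threshold sweep.

    The maximum of J over thresholds is positively biased even when CV
    carries no class information, so "is the achieved J real?" is tested
    against the permutation null: labels are shuffled ``n_permutations``
    times, the sweep is re-run, and the p-value is the fraction of
    permuted max-J values at least as large as the observed one (with
    the +1 correction).  Large p means the observed separation is
    indistinguishable from chance.
    """
    cv_values = np.asarray(cv_values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    keep = np.isfinite(cv_values)
    cv_values, labels = cv_values[keep], labels[keep]
    if rng is None:
        rng = np.random.default_rng(0)
    thresholds = np.round(step * np.arange(int(1 / step) + 1), 10)
    observed = _max_youden_j(
        np.sort(cv_values[labels == 1]), np.sort(cv_values[labels == 0]), thresholds
    )
    n_crop = int((labels == 1).sum())
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(cv_values.size)
        pc = np.sort(cv_values[perm[:n_crop]])
        pn = np.sort(cv_values[perm[n_crop:]])
        if _max_youden_j(pc, pn, thresholds) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def select_threshold_apriori(
    base_thr_coarse: float,
    coarse_pixel_m: float,
    fine_pixel_m: float,
    offset_per_halving: float = 0.0215,
) -> float:
    """A-priori CV threshold lookup with pixel-size adjustment.

    Optimal CV thresholds increase with finer grid spacing, so a
    threshold established at a coarse resolution is raised when applied
    to finer pixels:

        cv_thr = base + offset_per_halving * log2(coarse / fine)

    clipped to (0, 1].  The default offset maps the published
    coarse-resolution value 0.20 at 150 m pixels to 0.25 at 30 m.  This
    is a documented heuristic encoding of the published lookup reasoning,
    not a fitted model.
    """
    if coarse_pixel_m <= 0 or fine_pixel_m <= 0:
        raise ValueError("pixel sizes must be positive")
    if not 0 < base_thr_coarse <= 1:
        raise ValueError("base threshold must be in (0, 1]")
    thr = base_thr_coarse + offset_per_halving * math.log2(coarse_pixel_m / fine_pixel_m)
    return min(max(thr, 1e-9), 1.0)


def recover_count(accuracy_percent: float, n: int) -> int:
    """Invert a printed percentage back to the integer correct count.

    Returns the unique k in [0, n] with round(100*k/n, 1) equal to the
    printed value (half-up rounding); errors when no such k exists or
    several do.
    """
    if not 0 <= accuracy_percent <= 100:
        raise ValueError("accuracy_percent must be in [0, 100]")
    if n < 1:
        raise ValueError("n must be >= 1")
    target = round_half_up(accuracy_percent, 1)
    hits = [k for k in range(n + 1) if round_half_up(100.0 * k / n, 1) == target]
    if not hits:
        raise ValueError(f"no count matches {accuracy_percent}% of {n}")
    if len(hits) > 1:
        raise ValueError(f"ambiguous counts {hits} for {accuracy_percent}% of {n}")
    return hits[0]


def summarize_report(per_year: pd.DataFrame) -> pd.DataFrame:
    """Append the across-year unweighted mean row ('AVG') to a yearly table.

    ``per_year`` is indexed by year with one numeric column per reported
    accuracy.  Yearly values are first rounded to one decimal (they are
    printed that way), the AVG row is the arithmetic mean of those
    rounded values, itself rounded to one decimal, half-up.
    """
    if len(per_year) < 1:
        raise ValueError("need at least one year")
    rounded = per_year.map(lambda v: round_half_up(v, 1))
    avg = rounded.mean(axis=0).map(lambda v: round_half_up(v, 1))
    out = rounded.copy()
    out.loc["AVG"] = avg
    return out
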