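"""Segmentation evaluation: Dice, 95% Hausdorff distance, volumes, detection
outcomes, cohort summaries and lesion-size stratification.

Conventions
-----------
* DSC = 2|X∩Y| / (|X|+|Y|) with X the manual and Y the automated mask.
  When both masks are empty the DSC is defined as 1.0 (perfect agreement on
  absence, needed for control subjects); when exactly one is empty it is 0.
* HD95 is the symmetric max of the two directed 95th-percentile
  boundary-to-boundary distances, in mm using the voxel spacing.  Boundary
  voxels are foreground voxels with at least one background 6-neighbor
  (voxels on the array edge count as boundary); distances are between voxel
  centers; percentiles use linear interpolation.  Undefined (NaN) when either
  mask is empty.
* PVD = |vol_pred − vol_true| / vol_true × 100, undefined when vol_true = 0.
* Detection: a resection subject is a false negative iff the (screened)
  prediction has no overlap with the truth; a control subject is a false
  positive iff the screened prediction is non-empty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume_io import BinaryMask, require_same_geometry, voxel_volume_ml

__all__ = [
    "MetricsResult",
    "CohortSummary",
    "dsc",
    "hd95",
    "mask_volume_ml",
    "pvd",
    "detection_outcome",
    "evaluate_pair",
    "summarize_cohort",
    "stratify_by_size",
    "SIZE_THRESHOLD_ML",
]

#: Lesion-size stratification threshold (ml) separating small from large
#: resections; sphere-equivalent radius ≈ 16.2 mm.
SIZE_THRESHOLD_ML = 17.92


@dataclass
class MetricsResult:
    """Per-subject evaluation row."""

    subject_id: str
    dsc: float
    hd95_mm: float  # NaN when undefined (either mask empty)
    vol_true_ml: float
    vol_pred_ml: float
    pvd_pct: float  # NaN when vol_true == 0
    outcome: str | None = None  # detection outcome label, when assessed


@dataclass
class CohortSummary:
    n: int
    dsc_median: float
    dsc_iqr: float
    dsc_mean: float
    dsc_sd: float
    hd95_median: float
    hd95_iqr: float
    hd95_mean: float
    hd95_sd: float
    hd95_n_excluded: int
    volume_pearson_r: float
    volume_mae_ml: float
    fn_count: int
    fp_count: int


def dsc(X: BinaryMask, Y: BinaryMask) -> float:
    """Dice–Sørensen coefficient between two masks on the same grid."""
    require_same_geometry(X, Y, "DSC inputs")
    nx = int(X.data.sum())
    ny = int(Y.data.sum())
    if nx + ny == 0:
        return 1.0
    inter = int(np.logical_and(X.data, Y.data).sum())
    return 2.0 * inter / (nx + ny)


def _boundary(mask_data: np.ndarray) -> np.ndarray:
    """Foreground voxels with ≥1 background 6-neighbor (array edge = background)."""
    m = mask_data.astype(bool)
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(m, structure=structure, border_value=0)
    return m & ~eroded


def hd95(X: BinaryMask, Y: BinaryMask, percentile: float = 95.0) -> float:
    """95% Hausdorff distance in mm; NaN with a warning if either mask is empty."""
    require_same_geometry(X, Y, "HD95 inputs")
    if X.data.sum() == 0 or Y.data.sum() == 0:
        warnings.warn("HD95 undefined: at least one mask is empty")
        return float("nan")
    bx = _boundary(X.data)
    by = _boundary(Y.data)
    spacing = X.spacing
    # exact Euclidean distance from every voxel to the nearest boundary voxel
    dt_to_y = ndimage.distance_transform_edt(~by, sampling=spacing)
    dt_to_x = ndimage.distance_transform_edt(~bx, sampling=spacing)
    d_xy = np.percentile(dt_to_y[bx], percentile)
    d_yx = np.percentile(dt_to_x[by], percentile)
    return float(max(d_xy, d_yx))


def mask_volume_ml(mask: BinaryMask) -> float:
    """Foreground voxel count × voxel volume, in ml."""
    return int(mask.data.sum()) * voxel_volume_ml(mask)


def pvd(vol_pred: float, vol_true: float) -> float:
    """Percent volume difference, relative to the true (manual) volume."""
    if vol_true <= 0:
        return float("nan")
    return abs(vol_pred - vol_true) / vol_true * 100.0


def detection_outcome(
    pred: BinaryMask, truth: BinaryMask | None
) -> str:
    """Classify a (screened) prediction as TP/FN (resection) or TN/FP (control).

    ``truth=None`` signals a control subject.
    """
    if truth is None:
        return "false_positive" if pred.data.any() else "true_negative"
    require_same_geometry(pred, truth, "detection inputs")
    overlap = np.logical_and(pred.data, truth.data).any()
    return "true_positive" if overlap else "false_negative"


def evaluate_pair(
    subject_id: str, truth: BinaryMask, pred: BinaryMask
) -> MetricsResult:
    """Compute the full per-subject metrics row for a resection subject."""
    vt = mask_volume_ml(truth)
    vp = mask_volume_ml(pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        h = hd95(truth, pred)
    return MetricsResult(
        subject_id=subject_id,
        dsc=dsc(truth, pred),
        hd95_mm=h,
        vol_true_ml=vt,
        vol_pred_ml=vp,
        pvd_pct=pvd(vp, vt),
        outcome=detection_outcome(pred, truth),
    )


def _iqr(values: np.ndarray) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def summarize_cohort(results: list[MetricsResult]) -> CohortSummary:
    """Cohort descriptive statistics over per-subject metric rows.

    Undefined HD95 values are excluded from HD95 summaries (their count is
    reported); correlation fields are NaN below n = 2 or for constant series.
    """
    if not results:
        raise ValueError("summarize_cohort requires at least one result")
    d = np.array([r.dsc for r in results], dtype=float)
    h_all = np.array([r.hd95_mm for r in results], dtype=float)
    h = h_all[~np.isnan(h_all)]
    vt = np.array([r.vol_true_ml for r in results], dtype=float)
    vp = np.array([r.vol_pred_ml for r in results], dtype=float)
    n = len(results)

    if n >= 2 and np.std(vt) > 0 and np.std(vp) > 0:
        r_val = float(stats.pearsonr(vt, vp)[0])
    else:
        r_val = float("nan")

    def _stats(x: np.ndarray) -> tuple[float, float, float, float]:
        if x.size == 0:
            return (float("nan"),) * 4
        return (
            float(np.median(x)),
            _iqr(x),
            float(np.mean(x)),
            float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        )

    dm, di, dmean, dsd = _stats(d)
    hm, hi, hmean, hsd = _stats(h)
    outcomes = [r.outcome for r in results if r.outcome]
    return CohortSummary(
        n=n,
        dsc_median=dm,
        dsc_iqr=di,
        dsc_mean=dmean,
        dsc_sd=dsd,
        hd95_median=hm,
        hd95_iqr=hi,
        hd95_mean=hmean,
        hd95_sd=hsd,
        hd95_n_excluded=int(np.isnan(h_all).sum()),
        volume_pearson_r=r_val,
        volume_mae_ml=float(np.mean(np.abs(vp - vt))),
        fn_count=sum(o == "false_negative" for o in outcomes),
        fp_count=sum(o == "false_positive" for o in outcomes),
    )


def stratify_by_size(
    results: list[MetricsResult], threshold_ml: float = SIZE_THRESHOLD_ML
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Partition subjects into small/large resection groups at ``threshold_ml``.

    Returns a per-group table (n, mean DSC, mean PVD, mean true/pred volume)
    and per-metric two-sample Welch t-test comparisons ``{metric: (t, p)}``;
    comparisons are NaN when a group is empty.
    """
    if threshold_ml <= 0:
        raise ValueError("threshold must be positive")
    small = [r for r in results if r.vol_true_ml < threshold_ml]
    large = [r for r in results if r.vol_true_ml >= threshold_ml]

    def _row(group: list[MetricsResult]) -> dict:
        if not group:
            return {
                "n": 0, "dsc_mean": np.nan, "pvd_mean": np.nan,
                "vol_true_mean_ml": np.nan, "vol_pred_mean_ml": np.nan,
            }
        return {
            "n": len(group),
            "dsc_mean": float(np.mean([r.dsc for r in group])),
            "pvd_mean": float(np.nanmean([r.pvd_pct for r in group])),
            "vol_true_mean_ml": float(np.mean([r.vol_true_ml for r in group])),
            "vol_pred_mean_ml": float(np.mean([r.vol_pred_ml for r in group])),
        }

    table = pd.DataFrame([_row(small), _row(large)], index=["small", "large"])

    comparisons: dict[str, tuple[float, float]] = {}
    for metric, getter in (
        ("dsc", lambda r: r.dsc),
        ("pvd", lambda r: r.pvd_pct),
        ("vol_true", lambda r: r.vol_true_ml),
        ("vol_pred", lambda r: r.vol_pred_ml),
    ):
        a = np.array([getter(r) for r in small], dtype=float)
        b = np.array([getter(r) for r in large], dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            comparisons[metric] = (float("nan"), float("nan"))
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            comparisons[metric] = (float(t), float(p))
    return table, comparisons
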