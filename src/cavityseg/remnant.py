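"""Remnant quantification: which brain regions were resected, and how much.

Given a parcellation aligned to the postoperative image and a resection mask,
each region's resected volume is the voxel count of (region ∩ resection) and
its remnant is the rest; per-region percent resected drives the report table,
sorted by percent resected descending.  Resection voxels falling on
background (label 0) are reported as "unassigned" rather than dropped, so
volumes are conserved exactly: per region resected + remnant = total, and the
row resected volumes plus the unassigned volume sum to the total resection
volume.

Registration between pre- and post-operative images is out of scope: inputs
must already share a voxel grid, and geometry mismatches fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RegionLookupError
from .volume_io import (
    BinaryMask,
    Parcellation,
    require_same_geometry,
    voxel_volume_ml,
)

__all__ = [
    "RemnantReport",
    "intersect_parcellation",
    "region_remnant",
    "compare_remnant_estimates",
    "remnant_agreement",
    "render_report",
]

_ROW_COLUMNS = ["label", "region_name", "total_ml", "resected_ml", "remnant_ml",
                "pct_resected"]


@dataclass
class RemnantReport:
    """Per-region resection impact plus whole-mask totals (all volumes in ml)."""

    rows: pd.DataFrame
    total_resection_ml: float
    unassigned_resection_ml: float


def intersect_parcellation(parc: Parcellation, resection: BinaryMask) -> RemnantReport:
    """Intersect a parcellation with a resection mask into a remnant report.

    Every named region appears in the output, including those with zero
    overlap; rows are sorted by percent resected descending (ties by label).
    """
    require_same_geometry(parc, resection, "parcellation and resection mask")
    if not parc.labels:
        raise ValueError("parcellation has no named regions")
    vv = voxel_volume_ml(parc)
    nlab = int(parc.data.max()) + 1
    totals = np.bincount(parc.data.ravel(), minlength=nlab)
    resected = np.bincount(parc.data[resection.data.astype(bool)], minlength=nlab)
    rows = []
    for label, name in sorted(parc.labels.items()):
        tot, res = int(totals[label]), int(resected[label])
        rows.append({
            "label": label,
            "region_name": name,
            "total_ml": tot * vv,
            "resected_ml": res * vv,
            "remnant_ml": (tot - res) * vv,
            "pct_resected": 100.0 * res / tot if tot else 0.0,
        })
    df = pd.DataFrame(rows, columns=_ROW_COLUMNS).sort_values(
        ["pct_resected", "label"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return RemnantReport(
        rows=df,
        total_resection_ml=float(resection.data.sum()) * vv,
        unassigned_resection_ml=int(resected[0]) * vv,
    )


def region_remnant(report: RemnantReport, region_name: str) -> tuple[float, float]:
    """(remnant_ml, pct_resected) for one named region."""
    match = report.rows[report.rows.region_name == region_name]
    if match.empty:
        available = ", ".join(report.rows.region_name)
        raise RegionLookupError(
            f"no region named {region_name!r}; available: {available}"
        )
    row = match.iloc[0]
    return float(row.remnant_ml), float(row.pct_resected)


def compare_remnant_estimates(
    parc: Parcellation,
    manual_mask: BinaryMask,
    predicted_mask: BinaryMask,
    region_names: list[str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Percent-resected estimates from manual vs predicted masks, per region.

    Both arms are mask-intersection estimates (no voxel-wise remnant ground
    truth exists); agreement over the series is summarized by MAE in
    percentage points and, where defined, Pearson r.
    """
    rep_man = intersect_parcellation(parc, manual_mask)
    rep_pred = intersect_parcellation(parc, predicted_mask)
    rows = []
    for name in region_names:
        _, pct_m = region_remnant(rep_man, name)
        _, pct_p = region_remnant(rep_pred, name)
        rows.append({"region_name": name, "pct_resected_manual": pct_m,
                     "pct_resected_predicted": pct_p})
    df = pd.DataFrame(rows)
    stats_out = remnant_agreement(
        df.pct_resected_manual.to_numpy(), df.pct_resected_predicted.to_numpy()
    )
    return df, stats_out


def remnant_agreement(manual_pct: np.ndarray, predicted_pct: np.ndarray) -> dict[str, float]:
    """MAE (percentage points) and Pearson r between two estimate series."""
    manual_pct = np.asarray(manual_pct, dtype=float)
    predicted_pct = np.asarray(predicted_pct, dtype=float)
    mae = float(np.mean(np.abs(manual_pct - predicted_pct))) if manual_pct.size else float("nan")
    if manual_pct.size >= 2 and np.std(manual_pct) > 0 and np.std(predicted_pct) > 0:
        r = float(stats.pearsonr(manual_pct, predicted_pct)[0])
    else:
        r = float("nan")
    return {"mae_pct": mae, "pearson_r": r, "n": int(manual_pct.size)}


def render_report(report: RemnantReport, path: str | Path, format: str = "csv") -> None:
    """Write a report as CSV, JSON or a single self-contained HTML table.

    CSV/JSON carry all fields at full precision (CSV totals as ``#`` comment
    lines); HTML rounds percentages to one decimal place for display.
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# total_resection_ml={report.total_resection_ml!r}\n")
            fh.write(f"# unassigned_resection_ml={report.unassigned_resection_ml!r}\n")
            report.rows.to_csv(fh, index=False)
    elif format == "json":
        payload = {
            "total_resection_ml": report.total_resection_ml,
            "unassigned_resection_ml": report.unassigned_resection_ml,
            "rows": report.rows.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    elif format == "html":
        cells = "".join(
            "<tr><td>{}</td><td>{}</td><td>{:.2f}</td><td>{:.2f}</td>"
            "<td>{:.2f}</td><td>{:.1f}</td></tr>".format(
                int(r.label), r.region_name, r.total_ml, r.resected_ml,
                r.remnant_ml, r.pct_resected,
            )
            for r in report.rows.itertuples()
        )
        header = "".join(f"<th>{c}</th>" for c in _ROW_COLUMNS)
        html = (
            "<table>"
            f"<caption>Total resection volume: {report.total_resection_ml:.2f} ml "
            f"(unassigned: {report.unassigned_resection_ml:.2f} ml)</caption>"
            f"<thead><tr>{header}</tr></thead><tbody>{cells}</tbody></table>"
        )
        path.write_text(html)
    else:
        raise ValueError(f"unknown format {format!r}; expected csv, json or html")
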