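"""Closed-form quantifications of the functional assays.

Dye-dilution division numbers (2^X = initial/final MFI), vascular
association fractions, vessel co-option percentages at the invasive
front, Nestin-positive nuclei percentages, and time-lapse reprogramming
rates. "Attached" / "in contact" is operationalized as Euclidean distance
to the nearest vessel polyline <= contact_radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .datatypes import VesselScene


def min_distance_to_segments(
    points: np.ndarray, segments: list[np.ndarray]
) -> np.ndarray:
    """Minimum Euclidean distance from each 2-D point to any polyline."""
    pts = shapely.points(np.asarray(points, dtype=float))
    lines = [shapely.LineString(np.asarray(s, dtype=float)) for s in segments]
    dists = np.stack([shapely.distance(pts, line) for line in lines], axis=1)
    return dists.min(axis=1)


@dataclass
class DivisionEstimate:
    x: float  # number of divisions
    time_per_division: float | None  # hours; None when x == 0
    clipped: bool  # final MFI exceeded initial (labeling artifact), X clipped at 0


def division_number(
    mfi_initial: float, mfi_final: float, elapsed: float, tol: float = 0.0
) -> DivisionEstimate:
    """Division number from dye dilution: 2^X = B with B = initial/final MFI.

    X = log2(B); time per division = elapsed / X for X > 0, undefined (None)
    otherwise. A final MFI above initial x (1 + tol) is a labeling artifact:
    warn and clip X at 0.
    """
    if mfi_initial <= 0 or mfi_final <= 0:
        raise ValueError("MFI values must be positive")
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    clipped = False
    if mfi_final > mfi_initial * (1.0 + tol):
        warnings.warn(
            f"final MFI {mfi_final} exceeds initial {mfi_initial}; clipping X at 0",
            stacklevel=2,
        )
        x = 0.0
        clipped = True
    else:
        b = mfi_initial / mfi_final
        x = max(0.0, np.log2(b))
    tpd = elapsed / x if x > 0 else None
    return DivisionEstimate(x=x, time_per_division=tpd, clipped=clipped)


def division_numbers(records: pd.DataFrame, tol: float = 0.0) -> pd.DataFrame:
    """Vectorized :func:`division_number` over a record table
    (columns mfi_initial, mfi_final, elapsed)."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, r in records.iterrows():
            est = division_number(r["mfi_initial"], r["mfi_final"], r["elapsed"], tol=tol)
            out.append(
                {
                    "x": est.x,
                    "time_per_division": est.time_per_division,
                    "clipped": est.clipped,
                }
            )
    res = pd.DataFrame(out, index=records.index)
    if "record_id" in records.columns:
        res.insert(0, "record_id", records["record_id"])
    return res


def _attached_mask(scene: VesselScene, cells: pd.DataFrame) -> np.ndarray:
    pts = cells[["x", "y"]].to_numpy(dtype=float)
    segs = [np.asarray(v, dtype=float) for v in scene.segments.values()]
    return min_distance_to_segments(pts, segs) <= scene.contact_radius


def vascular_association(scene: VesselScene, cell_class: str) -> float:
    """Fraction of cells of a class attached to a vessel:
    (cells of class within contact_radius of any segment) / (cells of class)."""
    cells = scene.cells[scene.cells["cell_class"] == cell_class]
    if cells.empty:
        raise ValueError(f"no cells of class {cell_class!r} in scene")
    return float(_attached_mask(scene, cells).mean())


def vessel_cooption_percentage(
    scene: VesselScene, region: str = "invasive_front"
) -> float:
    """Percentage of cells in a region (default the invasive front) in
    contact with a vessel segment."""
    cells = scene.cells[scene.cells["region"] == region]
    if cells.empty:
        raise ValueError(f"no cells in region {region!r}")
    return 100.0 * float(_attached_mask(scene, cells).mean())


def infiltrating_cell_density(
    scene: VesselScene, region: str = "invasive_front", area: float | None = None
) -> float:
    """Cells per unit area in a region; area defaults to the region's
    cell bounding box (degenerate boxes are an error)."""
    cells = scene.cells[scene.cells["region"] == region]
    if cells.empty:
        raise ValueError(f"no cells in region {region!r}")
    if area is None:
        w = cells["x"].max() - cells["x"].min()
        h = cells["y"].max() - cells["y"].min()
        area = w * h
    if area <= 0:
        raise ValueError("region area must be positive")
    return len(cells) / area


def nestin_positive_percentage(nuclei: pd.DataFrame, region: str | None = None) -> float:
    """100 x positive nuclei / total nuclei, optionally within a region.

    Expects columns nestin_status (positive | negative) and region.
    """
    t = nuclei if region is None else nuclei[nuclei["region"] == region]
    if t.empty:
        raise ValueError("no nuclei in selection")
    bad = set(t["nestin_status"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown nestin_status values: {sorted(bad)}")
    return 100.0 * float((t["nestin_status"] == "positive").mean())


def reprogramming_rate(timelapse: pd.DataFrame) -> pd.Series:
    """Per-timepoint percent double-positive cells:
    100 x GFP+dTomato+ / (GFP+dTomato+ + GFP+dTomato-).

    Expects columns timepoint, double_positive, single_positive.
    """
    dp = timelapse["double_positive"].to_numpy(dtype=float)
    sp = timelapse["single_positive"].to_numpy(dtype=float)
    if (dp < 0).any() or (sp < 0).any():
        raise ValueError("negative cell counts")
    total = dp + sp
    if (total == 0).any():
        raise ValueError("timepoint with no cells")
    return pd.Series(
        100.0 * dp / total, index=timelapse["timepoint"], name="percent_double_positive"
    )


def fluorescence_area_fraction(timelapse: pd.DataFrame) -> pd.Series:
    """Per-timepoint dTomato+ cell area divided by total cell area.

    Expects columns timepoint, dtomato_area, total_area.
    """
    num = timelapse["dtomato_area"].to_numpy(dtype=float)
    den = timelapse["total_area"].to_numpy(dtype=float)
    if (num < 0).any() or (den <= 0).any():
        raise ValueError("areas must be non-negative with positive totals")
    if (num > den).any():
        raise ValueError("dTomato area exceeds total cell area")
    return pd.Series(num / den, index=timelapse["timepoint"], name="area_fraction")
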