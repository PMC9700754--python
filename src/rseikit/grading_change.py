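"""Five-grade RSEI classification, grade-area statistics, change detection.

RSEI values are cut at 0.2 intervals into poor / fair / moderate / good /
excellent.  Bins are left-closed, right-open, with the final bin closed at
1.0 so that every value in [0, 1] receives exactly one grade.  Change
between two epochs is the sign of the grade difference (improved /
unchanged / declined), which is what multi-year grade comparisons report.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .raster_core import CategoricalGrid, Grid

__all__ = [
    "GRADE_LABELS",
    "GRADE_EDGES",
    "CHANGE_LABELS",
    "grade_rsei",
    "grade_area_table",
    "change_detect",
    "load_regions",
]

GRADE_LABELS = {1: "poor", 2: "fair", 3: "moderate", 4: "good", 5: "excellent"}
GRADE_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
CHANGE_LABELS = {-1: "declined", 0: "unchanged", 1: "improved"}


def grade_rsei(rsei: Grid, tol: float = 1e-9) -> CategoricalGrid:
    """Classify RSEI into grades 1..5 at 0.2 intervals.

    Values must lie in [0, 1] up to ``tol``; 1.0 falls in the top (excellent)
    bin.  Nodata propagates.
    """
    vals = rsei.values
    valid = ~np.isnan(vals)
    if valid.any():
        lo, hi = vals[valid].min(), vals[valid].max()
        if lo < -tol or hi > 1.0 + tol:
            raise ValueError(f"RSEI values outside [0, 1]: range [{lo}, {hi}]")
    clipped = np.clip(vals, 0.0, 1.0)
    codes = np.full(rsei.shape, -1, dtype=np.int64)
    # digitize with right=False: [0,.2) -> 1, ..., [.8,1) -> 5; force 1.0 -> 5.
    binned = np.digitize(clipped, GRADE_EDGES[1:-1], right=False) + 1
    codes[valid] = np.minimum(binned[valid], 5)
    return CategoricalGrid(codes, GRADE_LABELS, rsei.origin_x, rsei.origin_y,
                           rsei.cell_size, rsei.crs_label, nodata=-1)


def load_regions(path: str | Path) -> dict[str, "object"]:
    """Read named polygons from a GeoJSON FeatureCollection.

    Feature names come from a ``name`` property (fallback: feature index).
    Returns {name: shapely geometry}.
    """
    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    regions = {}
    for i, feat in enumerate(doc.get("features", [])):
        name = str(feat.get("properties", {}).get("name", i))
        regions[name] = shape(feat["geometry"])
    return regions


def _region_mask(grades: CategoricalGrid, geom) -> np.ndarray:
    """Pixel-centre-in-polygon membership mask."""
    import shapely

    nr, nc = grades.shape
    xs = grades.origin_x + (np.arange(nc) + 0.5) * grades.cell_size
    ys = grades.origin_y - (np.arange(nr) + 0.5) * grades.cell_size
    xx, yy = np.meshgrid(xs, ys)
    return shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(nr, nc)


def grade_area_table(grades: CategoricalGrid, regions: dict | None = None) -> pd.DataFrame:
    """Area and percentage of valid pixels per grade, per region.

    Without regions the whole grid is one region named ``all``.  Percentages
    are over the region's valid pixels and sum to 100; a region with no valid
    pixels reports NaN percentages.  Area = pixel count x cell area.
    """
    cell_area = grades.cell_size ** 2
    if regions is None:
        masks = {"all": np.ones(grades.shape, dtype=bool)}
    else:
        masks = {name: _region_mask(grades, geom) for name, geom in regions.items()}
    rows = []
    for name, mask in masks.items():
        sel = grades.codes[mask & grades.valid_mask]
        total = sel.size
        for code, label in GRADE_LABELS.items():
            count = int((sel == code).sum())
            rows.append({
                "region": name,
                "grade": code,
                "label": label,
                "pixel_count": count,
                "area": count * cell_area,
                "percent": 100.0 * count / total if total else np.nan,
            })
    return pd.DataFrame(rows)


def change_detect(earlier: CategoricalGrid,
                  later: CategoricalGrid) -> tuple[CategoricalGrid, pd.DataFrame]:
    """Sign of grade change per pixel, plus improved/unchanged/declined shares.

    Nodata in either epoch yields nodata.  Swapping the epochs negates every
    change code.  Percentages are over jointly valid pixels and sum to 100.
    """
    if not earlier.co_registered(later):
        raise ValueError("epoch grids are not co-registered")
    valid = earlier.valid_mask & later.valid_mask
    diff = np.sign(later.codes - earlier.codes).astype(np.int64)
    codes = np.where(valid, diff, -9)
    change = CategoricalGrid(codes, CHANGE_LABELS, earlier.origin_x,
                             earlier.origin_y, earlier.cell_size,
                             earlier.crs_label, nodata=-9)
    total = int(valid.sum())
    rows = []
    for code, label in CHANGE_LABELS.items():
        count = int((codes[valid] == code).sum())
        rows.append({
            "change": label,
            "pixel_count": count,
            "percent": 100.0 * count / total if total else np.nan,
        })
    return change, pd.DataFrame(rows)
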