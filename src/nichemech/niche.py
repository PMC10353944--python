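"""Spatial quantification of brain-section geometry.

Works on z-projected 2-D sections: marker-classified cell centroids, a
hand-traced ventricle-border polyline, and hand-drawn region polygons
(SVZ along the ventricle, the rostral migratory stream, and the olfactory
bulb).  Quantities follow the conventions of SVZ section analysis:
Euclidean distance from
each nucleus center to the ventricle border, analysis restricted to a
200-um band from the ventricle wall (to exclude striatal astrocytes), cells
directly lining blood vessels censored, and EdU labeling efficiency as
EdU+ / Ki67+ within the SVZ.

Boundary behavior is deterministic: a point on the border is at distance 0,
inside the band, and inside a region.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from .stats import mann_whitney_two_tailed

__all__ = [
    "make_polyline",
    "distance_to_border",
    "classify_cell",
    "filter_band",
    "per_animal_distance_summary",
    "count_in_regions",
    "labeling_efficiency",
    "PANELS",
]

#: marker-panel decision tables; flags not listed are ignored by the panel
PANELS = {
    "GFAP/Ki67": {
        "required": ("GFAP", "Ki67"),
        "rules": [
            ({"GFAP": True, "Ki67": False}, "qNSC/astrocyte"),
            ({"GFAP": True, "Ki67": True}, "aNSC"),
        ],
    },
    "S100a6/Ki67": {
        "required": ("S100a6", "Ki67"),
        "rules": [
            ({"S100a6": True, "Ki67": False}, "qNSC"),
            ({"S100a6": True, "Ki67": True}, "aNSC"),
        ],
    },
    "EdU/Ki67/DCX": {
        "required": ("EdU", "Ki67", "DCX"),
        "rules": [
            ({"EdU": True, "DCX": True}, "neuroblast"),
            ({"EdU": True, "Ki67": True, "DCX": False}, "aNSC/NPC"),
        ],
    },
}


def make_polyline(vertices) -> LineString:
    """Validate and build a border polyline from an (n, 2) vertex array."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 2:
        raise ValueError("polyline needs >= 2 (x, y) vertices")
    if not np.isfinite(vertices).all():
        raise ValueError("polyline vertices must be finite")
    if np.any(np.all(np.diff(vertices, axis=0) == 0, axis=1)):
        raise ValueError("consecutive polyline vertices must be distinct")
    return LineString(vertices)


def _as_linestring(polyline) -> LineString:
    if isinstance(polyline, LineString):
        return polyline
    return make_polyline(polyline)


def distance_to_border(point, polyline) -> float:
    """Minimum Euclidean distance (um) from a point to the border polyline."""
    point = np.asarray(point, dtype=float)
    if point.shape != (2,) or not np.isfinite(point).all():
        raise ValueError("point must be a finite (x, y) pair")
    return float(_as_linestring(polyline).distance(Point(point)))


def _distances(cells: pd.DataFrame, polyline) -> np.ndarray:
    line = _as_linestring(polyline)
    pts = shapely.points(cells["x"].to_numpy(float), cells["y"].to_numpy(float))
    return shapely.distance(line, pts)


def classify_cell(record, panel) -> str:
    """Cell-type label from a record of boolean marker flags.

    ``record`` is any mapping with the panel's marker flags and an optional
    ``vessel_adjacent`` flag; vessel-adjacent cells are censored (they sit on
    blood vessels rather than the ventricle-lining niche).  Flags not
    matching any rule yield ``"unclassified"``.
    """
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}; choose from {sorted(PANELS)}")
    spec = PANELS[panel]
    for flag in spec["required"]:
        if flag not in record:
            raise KeyError(f"panel {panel!r} requires marker flag {flag!r}")
    if record.get("vessel_adjacent", False):
        return "censored"
    for conditions, label in spec["rules"]:
        if all(bool(record[k]) == v for k, v in conditions.items()):
            return label
    return "unclassified"


def filter_band(cells, polyline, max_distance=200.0) -> pd.DataFrame:
    """Retain cells within ``max_distance`` um of the border (inclusive).

    The 200-um default mirrors the restriction used to exclude striatal
    astrocytes from SVZ quantification.  Idempotent by construction.
    """
    cells = pd.DataFrame(cells)
    if cells.empty:
        return cells.copy()
    keep = _distances(cells, polyline) <= max_distance
    return cells.loc[keep].copy()


def per_animal_distance_summary(
    cells,
    polyline,
    group_col="group",
    animal_col="animal",
    type_col="cell_type",
):
    """Per-animal mean distance to the border, compared across two groups.

    Returns a dict with ``animal_means`` (animal x cell-type means) and
    ``comparisons`` (cell type -> GroupComparison from the two-tailed
    Mann-Whitney test on animal means).
    """
    cells = pd.DataFrame(cells).copy()
    cells["distance"] = _distances(cells, polyline)
    by = [c for c in (group_col, animal_col, type_col) if c in cells.columns]
    animal_means = cells.groupby(by)["distance"].mean().reset_index()
    result = {"animal_means": animal_means, "comparisons": {}}
    if group_col in cells.columns:
        groups = list(pd.unique(cells[group_col]))
        if len(groups) == 2:
            g1, g2 = groups
            types = (
                pd.unique(animal_means[type_col])
                if type_col in animal_means.columns
                else [None]
            )
            for ct in types:
                sub = (
                    animal_means
                    if ct is None
                    else animal_means[animal_means[type_col] == ct]
                )
                x = sub.loc[sub[group_col] == g1, "distance"]
                y = sub.loc[sub[group_col] == g2, "distance"]
                if len(x) and len(y):
                    result["comparisons"][ct] = mann_whitney_two_tailed(x, y)
    return result


def count_in_regions(cells, regions, marker_filter=None) -> dict:
    """Count cells inside each named region polygon (boundary inclusive).

    ``regions`` maps name -> (n, 2) vertex array or shapely Polygon; regions
    that overlap trigger a warning and cells are counted in each.
    ``marker_filter`` is an optional boolean column name (or callable on the
    row) restricting which cells count.
    """
    cells = pd.DataFrame(cells)
    polys = {}
    for name, poly in regions.items():
        if not isinstance(poly, Polygon):
            poly = Polygon(np.asarray(poly, dtype=float))
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"region {name!r} is not a valid simple polygon")
        polys[name] = poly
    names = list(polys)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = polys[a].intersection(polys[b])
            if inter.area > 0:
                warnings.warn(
                    f"regions {a!r} and {b!r} overlap; cells in the overlap "
                    "are counted in both",
                    stacklevel=2,
                )
    if marker_filter is not None:
        if callable(marker_filter):
            cells = cells[cells.apply(marker_filter, axis=1)]
        else:
            cells = cells[cells[marker_filter].astype(bool)]
    if cells.empty:
        return {name: 0 for name in names}
    pts = shapely.points(cells["x"].to_numpy(float), cells["y"].to_numpy(float))
    return {
        name: int(shapely.covers(polys[name], pts).sum()) for name in names
    }


def labeling_efficiency(cells, svz_region=None) -> float:
    """EdU labeling efficiency: |EdU+| / |Ki67+| within the SVZ.

    ``cells`` needs boolean ``EdU`` and ``Ki67`` columns; when
    ``svz_region`` (polygon) is given, only cells inside it count, otherwise
    all provided cells are assumed to lie in the SVZ.
    """
    cells = pd.DataFrame(cells)
    if svz_region is not None:
        poly = (
            svz_region
            if isinstance(svz_region, Polygon)
            else Polygon(np.asarray(svz_region, dtype=float))
        )
        pts = shapely.points(
            cells["x"].to_numpy(float), cells["y"].to_numpy(float)
        )
        cells = cells[shapely.covers(poly, pts)]
    n_ki67 = int(cells["Ki67"].astype(bool).sum())
    if n_ki67 == 0:
        raise ValueError("no Ki67+ cells in the SVZ; efficiency undefined")
    n_edu = int(cells["EdU"].astype(bool).sum())
    return n_edu / n_ki67
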