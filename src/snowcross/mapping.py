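"""Spatial prediction grids, decile scores and community preference maps.

Cells are square (default 30 m, matching the land-cover raster resolution)
and belong to the grid when their centroid lies within the buffer distance of
the route polyline: 15 m for the crossing (highway) corridor, 1 km for the
approach corridor.  Per-group predicted abundance is binned into empirical
deciles (1 = lowest) and the community score is the product of the group
deciles scaled so its maximum is 10: with g groups, product / 10^(g-1)
(the familiar /1000 for four groups).

Coordinates are planar metres in a local frame; no geodesy.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString

from snowcross.count_models import StandardizationParams
from snowcross.selection import AveragedModel


@dataclass
class PredictionCell:
    """One square grid cell along a route corridor."""

    cell_id: int
    row: int
    col: int
    centroid_x: float
    centroid_y: float
    size_m: float
    corridor: str = "highway"


def build_grid(
    route: LineString | Sequence[tuple[float, float]],
    cell_m: float = 30.0,
    buffer_m: float = 15.0,
    corridor: str = "highway",
) -> list[PredictionCell]:
    """All cells whose centroid lies strictly within ``buffer_m`` of the polyline.

    The grid is anchored at the polyline's bounding box: columns tile from
    min-x, and rows are shifted half a cell so the row through min-y is
    centred on it.  For a straight route this puts the line through cell
    centres, giving a single strip at the 15 m highway buffer.  Cells are
    ordered by (row, col); the anchoring depends only on the route, so grids
    built with different buffers from one route nest exactly.
    """
    line = route if isinstance(route, LineString) else LineString(route)
    if line.length <= 0:
        raise ValueError("route polyline has zero length")
    if buffer_m <= 0:
        raise ValueError("buffer_m must be positive")
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")

    minx, miny, maxx, maxy = line.bounds
    x0 = minx  # column edges tile from here
    y0 = miny - cell_m / 2.0  # row through miny is cell-centred

    col_lo = math.floor((minx - buffer_m - x0) / cell_m)
    col_hi = math.ceil((maxx + buffer_m - x0) / cell_m)
    row_lo = math.floor((miny - buffer_m - y0) / cell_m)
    row_hi = math.ceil((maxy + buffer_m - y0) / cell_m)

    cols = np.arange(col_lo, col_hi + 1)
    rows = np.arange(row_lo, row_hi + 1)
    cc, rr = np.meshgrid(cols, rows)
    cx = x0 + (cc + 0.5) * cell_m
    cy = y0 + (rr + 0.5) * cell_m

    points = shapely.points(cx.ravel(), cy.ravel())
    dist = shapely.distance(points, line)
    # strictly inside: centroids exactly at the buffer boundary (the strip
    # ends, and the rows tangent to a straight route) do not belong
    inside = dist < buffer_m - 1e-9

    cells = []
    for cell_id, (r, c, x, y) in enumerate(
        zip(rr.ravel()[inside], cc.ravel()[inside], cx.ravel()[inside], cy.ravel()[inside])
    ):
        cells.append(
            PredictionCell(
                cell_id=cell_id,
                row=int(r),
                col=int(c),
                centroid_x=float(x),
                centroid_y=float(y),
                size_m=cell_m,
                corridor=corridor,
            )
        )
    return cells


def cells_frame(cells: Sequence[PredictionCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "row": [c.row for c in cells],
            "col": [c.col for c in cells],
            "centroid_x": [c.centroid_x for c in cells],
            "centroid_y": [c.centroid_y for c in cells],
            "size_m": [c.size_m for c in cells],
            "corridor": [c.corridor for c in cells],
        }
    )


def predict_abundance(
    averaged: AveragedModel,
    cell_predictors: pd.DataFrame,
    standardization: StandardizationParams,
) -> np.ndarray:
    """Averaged-model predicted abundance per cell.

    Cell predictors are standardized with the *training* means/sds before
    prediction; a missing predictor column raises, naming the column.
    """
    needed: set[str] = set()
    for model in averaged.members:
        needed.update(model.spec.count_predictors)
        needed.update(model.spec.zero_predictors or ())
    missing = sorted(needed - set(cell_predictors.columns))
    if missing:
        raise KeyError(f"missing predictor column(s) for cells: {missing}")
    params = StandardizationParams(
        means=standardization.means[standardization.means.index.isin(cell_predictors.columns)],
        sds=standardization.sds[standardization.sds.index.isin(cell_predictors.columns)],
    )
    standardized = params.apply(cell_predictors)
    return averaged.predict(standardized)


@dataclass
class DecileScores:
    """Empirical-decile bin (1..10) of each cell's abundance."""

    scores: np.ndarray
    boundaries: np.ndarray
    degenerate: bool = False


def decile_scores(values: Sequence[float]) -> DecileScores:
    """Bin abundance values into empirical deciles, 1 = lowest.

    Ties share a bin (the lowest bin containing their common value); a
    surface where bins collapse entirely — e.g. all values identical — is
    flagged degenerate rather than jittered.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 cells for decile scores")
    boundaries = np.quantile(values, np.arange(1, 10) / 10.0)
    # count of boundaries strictly below each value -> bin index 0..9
    scores = 1 + np.searchsorted(boundaries, values, side="left")
    degenerate = len(np.unique(scores)) < 10
    return DecileScores(
        scores=scores.astype(int), boundaries=boundaries, degenerate=degenerate
    )


def community_score(
    group_deciles: Mapping[str, Sequence[int]],
) -> np.ndarray:
    """Product of per-group decile scores, scaled to a (0, 10] range.

    With g groups the product is divided by 10^(g-1) so that all-decile-10
    cells score exactly 10 (for four groups this is the product over 1000).
    Cell sets must match across groups.
    """
    if not group_deciles:
        raise ValueError("need at least one group")
    arrays = {g: np.asarray(v) for g, v in group_deciles.items()}
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("mismatched cell sets across groups")
    g = len(arrays)
    product = np.ones(lengths.pop(), dtype=float)
    for scores in arrays.values():
        if np.any((scores < 1) | (scores > 10)):
            raise ValueError("decile scores must lie in 1..10")
        product *= scores
    return product / 10.0 ** (g - 1)


@dataclass
class OverlapSegment:
    start_km: float
    end_km: float
    crossing_score: float
    approach_score: float
    classification: str  # both-high | crossing-only-high | approach-only-high | both-low


def overlap_report(
    positions_km: Sequence[float],
    crossing_scores: Sequence[float],
    approach_scores: Sequence[float],
    segment_km: float = 1.0,
    quantile: float = 0.75,
) -> list[OverlapSegment]:
    """Classify route segments by joint crossing/approach preference.

    Both score series are indexed by the same route positions.  Each
    ``segment_km`` bin gets the mean of each series and is classified against
    that series' ``quantile`` threshold (default: top quartile).  Segments
    high on both maps are the mitigation priorities; crossing-only-high
    segments are the "less ideal" case.  Constant score maps collapse to a
    single class and are flagged degenerate in the classification string.
    """
    positions = np.asarray(positions_km, dtype=float)
    crossing = np.asarray(crossing_scores, dtype=float)
    approach = np.asarray(approach_scores, dtype=float)
    if not (len(positions) == len(crossing) == len(approach)):
        raise ValueError("positions and score series must align")
    c_thresh = np.quantile(crossing, quantile)
    a_thresh = np.quantile(approach, quantile)
    degenerate = np.ptp(crossing) == 0 or np.ptp(approach) == 0
    if degenerate:
        warnings.warn("constant score map: overlap classes are degenerate")

    edges = np.arange(0.0, positions.max() + segment_km, segment_km)
    segments = []
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (positions >= a) & (positions < b)
        if not mask.any():
            continue
        c_mean = float(crossing[mask].mean())
        a_mean = float(approach[mask].mean())
        c_high = c_mean > c_thresh
        a_high = a_mean > a_thresh
        if degenerate:
            label = "degenerate"
        elif c_high and a_high:
            label = "both-high"
        elif c_high:
            label = "crossing-only-high"
        elif a_high:
            label = "approach-only-high"
        else:
            label = "both-low"
        segments.append(
            OverlapSegment(
                start_km=float(a),
                end_km=float(b),
                crossing_score=c_mean,
                approach_score=a_mean,
                classification=label,
            )
        )
    return segments


def cells_to_geojson(
    cells: Sequence[PredictionCell],
    properties: pd.DataFrame | None = None,
) -> dict:
    """GeoJSON FeatureCollection of square cell polygons with properties."""
    features = []
    for i, cell in enumerate(cells):
        h = cell.size_m / 2.0
        x, y = cell.centroid_x, cell.centroid_y
        ring = [
            [x - h, y - h],
            [x + h, y - h],
            [x + h, y + h],
            [x - h, y + h],
            [x - h, y - h],
        ]
        props: dict = {
            "cell_id": cell.cell_id,
            "row": cell.row,
            "col": cell.col,
            "corridor": cell.corridor,
        }
        if properties is not None:
            for name, series in properties.items():
                value = series.iloc[i]
                if isinstance(value, (np.integer,)):
                    value = int(value)
                elif isinstance(value, (np.floating,)):
                    value = float(value)
                props[name] = value
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(collection: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(collection, fh)
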