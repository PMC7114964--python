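"""Delineation of positive-relief seabed features from a BPI raster.

The delineation thresholds the BPI raster at a user-set "cutline" value,
grows 8-connected regions, filters them on peak BPI, footprint area and
minimum-bounding-rectangle width/length ratio, polygonises the survivors
along cell boundaries and finally expands each polygon by a buffer distance
(the cutline normally reaches a mound's lateral slopes rather than its base,
so the buffer compensates).

All three filters act on the RAW (pre-buffer) region; the buffer is a
cosmetic expansion. Buffered outlines that touch a neighbour are flagged
``merged_flag`` but never dissolved — resolving genuine merges is a manual
editing task downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .grid import Grid

__all__ = ["DelineationConfig", "FeaturePolygon", "delineate", "min_bounding_rectangle"]


@dataclass
class DelineationConfig:
    """Thresholds of the delineation, in the units of the input layers.

    Defaults are the operational values for 2-m bathymetry of small reef
    mounds: cutline BPI 3, minimum (peak) BPI 3.5, minimum area 50 m²,
    minimum width/length ratio 0.2 and a 4-m buffer.
    """

    cutline_bpi: float = 3.0
    min_bpi: float = 3.5
    min_area: float = 50.0
    min_wl_ratio: float = 0.2
    buffer_distance: float = 4.0

    def __post_init__(self) -> None:
        if self.min_bpi < self.cutline_bpi:
            raise ValueError("min_bpi must be >= cutline_bpi")
        if self.min_area <= 0:
            raise ValueError("min_area must be positive")
        if not 0 < self.min_wl_ratio <= 1:
            raise ValueError("min_wl_ratio must be in (0, 1]")
        if self.buffer_distance < 0:
            raise ValueError("buffer_distance must be >= 0")


@dataclass
class FeaturePolygon:
    """A delineated feature outline.

    ``ring`` is the buffered outline used by the description stage;
    ``raw_ring`` the pre-buffer outline traced along cell boundaries.
    ``merged_flag`` marks features whose buffered outline intersects a
    neighbour's (candidates for manual splitting); ``edited_flag`` records
    downstream manual modification.
    """

    feature_id: int
    ring: Polygon
    raw_ring: Polygon
    merged_flag: bool = False
    edited_flag: bool = False
    region_cells: np.ndarray = field(default=None, repr=False)  # (n, 2) row/col

    @property
    def area(self) -> float:
        return self.ring.area


def min_bounding_rectangle(poly: Polygon) -> tuple[float, float, float]:
    """Width, length and orientation of the minimum-area bounding rectangle.

    Width is the shorter side. Orientation is the azimuth of the LONG axis,
    clockwise from grid north, in [0, 180); 0 for a tie (square).
    """
    rect = poly.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate (point/line) region
        length = rect.length
        return 0.0, length, 0.0
    xs, ys = rect.exterior.coords.xy
    p = np.column_stack([xs, ys])[:4]
    e1 = p[1] - p[0]
    e2 = p[2] - p[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    if np.isclose(l1, l2):
        width = length = l1
        return width, length, 0.0
    if l1 >= l2:
        long_vec, length, width = e1, l1, l2
    else:
        long_vec, length, width = e2, l2, l1
    azimuth = np.degrees(np.arctan2(long_vec[0], long_vec[1])) % 180.0
    return float(width), float(length), float(azimuth)


def _region_polygon(rows: np.ndarray, cols: np.ndarray, grid: Grid) -> Polygon:
    """Union of the cell squares of one region (outline along cell edges)."""
    c = grid.cell_size
    x0, y0 = grid.origin
    xmin = x0 + cols * c
    ymax = y0 - rows * c
    boxes = shapely.box(xmin, ymax - c, xmin + c, ymax)
    merged = unary_union(boxes)
    if merged.geom_type == "MultiPolygon":
        # cells joined only across a corner: weld with a hairline dilation
        eps = c * 1e-6
        merged = unary_union(shapely.buffer(boxes, eps, quad_segs=1)).buffer(-eps)
        if merged.geom_type == "MultiPolygon":  # pragma: no cover
            merged = max(merged.geoms, key=lambda g: g.area)
    return merged


_EIGHT = np.ones((3, 3), dtype=int)


def delineate(bpi: Grid, config: DelineationConfig = DelineationConfig()) -> list[FeaturePolygon]:
    """Delineate positive features from a BPI raster.

    Returns one :class:`FeaturePolygon` per surviving region, ids assigned
    in raster scan order (deterministic for identical inputs).
    """
    valid = ~bpi.nodata_mask
    if not valid.any():
        warnings.warn("BPI raster is entirely nodata; no features delineated", stacklevel=2)
        return []
    mask = np.zeros(bpi.shape, bool)
    mask[valid] = bpi.values[valid] >= config.cutline_bpi
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=_EIGHT)
    cell_area = bpi.cell_size**2
    objects = ndimage.find_objects(labels)
    survivors: list[tuple[np.ndarray, np.ndarray, Polygon]] = []
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        rows, cols = np.nonzero(sub)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        if rows.size * cell_area < config.min_area:
            continue
        if np.nanmax(bpi.values[rows, cols]) < config.min_bpi:
            continue
        poly = _region_polygon(rows, cols, bpi)
        width, length, _ = min_bounding_rectangle(poly)
        if length > 0 and width / length < config.min_wl_ratio:
            continue
        survivors.append((rows, cols, poly))

    features: list[FeaturePolygon] = []
    buffered: list[Polygon] = []
    for rows, cols, raw in survivors:
        if config.buffer_distance > 0:
            ring = raw.buffer(config.buffer_distance, quad_segs=16, join_style="round")
        else:
            ring = raw
        buffered.append(ring)
        features.append(
            FeaturePolygon(
                feature_id=len(features) + 1,
                ring=ring,
                raw_ring=raw,
                region_cells=np.column_stack([rows, cols]),
            )
        )
    # flag (not dissolve) buffered outlines that touch a neighbour
    if len(features) > 1:
        tree = shapely.STRtree(buffered)
        pairs = tree.query(np.array(buffered, dtype=object), predicate="intersects")
        for a, b in pairs.T:
            if a != b:
                features[a].merged_flag = True
                features[b].merged_flag = True
    return features
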