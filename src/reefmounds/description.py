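"""Feature description: morphometric and acoustic attributes per feature.

For every delineated feature this module computes the attribute record used
downstream by the habitat model: planimetric area and perimeter, peak BPI,
minimum-bounding-rectangle width/length/orientation, water-depth statistics
(positive down), the depth of the deepest contour line confined inside the
outline, vertical relief, rugosity and backscatter statistics, the assumed
pre-mound "initial slope", plus the joined current speed and the live-coral
cover class.

Zonal membership is by cell centre inside the (buffered) outline. Vertical
relief follows the profile geometry: MaxVRelief = MaxWD - MinWD (summit above
the deepest in-polygon cell) and MinVRelief = ConfCL_WD - MinWD (summit above
the deepest confined contour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve
from shapely.geometry import LineString, Point, Polygon
from skimage import measure

from .delineation import FeaturePolygon, min_bounding_rectangle
from .grid import Grid, slope

__all__ = [
    "FeatureAttributes",
    "describe_features",
    "initial_slope",
    "join_current",
    "cover_class",
    "COVER_CLASSES",
    "attributes_table",
]

#: Five live-coral cover classes; half-open "]a;b]" bins plus the zero class.
COVER_CLASSES = ("=0", "]0;25]", "]25;50]", "]50;75]", "]75;100]")


@dataclass
class FeatureAttributes:
    """One attribute record per delineated feature (depths positive-down)."""

    feature_id: int
    area: float  # m^2, buffered outline
    perimeter: float  # m
    max_bpi: float
    mbg_width: float  # m, shorter rectangle side
    mbg_length: float  # m
    mbg_w_l: float
    mbg_orient: float  # degrees clockwise from north, [0, 180)
    min_wd: float  # m, shallowest point
    max_wd: float  # m, deepest point
    mean_wd: float
    confcl_wd: float  # depth of deepest confined contour line
    min_vrelief: float
    max_vrelief: float
    min_rug: float
    max_rug: float
    mean_rug: float
    min_bs: float = np.nan
    max_bs: float = np.nan
    mean_bs: float = np.nan
    initial_slp: float = np.nan  # decimal degrees
    max_current: float = np.nan  # m/s, joined from a coarse raster
    cover_pct: float = np.nan
    cover_class: str | None = None
    presence: bool | None = None


#: CSV column name per dataclass field (Table-style attribute names).
COLUMN_NAMES = {
    "feature_id": "FeatureID",
    "area": "Area",
    "perimeter": "Perimeter",
    "max_bpi": "Index",
    "mbg_width": "MBG_Width",
    "mbg_length": "MBG_Length",
    "mbg_w_l": "MBG_W_L",
    "mbg_orient": "MBG_Orient",
    "min_wd": "MinWD",
    "max_wd": "MaxWD",
    "mean_wd": "MeanWD",
    "confcl_wd": "ConfCL_WD",
    "min_vrelief": "MinVRelief",
    "max_vrelief": "MaxVRelief",
    "min_rug": "Min_Rug",
    "max_rug": "Max_Rug",
    "mean_rug": "Mean_Rug",
    "min_bs": "Min_BS",
    "max_bs": "Max_BS",
    "mean_bs": "Mean_BS",
    "initial_slp": "InitialSlp",
    "max_current": "MaxCurrent",
    "cover_pct": "CoverPct",
    "cover_class": "CoverClass",
    "presence": "Presence",
}


def attributes_table(records: list[FeatureAttributes]) -> pd.DataFrame:
    """Attribute records as a DataFrame with the canonical column names."""
    rows = [{COLUMN_NAMES[f.name]: getattr(r, f.name) for f in dc_fields(r)} for r in records]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# zonal helpers
# ---------------------------------------------------------------------------


def _cells_in_polygon(grid: Grid, poly: Polygon) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of cells whose centres fall inside the polygon."""
    minx, miny, maxx, maxy = poly.bounds
    r0, c0 = grid.index_of(minx, maxy)
    r1, c1 = grid.index_of(maxx, miny)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, grid.shape[0] - 1), min(c1, grid.shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return np.empty(0, int), np.empty(0, int)
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    xs = grid.origin[0] + (cols + 0.5) * grid.cell_size
    ys = grid.origin[1] - (rows + 0.5) * grid.cell_size
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    rr, cc = np.nonzero(inside)
    return rows[rr], cols[cc]


def _zonal(values: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    v = values[rows, cols]
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan, np.nan, np.nan
    return float(v.min()), float(v.max()), float(v.mean())


# ---------------------------------------------------------------------------
# deepest confined contour line
# ---------------------------------------------------------------------------


def _confined_contour_depth(
    dem: Grid,
    ring: Polygon,
    summit_xy: tuple[float, float],
    contour_interval: float,
) -> float:
    """Water depth of the deepest contour that closes entirely inside the
    outline and encloses the summit; NaN when no contour qualifies."""
    margin = 2 * dem.cell_size
    minx, miny, maxx, maxy = ring.bounds
    r0, c0 = dem.index_of(minx - margin, maxy + margin)
    r1, c1 = dem.index_of(maxx + margin, miny - margin)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, dem.shape[0] - 1), min(c1, dem.shape[1] - 1)
    window = dem.values[r0 : r1 + 1, c0 : c1 + 1]
    finite = window[np.isfinite(window)]
    if finite.size == 0:
        return np.nan
    zmin, zmax = finite.min(), finite.max()
    levels = np.arange(np.ceil(zmin / contour_interval), np.ceil(zmax / contour_interval)) * (
        contour_interval
    )
    summit = Point(summit_xy)
    cs = dem.cell_size
    for level in levels:  # ascending elevation = descending water depth
        for contour in measure.find_contours(window, level):
            if not np.allclose(contour[0], contour[-1]):
                continue
            x = dem.origin[0] + (c0 + contour[:, 1] + 0.5) * cs
            y = dem.origin[1] - (r0 + contour[:, 0] + 0.5) * cs
            if len(x) < 4:
                continue
            line = LineString(np.column_stack([x, y]))
            if not ring.contains(line):
                continue
            poly = Polygon(np.column_stack([x, y]))
            if not poly.is_valid:
                poly = poly.buffer(0)
            if poly.contains(summit):
                return float(-level)
    return np.nan


# ---------------------------------------------------------------------------
# initial slope
# ---------------------------------------------------------------------------


def initial_slope(dem: Grid, feature: FeaturePolygon) -> float:
    """Mean assumed pre-mound slope (decimal degrees) under a feature.

    The bathymetry inside the outline is removed and re-created by harmonic
    (Laplace) interpolation from the surrounding cells, then the Horn slope
    of the reconstructed surface is averaged over the voided cells. A linear
    seabed is reproduced exactly up to discretisation, so a mound planted on
    a plane returns the plane's slope.
    """
    rows, cols = _cells_in_polygon(dem, feature.ring)
    if rows.size == 0:
        raise ValueError(f"feature {feature.feature_id} covers no cell centres")
    nr, nc = dem.shape
    if rows.min() == 0 or cols.min() == 0 or rows.max() == nr - 1 or cols.max() == nc - 1:
        raise ValueError(
            f"feature {feature.feature_id} touches the raster edge; no closed boundary"
        )
    void = np.zeros(dem.shape, bool)
    void[rows, cols] = True
    # Dirichlet boundary: the 4-neighbours of the void region must be valid
    idx = {(r, c): k for k, (r, c) in enumerate(zip(rows, cols))}
    n = rows.size
    A = lil_matrix((n, n))
    b = np.zeros(n)
    for k, (r, c) in enumerate(zip(rows, cols)):
        A[k, k] = 4.0
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if void[rr, cc]:
                A[k, idx[(rr, cc)]] = -1.0
            else:
                z = dem.values[rr, cc]
                if not np.isfinite(z):
                    raise ValueError(
                        f"feature {feature.feature_id}: nodata on the interpolation boundary"
                    )
                b[k] += z
    filled = spsolve(A.tocsr(), b)
    recon = dem.values.copy()
    recon[rows, cols] = filled
    slp = slope(Grid(recon, dem.cell_size, dem.origin, dem.crs_tag))
    vals = slp.values[rows, cols]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"feature {feature.feature_id}: no slope values in infill")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# main description
# ---------------------------------------------------------------------------


def describe_features(
    dem: Grid,
    bpi: Grid,
    features: list[FeaturePolygon],
    rugosity_grid: Grid,
    backscatter: Grid | None = None,
    contour_interval: float = 0.5,
    compute_initial_slope: bool = True,
) -> list[FeatureAttributes]:
    """Compute the attribute record for every feature.

    All rasters must be co-registered with ``dem``. Attributes are measured
    on the buffered outline. Features covering no cell centres yield a record
    of NaNs with a warning.
    """
    for other, name in ((bpi, "bpi"), (rugosity_grid, "rugosity"), (backscatter, "backscatter")):
        if other is not None and (
            other.shape != dem.shape or not np.isclose(other.cell_size, dem.cell_size)
        ):
            raise ValueError(f"{name} raster is not co-registered with the DEM")
    records: list[FeatureAttributes] = []
    for feat in features:
        ring = feat.ring
        width, length, orient = min_bounding_rectangle(ring)
        rows, cols = _cells_in_polygon(dem, ring)
        if rows.size == 0:
            warnings.warn(
                f"feature {feat.feature_id} contains no cell centres; attributes are nodata",
                stacklevel=2,
            )
            records.append(
                FeatureAttributes(
                    feat.feature_id, ring.area, ring.length, np.nan, width, length,
                    width / length if length else np.nan, orient,
                    *[np.nan] * 9,
                )
            )
            continue
        zmin, zmax, zmean = _zonal(dem.values, rows, cols)
        min_wd, max_wd, mean_wd = -zmax, -zmin, -zmean
        _, max_bpi, _ = _zonal(bpi.values, rows, cols)
        rug_min, rug_max, rug_mean = _zonal(rugosity_grid.values, rows, cols)
        if backscatter is not None:
            bs_min, bs_max, bs_mean = _zonal(backscatter.values, rows, cols)
        else:
            bs_min = bs_max = bs_mean = np.nan
        zvals = dem.values[rows, cols]
        summit_k = int(np.nanargmax(zvals))
        summit_xy = dem.cell_center(int(rows[summit_k]), int(cols[summit_k]))
        confcl = _confined_contour_depth(dem, ring, summit_xy, contour_interval)
        max_vrelief = max_wd - min_wd
        min_vrelief = confcl - min_wd if np.isfinite(confcl) else np.nan
        init_slp = np.nan
        if compute_initial_slope:
            try:
                init_slp = initial_slope(dem, feat)
            except ValueError as exc:
                warnings.warn(f"initial slope unavailable: {exc}", stacklevel=2)
        records.append(
            FeatureAttributes(
                feature_id=feat.feature_id,
                area=ring.area,
                perimeter=ring.length,
                max_bpi=max_bpi,
                mbg_width=width,
                mbg_length=length,
                mbg_w_l=width / length if length else np.nan,
                mbg_orient=orient,
                min_wd=min_wd,
                max_wd=max_wd,
                mean_wd=mean_wd,
                confcl_wd=confcl,
                min_vrelief=min_vrelief,
                max_vrelief=max_vrelief,
                min_rug=rug_min,
                max_rug=rug_max,
                mean_rug=rug_mean,
                min_bs=bs_min,
                max_bs=bs_max,
                mean_bs=bs_mean,
                initial_slp=init_slp,
            )
        )
    return records


# ---------------------------------------------------------------------------
# joins
# ---------------------------------------------------------------------------


def join_current(
    attributes: list[FeatureAttributes],
    features: list[FeaturePolygon],
    current: Grid,
) -> list[FeatureAttributes]:
    """Attach the (coarse) current-speed value at each feature's centroid."""
    by_id = {f.feature_id: f for f in features}
    for rec in attributes:
        feat = by_id.get(rec.feature_id)
        if feat is None:
            continue
        cx, cy = feat.ring.centroid.x, feat.ring.centroid.y
        row, col = current.index_of(cx, cy)
        if not (0 <= row < current.shape[0] and 0 <= col < current.shape[1]):
            warnings.warn(
                f"feature {rec.feature_id} centroid outside the current raster",
                stacklevel=2,
            )
            rec.max_current = np.nan
            continue
        rec.max_current = float(current.values[row, col])
    return attributes


def classify_cover(pct: float) -> str:
    """Map a percent cover to its class: =0, ]0;25], ]25;50], ]50;75], ]75;100]."""
    if not np.isfinite(pct) or not 0 <= pct <= 100:
        raise ValueError(f"cover percentage out of range: {pct}")
    if pct == 0:
        return COVER_CLASSES[0]
    for hi, cls in zip((25, 50, 75, 100), COVER_CLASSES[1:]):
        if pct <= hi:
            return cls
    raise AssertionError("unreachable")


def cover_class(
    attributes: list[FeatureAttributes],
    features: list[FeaturePolygon],
    coral_polygons: list[Polygon],
) -> list[FeatureAttributes]:
    """Percent live-coral cover and cover class per feature.

    Cover is the area of intersection between the feature outline and the
    union of coral polygons, as a percentage of the outline area; the class
    bins are left-exclusive/right-inclusive and presence is cover > 0.
    """
    repaired = []
    for i, poly in enumerate(coral_polygons):
        if not poly.is_valid:
            fixed = poly.buffer(0)
            if fixed.is_empty or not fixed.is_valid:
                raise ValueError(f"coral polygon {i} is invalid and unrepairable")
            poly = fixed
        repaired.append(poly)
    coral_union = shapely.unary_union(repaired) if repaired else Polygon()
    by_id = {f.feature_id: f for f in features}
    for rec in attributes:
        feat = by_id.get(rec.feature_id)
        if feat is None:
            continue
        pct = 100.0 * feat.ring.intersection(coral_union).area / feat.ring.area
        pct = min(max(pct, 0.0), 100.0)
        rec.cover_pct = pct
        rec.cover_class = classify_cover(pct)
        rec.presence = pct > 0
    return attributes
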