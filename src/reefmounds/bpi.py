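"""Bathymetric positioning index (BPI).

BPI is the elevation of a cell minus the mean elevation over an annular
neighbourhood around it. Positive values mark cells shallower than their
surroundings (ridges, mound summits), negative values mark locally deep
cells (depressions), and values near zero flats or constant slopes. Raw
values are used directly as delineation thresholds; no standardisation is
applied.
"""

from __future__ import annotations

from .grid import AnnulusSpec, Grid, focal_mean_annulus

__all__ = ["compute_bpi", "DEFAULT_ANNULUS"]

#: The "i8 x o24" neighbourhood: inner radius 8 cells, outer radius 24.
DEFAULT_ANNULUS = AnnulusSpec(8, 24)


def compute_bpi(
    grid: Grid,
    annulus: AnnulusSpec = DEFAULT_ANNULUS,
    min_valid_fraction: float = 0.5,
) -> Grid:
    """BPI = z - focal annulus mean of z, on an up-positive elevation grid."""
    mean = focal_mean_annulus(grid, annulus, min_valid_fraction)
    return grid.like(grid.values - mean.values)
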