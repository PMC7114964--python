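"""Independent brute-force oracles the implementation is checked against.

Everything here is written as the slowest, most literal version of each
definition (double loops, pairwise counts, rejection sampling) and shares no
code with the package paths it verifies.
"""

from __future__ import annotations

import numpy as np


def annulus_mean_brute(values: np.ndarray, row: int, col: int, inner: int, outer: int):
    """Double-loop annular mean around one cell; NaN-aware; None if empty."""
    nr, nc = values.shape
    total, count = 0.0, 0
    for r in range(nr):
        for c in range(nc):
            d = np.hypot(r - row, c - col)
            if inner <= d <= outer and np.isfinite(values[r, c]):
                total += values[r, c]
                count += 1
    if count == 0:
        return None
    return total / count


def horn_slope_brute(values: np.ndarray, row: int, col: int, cell: float) -> float:
    """Horn 3x3 slope (degrees) at an interior cell, written out longhand."""
    z = values
    a, b, c = z[row - 1, col - 1], z[row - 1, col], z[row - 1, col + 1]
    d, f = z[row, col - 1], z[row, col + 1]
    g, h, i = z[row + 1, col - 1], z[row + 1, col], z[row + 1, col + 1]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell)
    return float(np.degrees(np.arctan(np.sqrt(dzdx**2 + dzdy**2))))


def sd3x3_brute(values: np.ndarray, row: int, col: int) -> float:
    """Population SD of the full 3x3 window around an interior cell."""
    window = values[row - 1 : row + 2, col - 1 : col + 2].ravel()
    return float(np.sqrt(np.mean((window - window.mean()) ** 2)))


def flood_fill_regions(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected regions of a boolean mask by literal BFS flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    regions = []
    nr, nc = mask.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            frontier = [(r0, c0)]
            seen[r0, c0] = True
            region = set()
            while frontier:
                r, c = frontier.pop()
                region.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            frontier.append((rr, cc))
            regions.append(region)
    return regions


def min_area_rect_brute(points: np.ndarray) -> tuple[float, float]:
    """(width, length) of the minimum-area bounding rectangle.

    Rotating-calipers style: the optimal rectangle is aligned with a hull
    edge, so try the direction of every pair of points (superset of hull
    edges) and keep the smallest-area axis-aligned box after rotation.
    """
    pts = np.asarray(points, float)
    best = None
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            v = pts[j] - pts[i]
            norm = np.hypot(*v)
            if norm == 0:
                continue
            ux, uy = v / norm
            proj1 = pts @ np.array([ux, uy])
            proj2 = pts @ np.array([-uy, ux])
            s1 = proj1.max() - proj1.min()
            s2 = proj2.max() - proj2.min()
            if best is None or s1 * s2 < best[0]:
                best = (s1 * s2, min(s1, s2), max(s1, s2))
    return best[1], best[2]


def auc_pairwise_brute(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as concordant positive/negative pairs, ties counted half."""
    pos = scores[np.asarray(labels, bool)]
    neg = scores[~np.asarray(labels, bool)]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def cover_fraction_monte_carlo(feature_poly, coral_polys, rng, n: int = 200_000) -> float:
    """Rejection-sampling estimate of covered fraction of a feature outline."""
    import shapely

    minx, miny, maxx, maxy = feature_poly.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    inside = shapely.contains_xy(feature_poly, xs, ys)
    xs, ys = xs[inside], ys[inside]
    covered = np.zeros(len(xs), bool)
    for poly in coral_polys:
        covered |= shapely.contains_xy(poly, xs, ys)
    return covered.mean()
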