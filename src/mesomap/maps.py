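"""Delaunay-based cell-packing and proliferation-index maps.

Nucleus centroids become nodes of a Delaunay triangulation whose edges
define "nearest neighbours".  Local cell packing at a cell is the mean
length of its incident Delaunay edges, smoothed by averaging with its
neighbours (one corona by default).  The local labelling (proliferation)
index is the fraction of label-positive cells in the cell's *double
corona*: the cell, its neighbours, and their neighbours, as a set.

Serial sections are pooled by applying their rigid transforms,
concatenating the centroid tables, and re-triangulating, so maps on the
pooled field average over sections.  Maps are rendered as Voronoi tiles
clipped to a domain polygon, coloured by the per-cell value.

Edges on the convex hull can be arbitrarily long and dominated by the
tissue boundary rather than cell packing; hull points are flagged and
excluded from regional means and colour autoscaling by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay, Voronoi, cKDTree
from shapely.geometry import Point, Polygon

from .fields import CentroidField
from .geometry import RigidTransform2D

__all__ = [
    "NeighborGraph",
    "PackingMap",
    "ProliferationMap",
    "RegionMask",
    "RegionStats",
    "VoronoiMap",
    "delaunay_neighbors",
    "interior_points",
    "packing_map",
    "double_corona_index",
    "align_and_pool",
    "voronoi_heatmap",
    "regional_mean",
    "compare_groups",
]

DEDUP_TOL_UM = 1e-6


@dataclass
class NeighborGraph:
    """Delaunay adjacency with per-edge lengths and convex-hull flags."""

    adjacency: list[set[int]]
    edge_lengths: dict[tuple[int, int], float]  # keyed (i, j) with i < j
    hull_flags: np.ndarray

    def __len__(self) -> int:
        return len(self.adjacency)

    def neighbors(self, i: int) -> set[int]:
        return self.adjacency[i]

    def edge_length(self, i: int, j: int) -> float:
        return self.edge_lengths[(i, j) if i < j else (j, i)]


@dataclass
class PackingMap:
    """Per-cell local packing: raw mean incident edge length s_i and smoothed s̄_i (μm)."""

    raw_mean_edge: np.ndarray
    smoothed_mean_edge: np.ndarray
    hull_flags: np.ndarray


@dataclass
class ProliferationMap:
    """Per-cell local labelling index L_i in [0, 1] over the double corona."""

    local_index: np.ndarray
    corona_size: np.ndarray


@dataclass
class RegionMask:
    """A named analysis region (e.g. anterior/middle/posterior third)."""

    polygon: Polygon | list[tuple[float, float]]
    name: str = "region"

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid:
            raise ValueError(f"region {self.name!r}: polygon must be simple (non-self-intersecting)")

    def contains(self, points: np.ndarray) -> np.ndarray:
        import shapely

        pts = np.atleast_2d(points)
        return shapely.contains_xy(self.polygon, pts[:, 0], pts[:, 1])


@dataclass
class RegionStats:
    mean: float
    sd: float
    n: int
    name: str = "region"


def delaunay_neighbors(field: CentroidField | np.ndarray) -> NeighborGraph:
    """Delaunay triangulation of the centroids as a neighbour graph.

    Requires at least 3 non-collinear points.  Cocircular degeneracies
    are resolved by Qhull's exact joggle-free tie-break.
    """
    pts = field.points if isinstance(field, CentroidField) else np.asarray(field, dtype=float)
    if len(pts) < 3:
        raise ValueError("Delaunay triangulation needs at least 3 points")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # Qhull raises its own error class for flat inputs
        raise ValueError(f"Delaunay triangulation failed (collinear input?): {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("all points are collinear; no triangulation exists")
    n = len(pts)
    adjacency: list[set[int]] = [set() for _ in range(n)]
    edge_lengths: dict[tuple[int, int], float] = {}
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            if i > j:
                i, j = j, i
            if (i, j) not in edge_lengths:
                edge_lengths[(i, j)] = float(np.linalg.norm(pts[i] - pts[j]))
                adjacency[i].add(j)
                adjacency[j].add(i)
    hull = np.zeros(n, dtype=bool)
    hull[np.unique(tri.convex_hull)] = True
    return NeighborGraph(adjacency=adjacency, edge_lengths=edge_lengths, hull_flags=hull)


def packing_map(graph: NeighborGraph, smooth_depth: int = 1, include_hull: bool = False) -> PackingMap:
    """Local cell packing from a neighbour graph.

    s_i is the mean length of edges incident to cell i; the smoothed
    value averages s over the cell plus ``smooth_depth`` coronas of
    neighbours (default one corona).  Convex-hull cells have s_i
    dominated by arbitrarily long boundary edges, so by default their
    raw values are left out of neighbours' smoothing averages
    (``include_hull=True`` restores plain averaging); hull cells
    themselves still receive raw and smoothed values.
    """
    n = len(graph)
    raw = np.empty(n)
    for i in range(n):
        if not graph.adjacency[i]:
            raise ValueError(f"point {i} is isolated; not a valid triangulation")
        raw[i] = np.mean([graph.edge_length(i, j) for j in graph.adjacency[i]])
    smoothed = np.empty(n)
    for i in range(n):
        region = _corona(graph, i, smooth_depth)
        if not include_hull:
            trimmed = [j for j in region if not graph.hull_flags[j]]
            region = trimmed if trimmed else list(region)
        smoothed[i] = raw[list(region)].mean()
    return PackingMap(raw_mean_edge=raw, smoothed_mean_edge=smoothed, hull_flags=graph.hull_flags.copy())


def interior_points(graph: NeighborGraph, depth: int = 2) -> np.ndarray:
    """Boolean mask of cells at graph distance > ``depth`` from the convex hull.

    Cells on the hull have edge lengths dominated by the tissue boundary,
    and one-corona smoothing spreads that artefact one step inward, so
    map statistics should be read at least two steps inside (the default).
    """
    bad = set(np.flatnonzero(graph.hull_flags))
    for _ in range(depth):
        bad |= {j for i in bad for j in graph.adjacency[i]}
    mask = np.ones(len(graph), dtype=bool)
    mask[list(bad)] = False
    return mask


def _corona(graph: NeighborGraph, i: int, depth: int) -> set[int]:
    region = {i}
    frontier = {i}
    for _ in range(depth):
        frontier = set().union(*(graph.adjacency[j] for j in frontier)) - region
        region |= frontier
    return region


def double_corona_index(graph: NeighborGraph, label_flags: np.ndarray) -> ProliferationMap:
    """Local labelling index over the cell plus a double corona of neighbours.

    The region for cell i is {i} ∪ N(i) ∪ N(N(i)) as a set (no double
    counting); the index is the fraction of label-positive cells in it.
    """
    if label_flags is None:
        raise ValueError("label flags are required for the proliferation index")
    flags = np.asarray(label_flags, dtype=bool)
    if len(flags) != len(graph):
        raise ValueError("label flags must align with graph nodes")
    n = len(graph)
    idx = np.empty(n)
    size = np.empty(n, dtype=int)
    for i in range(n):
        region = list(_corona(graph, i, 2))
        size[i] = len(region)
        idx[i] = flags[region].mean()
    return ProliferationMap(local_index=idx, corona_size=size)


def align_and_pool(
    sections: list[tuple[CentroidField, RigidTransform2D]],
    dedup_tol_um: float = DEDUP_TOL_UM,
) -> CentroidField:
    """Register serial sections into the first section's frame and concatenate.

    Points closer than ``dedup_tol_um`` after pooling are merged (first
    occurrence kept) because duplicate points break the triangulation
    predicates.  Downstream maps should be recomputed on the pooled
    field (re-triangulation) so the averaging happens across sections.
    """
    if not sections:
        raise ValueError("need at least one section")
    pts_list, flag_list, sect_list = [], [], []
    has_flags = all(f.label_flags is not None for f, _ in sections)
    for k, (field, transform) in enumerate(sections):
        pts_list.append(transform.apply(field.points))
        sect_list.append(field.section_id if field.section_id.any() else np.full(len(field), k))
        if has_flags:
            flag_list.append(field.label_flags)
    pts = np.vstack(pts_list)
    sect = np.concatenate(sect_list)
    flags = np.concatenate(flag_list) if has_flags else None
    if dedup_tol_um > 0 and len(pts) > 1:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(dedup_tol_um, output_type="ndarray")
        drop = np.zeros(len(pts), dtype=bool)
        for i, j in pairs:
            lo, hi = (i, j) if i < j else (j, i)
            if not drop[lo]:
                drop[hi] = True
        keep = ~drop
        pts, sect = pts[keep], sect[keep]
        flags = flags[keep] if flags is not None else None
    return CentroidField(pts, flags, sect)


def _finite_voronoi_polygons(vor: Voronoi, radius: float) -> list[np.ndarray]:
    """Close the unbounded Voronoi regions by extending ridge rays to ``radius``."""
    centre = vor.points.mean(axis=0)
    all_ridges: dict[int, list[tuple[int, int, int]]] = {}
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        all_ridges.setdefault(p1, []).append((p2, v1, v2))
        all_ridges.setdefault(p2, []).append((p1, v1, v2))
    polys: list[np.ndarray] = []
    for p, region_idx in enumerate(vor.point_region):
        vertices = vor.regions[region_idx]
        if all(v >= 0 for v in vertices):
            polys.append(vor.vertices[vertices])
            continue
        finite = [v for v in vertices if v >= 0]
        new_pts = [vor.vertices[v] for v in finite]
        for p2, v1, v2 in all_ridges.get(p, []):
            if v2 < 0:
                v1, v2 = v2, v1
            if v1 >= 0:
                continue
            tangent = vor.points[p2] - vor.points[p]
            tangent /= np.linalg.norm(tangent)
            normal = np.array([-tangent[1], tangent[0]])
            midpoint = (vor.points[p] + vor.points[p2]) / 2
            if np.dot(midpoint - centre, normal) < 0:
                normal = -normal
            new_pts.append(vor.vertices[v2] + normal * radius)
        arr = np.array(new_pts)
        angles = np.arctan2(arr[:, 1] - arr[:, 1].mean(), arr[:, 0] - arr[:, 0].mean())
        polys.append(arr[np.argsort(angles)])
    return polys


@dataclass
class VoronoiMap:
    """Voronoi tiles clipped to a domain, one value (and clamped colour value) per tile."""

    tiles: list[Polygon]
    values: np.ndarray
    clamped: np.ndarray
    colour_range: tuple[float, float]
    domain: Polygon

    def plot(self, ax=None, cmap: str = "viridis", show_points: bool = False, points: np.ndarray | None = None):
        import matplotlib.pyplot as plt
        from matplotlib import colormaps
        from matplotlib.colors import Normalize
        from matplotlib.cm import ScalarMappable

        if ax is None:
            _, ax = plt.subplots()
        norm = Normalize(*self.colour_range)
        cm = colormaps[cmap]
        for tile, v in zip(self.tiles, self.clamped):
            if tile.is_empty:
                continue
            geoms = tile.geoms if tile.geom_type == "MultiPolygon" else [tile]
            for g in geoms:
                ax.fill(*g.exterior.xy, color=cm(norm(v)), linewidth=0.2, edgecolor="w")
        if show_points and points is not None:
            ax.plot(points[:, 0], points[:, 1], "k.", ms=1)
        ax.set_aspect("equal")
        ax.invert_yaxis()  # image convention: y increases downward
        plt.colorbar(ScalarMappable(norm=norm, cmap=cm), ax=ax, shrink=0.8)
        return ax


def voronoi_heatmap(
    field: CentroidField,
    values: np.ndarray,
    domain: RegionMask | Polygon | None = None,
    colour_range: tuple[float, float] | None = None,
    hull_flags: np.ndarray | None = None,
) -> VoronoiMap:
    """Colour Voronoi tiles around each centroid by its map value.

    Tiles are clipped to the domain polygon and partition it.  Without a
    domain, tiles are clipped to the convex hull buffered by the field's
    median nearest-neighbour scale.  ``colour_range`` defaults to the
    [2.5, 97.5] percentile of non-hull values; values outside the range
    are clamped to its ends.
    """
    pts = field.points
    values = np.asarray(values, dtype=float)
    if len(pts) < 4:
        raise ValueError("Voronoi heat map needs at least 4 points")
    if len(values) != len(pts):
        raise ValueError("need exactly one value per point")
    if domain is None:
        from shapely.geometry import MultiPoint

        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        poly = MultiPoint([Point(*p) for p in pts]).convex_hull.buffer(float(np.median(d[:, 1])))
    else:
        poly = domain.polygon if isinstance(domain, RegionMask) else domain
    span = np.ptp(pts, axis=0).max() * 4 + 1
    vor = Voronoi(pts)
    raw_polys = _finite_voronoi_polygons(vor, radius=span)
    tiles = [Polygon(p).buffer(0).intersection(poly) for p in raw_polys]
    if colour_range is None:
        mask = ~hull_flags if hull_flags is not None else np.ones(len(values), dtype=bool)
        colour_range = (float(np.percentile(values[mask], 2.5)), float(np.percentile(values[mask], 97.5)))
    clamped = np.clip(values, colour_range[0], colour_range[1])
    return VoronoiMap(tiles=tiles, values=values, clamped=clamped,
                      colour_range=colour_range, domain=poly)


def regional_mean(
    map_values: np.ndarray,
    region: RegionMask,
    field: CentroidField,
    exclude_hull: np.ndarray | None = None,
) -> RegionStats:
    """Mean and SD of per-cell values whose centroid lies inside the region."""
    values = np.asarray(map_values, dtype=float)
    inside = region.contains(field.points)
    if exclude_hull is not None:
        inside &= ~np.asarray(exclude_hull, dtype=bool)
    if not inside.any():
        raise ValueError(f"region {region.name!r} contains no points")
    sel = values[inside]
    return RegionStats(mean=float(sel.mean()), sd=float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
                       n=int(inside.sum()), name=region.name)


def compare_groups(values_a, values_b) -> float:
    """Welch two-sample t-test p-value between two groups of map values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
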