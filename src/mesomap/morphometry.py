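"""Palatal-shelf morphometry from annotated section outlines.

Two gross measurements characterise a shelf in a frontal section:

* **protrusion** — the length of the line from the distal edge of the
  shelf, perpendicular to the shelf-boundary reference line, to that
  line.  The boundary line joins the two "axils" of the outgrowth
  before elevation, or the nasal shoulder and nearest oral surface
  after elevation; the landmarks are supplied by the annotator.
* **thickness** — the width of the shelf measured at right angles to
  the protrusion axis, one quarter of the protrusion length away from
  the distal edge (the chord of the outline at that station).

Both are invariant under rigid motion of the annotation and scale
linearly under uniform scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point, Polygon

__all__ = ["ShelfAnnotation", "protrusion_length", "thickness_at_quarter", "stage_summary"]

LANDMARK_TOL_UM = 1.0


@dataclass
class ShelfAnnotation:
    """Mesenchyme outline plus the three measurement landmarks (μm).

    ``boundary_a`` and ``boundary_b`` define the shelf-boundary line;
    ``distal_point`` marks the distal edge of the shelf on the outline.
    If ``distal_point`` is None it is chosen automatically as the
    outline vertex farthest from the boundary line.
    """

    outline: Sequence[tuple[float, float]] | Polygon
    boundary_a: tuple[float, float]
    boundary_b: tuple[float, float]
    distal_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.polygon = self.outline if isinstance(self.outline, Polygon) else Polygon(self.outline)
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("outline must be a simple polygon with positive area")
        a, b = np.asarray(self.boundary_a, float), np.asarray(self.boundary_b, float)
        if np.allclose(a, b):
            raise ValueError("boundary landmarks must be distinct")
        if self.distal_point is None:
            verts = np.asarray(self.polygon.exterior.coords)[:-1]
            ab = b - a
            d = np.abs(ab[0] * (verts[:, 1] - a[1]) - ab[1] * (verts[:, 0] - a[0])) / np.linalg.norm(ab)
            self.distal_point = tuple(verts[np.argmax(d)])
        for name, p in (("boundary_a", a), ("boundary_b", b),
                        ("distal_point", np.asarray(self.distal_point, float))):
            if self.polygon.exterior.distance(Point(*p)) > LANDMARK_TOL_UM and not self.polygon.contains(Point(*p)):
                raise ValueError(f"{name} must lie on or within {LANDMARK_TOL_UM} μm of the outline")


def _boundary_axis(annotation: ShelfAnnotation) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Return (distal point, foot of perpendicular, unit axis distal→boundary, protrusion)."""
    a = np.asarray(annotation.boundary_a, float)
    b = np.asarray(annotation.boundary_b, float)
    d = np.asarray(annotation.distal_point, float)
    u = (b - a) / np.linalg.norm(b - a)
    t = np.dot(d - a, u)
    foot = a + t * u
    if t < 0 or t > np.linalg.norm(b - a):
        warnings.warn("perpendicular foot falls outside the boundary segment; "
                      "using the infinite boundary line", stacklevel=3)
    length = float(np.linalg.norm(d - foot))
    if length == 0:
        raise ValueError("distal point lies on the boundary line; protrusion undefined")
    axis = (foot - d) / length
    return d, foot, axis, length


def protrusion_length(annotation: ShelfAnnotation) -> float:
    """Perpendicular distance (μm) from the distal edge to the shelf-boundary line."""
    return _boundary_axis(annotation)[3]


def thickness_at_quarter(annotation: ShelfAnnotation) -> float:
    """Shelf width (μm) perpendicular to the protrusion axis at protrusion/4 from the distal edge.

    If the cutting line crosses the outline more than twice, the chord
    is the intersection component that brackets the protrusion axis.
    """
    d, _, axis, length = _boundary_axis(annotation)
    station = d + (length / 4.0) * axis
    perp = np.array([-axis[1], axis[0]])
    span = 4.0 * (length + np.sqrt(annotation.polygon.area)) + 1.0
    cut = LineString([station - span * perp, station + span * perp])
    chord = cut.intersection(annotation.polygon)
    if chord.is_empty:
        raise ValueError("thickness line does not intersect the outline")
    if chord.geom_type == "LineString":
        return float(chord.length)
    # multiple components: keep the one crossing the protrusion axis
    for geom in chord.geoms:
        if geom.distance(Point(*station)) < 1e-9:
            return float(geom.length)
    raise ValueError("no intersection component brackets the protrusion axis")


def measure(annotation: ShelfAnnotation) -> dict[str, float]:
    """Both shelf measurements for one annotated section."""
    return {"protrusion_um": protrusion_length(annotation),
            "thickness_um": thickness_at_quarter(annotation)}


def stage_summary(
    measurements: pd.DataFrame,
    value_cols: Sequence[str] = ("protrusion_um", "thickness_um"),
    group_col: str = "genotype",
    stage_col: str = "stage",
) -> pd.DataFrame:
    """Per-stage group means ± SD with Welch t-test p-values.

    ``measurements`` is tidy: one row per embryo/section with stage and
    genotype columns plus the measurement columns.  Exactly two genotype
    groups are compared per stage; stages with a single observation in a
    group report the mean but skip the test (with a warning).  The
    significance classes mirror the usual figure convention
    (*(<0.05), **(<0.01), ***(<0.001)).
    """
    rows = []
    for stage, stage_df in measurements.groupby(stage_col, sort=True):
        groups = [g for g, _ in stage_df.groupby(group_col, sort=True)]
        if len(stage_df) == 0:
            warnings.warn(f"stage {stage}: no observations; row omitted", stacklevel=2)
            continue
        for col in value_cols:
            row: dict = {stage_col: stage, "measure": col}
            series = {g: gdf[col].dropna().to_numpy() for g, gdf in stage_df.groupby(group_col, sort=True)}
            for g, vals in series.items():
                row[f"{g}_mean"] = vals.mean() if len(vals) else np.nan
                row[f"{g}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
                row[f"{g}_n"] = len(vals)
            if len(groups) == 2 and all(len(series[g]) >= 2 for g in groups):
                a, b = series[groups[0]], series[groups[1]]
                if a.std() == 0 and b.std() == 0:
                    p = 1.0 if a.mean() == b.mean() else 0.0
                else:
                    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                row["p_value"] = p
                row["significance"] = ("***" if p < 0.001 else "**" if p < 0.01
                                       else "*" if p < 0.05 else "")
            else:
                if len(groups) == 2:
                    warnings.warn(f"stage {stage}: a group has a single observation; test skipped",
                                  stacklevel=2)
                row["p_value"] = np.nan
                row["significance"] = ""
            rows.append(row)
    return pd.DataFrame(rows)
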