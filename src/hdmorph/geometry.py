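"""Contour-based morphometry of bowel-wall layers.

A specimen is a set of manually delineated boundary polylines in physical
micrometre coordinates.  Each histoanatomic layer (mucosa, submucosa,
muscularis interna, myenteric tissue layer, muscularis externa, and the full
wall) is represented by an inner (luminal-side) and an outer boundary
contour.  Thickness is sampled at fixed arc-length intervals (14 µm by
default) along the inner boundary: at every sample a ray is cast along the
local inward-to-outward normal and the distance to its first intersection
with the outer boundary is the local thickness.  Per-layer summaries (mean
and SD of thickness, enclosed area, boundary lengths) and the two derived
ratios — muscularis interna / muscularis externa mean thickness, and the
submucosal inner/outer length "folding" ratio — are reported in mm-based
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "LAYERS",
    "ALL_LAYERS",
    "Contour",
    "LayerDelineation",
    "LayerMeasurement",
    "SpecimenMeasurement",
    "ResampledContour",
    "ThicknessProfile",
    "DegenerateContourError",
    "resample_contour",
    "measure_thickness",
    "layer_statistics",
    "folding_ratio",
    "measure_specimen",
]

#: Histoanatomic layers ordered from the lumen outwards.
LAYERS = (
    "mucosa",
    "submucosa",
    "muscularis_interna",
    "myenteric",
    "muscularis_externa",
)
ALL_LAYERS = LAYERS + ("full_wall",)

UM_PER_MM = 1000.0


class DegenerateContourError(ValueError):
    """Raised when a delineation is too short or malformed to measure."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contour:
    """An ordered boundary polyline in µm coordinates.

    Parameters
    ----------
    points
        ``(n, 2)`` array of vertices in µm.  For closed contours the closing
        edge from the last vertex back to the first is implicit; a repeated
        first vertex at the end is stripped on construction.
    closed
        Whether the polyline is a closed ring (full circumference) or an
        open arc (partial delineation).
    label
        Free-text boundary name.
    """

    points: np.ndarray
    closed: bool
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour coordinates must be finite")
        if self.closed and len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 distinct points")
        seg = np.diff(pts, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ValueError("consecutive duplicate points in contour")
        if self.closed:
            ring = LineString(np.vstack([pts, pts[:1]]))
            if not ring.is_simple:
                raise ValueError("closed contour is self-intersecting")
        object.__setattr__(self, "points", pts)

    @property
    def vertices_with_closure(self) -> np.ndarray:
        """Vertices with the first point appended for closed contours."""
        if self.closed:
            return np.vstack([self.points, self.points[:1]])
        return self.points

    @property
    def length(self) -> float:
        """Total arc length in µm (perimeter for closed contours)."""
        v = self.vertices_with_closure
        seg = np.diff(v, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    @property
    def signed_area(self) -> float:
        """Shoelace signed area in µm² (positive for counter-clockwise)."""
        v = self.vertices_with_closure
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

    def to_shapely(self) -> LineString | Polygon:
        if self.closed:
            return Polygon(self.points)
        return LineString(self.points)

    def transformed(self, rotation_rad: float = 0.0, translation=(0.0, 0.0)) -> "Contour":
        """Rigidly transformed copy (used for invariance checks)."""
        c, s = math.cos(rotation_rad), math.sin(rotation_rad)
        rot = np.array([[c, -s], [s, c]])
        pts = self.points @ rot.T + np.asarray(translation, dtype=float)
        return Contour(pts, self.closed, self.label)


@dataclass(frozen=True)
class LayerDelineation:
    """Paired inner (luminal-side) and outer boundary of one layer."""

    layer: str
    inner: Contour
    outer: Contour

    def __post_init__(self) -> None:
        if self.inner.closed != self.outer.closed:
            raise ValueError("inner and outer contours must both be closed or both open")
        if self.inner.closed:
            pin = Polygon(self.inner.points)
            pout = Polygon(self.outer.points)
            if not shapely.contains_properly(pout, pin):
                raise ValueError(
                    f"inner contour of layer {self.layer!r} is not strictly "
                    "inside the outer contour"
                )

    @property
    def closed(self) -> bool:
        return self.inner.closed


@dataclass(frozen=True)
class LayerMeasurement:
    """Per-layer summary statistics, mm-based units."""

    layer: str
    mean_thickness: float  # mm
    sd_thickness: float  # mm, SD of per-sample thicknesses within the specimen
    area: float  # mm²
    inner_length: float  # mm
    outer_length: float  # mm
    n_samples: int
    coverage_fraction: float  # fraction of the circumference delineated
    n_fallback: int = 0  # samples measured by nearest-point fallback

    def __post_init__(self) -> None:
        if self.mean_thickness <= 0:
            raise ValueError("mean thickness must be positive")
        if self.sd_thickness < 0 or self.area <= 0 or self.n_samples < 1:
            raise ValueError("invalid layer measurement")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError("coverage fraction must be in (0, 1]")


@dataclass
class SpecimenMeasurement:
    """All layer measurements for one specimen plus the derived ratios."""

    specimen_id: str
    segment: str  # "aganglionic" | "ganglionic"
    layers: dict[str, LayerMeasurement]
    mi_me_ratio: float | None = None
    folding_ratio: float | None = None
    patient_id: str | None = None

    def to_features(self) -> dict[str, float | None]:
        """Flat feature mapping used by the cohort statistics."""
        feats: dict[str, float | None] = {}
        for name in ALL_LAYERS:
            m = self.layers.get(name)
            feats[name] = m.mean_thickness if m is not None else None
        feats["mi_me_ratio"] = self.mi_me_ratio
        feats["folding_ratio"] = self.folding_ratio
        return feats


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResampledContour:
    """Equidistant arc-length samples with unit tangents."""

    points: np.ndarray  # (m, 2) µm
    tangents: np.ndarray  # (m, 2) unit vectors
    arc_positions: np.ndarray  # (m,) µm along the contour
    spacing: float  # actual spacing used, µm
    closed: bool

    def __len__(self) -> int:
        return len(self.points)


def resample_contour(c: Contour, spacing: float) -> ResampledContour:
    """Resample a contour at fixed arc-length intervals.

    For closed contours the nominal spacing is adjusted to the nearest value
    that divides the perimeter evenly (``floor(L / spacing)`` samples), so
    samples are strictly uniform around the ring.  For open contours samples
    sit at 0, ``spacing``, 2·``spacing``, … with the final sample placed on
    the end point (the last gap may be shorter).

    Tangents are unit vectors from local finite differences of the sampled
    polyline.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    total = c.length
    if total < spacing:
        raise DegenerateContourError(
            f"contour length {total:.1f} µm is shorter than one {spacing:g} µm interval"
        )
    verts = c.vertices_with_closure
    seg = np.diff(verts, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    if c.closed:
        n = int(math.floor(total / spacing))
        actual = total / n
        s = np.arange(n) * actual
    else:
        s = np.arange(0.0, total, spacing)
        if total - s[-1] > 1e-9:
            s = np.append(s, total)
        actual = float(spacing)

    x = np.interp(s, cum, verts[:, 0])
    y = np.interp(s, cum, verts[:, 1])
    pts = np.column_stack([x, y])

    if c.closed:
        d = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    else:
        d = np.empty_like(pts)
        d[1:-1] = pts[2:] - pts[:-2]
        d[0] = pts[1] - pts[0]
        d[-1] = pts[-1] - pts[-2]
    norms = np.hypot(d[:, 0], d[:, 1])
    norms[norms == 0.0] = 1.0
    tangents = d / norms[:, None]
    return ResampledContour(pts, tangents, s, float(actual), c.closed)


# ---------------------------------------------------------------------------
# thickness measurement
# ---------------------------------------------------------------------------


def _ray_polyline_first_hit(
    origins: np.ndarray,
    directions: np.ndarray,
    polyline: np.ndarray,
    t_min: float = 1e-6,
) -> np.ndarray:
    """Distance from each origin along its ray to the first polyline crossing.

    Fully vectorised ray/segment intersection; returns ``inf`` where a ray
    never meets the polyline.  ``t_min`` discards hits at the origin itself.
    """
    a = polyline[:-1]
    e = np.diff(polyline, axis=0)  # (k, 2)
    # for each (sample i, segment k): origins[i] + t*directions[i] = a[k] + u*e[k]
    diff = a[None, :, :] - origins[:, None, :]  # (m, k, 2)
    denom = directions[:, 0, None] * e[None, :, 1] - directions[:, 1, None] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (diff[:, :, 0] * e[None, :, 1] - diff[:, :, 1] * e[None, :, 0]) / denom
        u = (diff[:, :, 0] * directions[:, 1, None] - diff[:, :, 1] * directions[:, 0, None]) / denom
    ok = (np.abs(denom) > 1e-12) & (t > t_min) & (u >= -1e-9) & (u <= 1.0 + 1e-9)
    t = np.where(ok, t, np.inf)
    return t.min(axis=1)


def _outward_normals(rs: ResampledContour, inner: Contour, outer: Contour) -> np.ndarray:
    """Unit normals pointing from the inner contour towards the outer one."""
    # rotate tangent by -90°: right-hand side of the direction of travel
    right = np.column_stack([rs.tangents[:, 1], -rs.tangents[:, 0]])
    if inner.closed:
        # counter-clockwise ring -> interior on the left -> outward is right
        return right if inner.signed_area > 0 else -right
    # open arc: orient each normal towards the nearest point of the outer arc
    outer_ls = LineString(outer.points)
    signs = np.empty(len(rs.points))
    for i, p in enumerate(rs.points):
        nearest = outer_ls.interpolate(outer_ls.project(Point(p)))
        v = np.array([nearest.x - p[0], nearest.y - p[1]])
        s = float(np.dot(right[i], v))
        signs[i] = 1.0 if s >= 0 else -1.0
    return right * signs[:, None]


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-sample thickness measurements along the inner boundary."""

    thickness_mm: np.ndarray  # (m,) valid samples only
    sample_points: np.ndarray  # (m, 2) µm, inner-boundary sample positions
    fallback: np.ndarray  # (m,) bool, nearest-point fallback used
    n_discarded: int  # open-arc samples whose normal missed the outer arc


def measure_thickness(layer: LayerDelineation, spacing: float = 14.0) -> ThicknessProfile:
    """Sample layer thickness at fixed arc-length intervals.

    Samples are anchored on the inner (luminal) boundary.  Each thickness is
    the length of the ray cast along the local outward normal to its first
    intersection with the outer boundary.  On closed delineations a ray that
    misses the outer ring (possible at high curvature) falls back to the
    nearest-point distance and is flagged; on open arcs such samples exit
    through the end caps and are discarded instead.
    """
    rs = resample_contour(layer.inner, spacing)
    normals = _outward_normals(rs, layer.inner, layer.outer)
    outer_poly = layer.outer.vertices_with_closure
    t_hit = _ray_polyline_first_hit(rs.points, normals, outer_poly)

    missed = ~np.isfinite(t_hit)
    if layer.closed:
        if np.any(missed):
            outer_ls = LineString(outer_poly)
            for i in np.flatnonzero(missed):
                t_hit[i] = outer_ls.distance(Point(rs.points[i]))
        fallback = missed
        keep = np.ones(len(t_hit), dtype=bool)
    else:
        keep = ~missed
        fallback = np.zeros(int(keep.sum()), dtype=bool)

    if int(keep.sum()) < 1:
        raise DegenerateContourError(
            f"no valid thickness samples for layer {layer.layer!r}"
        )
    thickness_mm = t_hit[keep] / UM_PER_MM
    return ThicknessProfile(
        thickness_mm=thickness_mm,
        sample_points=rs.points[keep],
        fallback=fallback[keep] if layer.closed else fallback,
        n_discarded=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# per-layer statistics
# ---------------------------------------------------------------------------


def _open_layer_area_um2(inner: Contour, outer: Contour) -> float:
    """Shoelace area of the region bounded by two open arcs plus end caps.

    The arcs are joined endpoint-to-endpoint by proximity so the polygon
    walks the inner path, crosses an end cap, walks the outer path in
    reverse, and closes through the other cap.
    """
    pin, pout = inner.points, outer.points
    same_orientation = np.linalg.norm(pin[-1] - pout[-1]) + np.linalg.norm(
        pin[0] - pout[0]
    ) <= np.linalg.norm(pin[-1] - pout[0]) + np.linalg.norm(pin[0] - pout[-1])
    ring = np.vstack([pin, pout[::-1] if same_orientation else pout])
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(
        float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    )


def _fit_circle_center(points: np.ndarray) -> np.ndarray:
    """Least-squares (Kåsa) circle-fit center of a point set."""
    x, y = points[:, 0], points[:, 1]
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.array([0.5 * sol[0], 0.5 * sol[1]])


def _coverage_fraction(layer: LayerDelineation) -> float:
    if layer.closed:
        return 1.0
    center = _fit_circle_center(layer.inner.points)
    rel = layer.inner.points - center
    angles = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    span = abs(angles[-1] - angles[0])
    return float(min(max(span / (2.0 * math.pi), 1e-9), 1.0))


def layer_statistics(layer: LayerDelineation, spacing: float = 14.0) -> LayerMeasurement:
    """Compute the per-layer measurement summary.

    Mean/SD are taken over the per-sample thicknesses (sample SD, ``ddof=1``);
    area is the polygon area between the two boundaries; lengths are the
    boundary arc lengths.  Everything is reported in mm-based units.
    """
    prof = measure_thickness(layer, spacing)
    th = prof.thickness_mm
    mean = float(th.mean())
    sd = float(th.std(ddof=1)) if len(th) > 1 else 0.0

    if layer.closed:
        area_um2 = Polygon(layer.outer.points).area - Polygon(layer.inner.points).area
    else:
        area_um2 = _open_layer_area_um2(layer.inner, layer.outer)

    return LayerMeasurement(
        layer=layer.layer,
        mean_thickness=mean,
        sd_thickness=sd,
        area=area_um2 / UM_PER_MM**2,
        inner_length=layer.inner.length / UM_PER_MM,
        outer_length=layer.outer.length / UM_PER_MM,
        n_samples=len(th),
        coverage_fraction=_coverage_fraction(layer),
        n_fallback=int(prof.fallback.sum()),
    )


def folding_ratio(submucosa: LayerDelineation) -> float:
    """Submucosal folding: inner boundary length / outer boundary length.

    The pleated luminal-side boundary is the numerator, so a more folded
    submucosa yields a larger ratio (≈ 1.1 in heavily pleated specimens,
    below 1 for a perfectly smooth annular layer).
    """
    return submucosa.inner.length / submucosa.outer.length


def measure_specimen(
    delineations: Iterable[LayerDelineation],
    spacing: float = 14.0,
    specimen_id: str = "",
    segment: str = "",
    patient_id: str | None = None,
) -> SpecimenMeasurement:
    """Measure every delineated layer of one specimen and derive the ratios.

    The layer set may be incomplete; the muscularis interna/externa ratio and
    the submucosal folding ratio are populated only when the layers they need
    are present.  The full wall is measured from its own innermost/outermost
    boundary pair, never by summing layer means.
    """
    delineations = list(delineations)
    seen: set[str] = set()
    for d in delineations:
        if d.layer in seen:
            raise ValueError(f"duplicate delineation for layer {d.layer!r}")
        seen.add(d.layer)

    layers = {d.layer: layer_statistics(d, spacing) for d in delineations}

    mi = layers.get("muscularis_interna")
    me = layers.get("muscularis_externa")
    mi_me = mi.mean_thickness / me.mean_thickness if mi and me else None

    sub = next((d for d in delineations if d.layer == "submucosa"), None)
    fold = folding_ratio(sub) if sub is not None else None

    return SpecimenMeasurement(
        specimen_id=specimen_id,
        segment=segment,
        layers=layers,
        mi_me_ratio=mi_me,
        folding_ratio=fold,
        patient_id=patient_id,
    )
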