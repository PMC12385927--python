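import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from hdmorph.geometry import (
    Contour,
    DegenerateContourError,
    LayerDelineation,
    folding_ratio,
    layer_statistics,
    measure_specimen,
    measure_thickness,
    resample_contour,
)

from .conftest import AGANGLIONIC_MEANS, circle, star_convex_contour


# ---------------------------------------------------------------------------
# contour validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "points, closed",
    [
        ([[0, 0], [1, 1]], False),  # too few points
        ([[0, 0], [0, 0], [1, 1]], False),  # consecutive duplicate
        ([[0, 0], [2, 2], [2, 0], [0, 2]], True),  # bow-tie self-intersection
        ([[0, 0], [1, np.nan], [2, 0]], False),  # non-finite
    ],
)
def test_invalid_contours_rejected(points, closed):
    with pytest.raises(ValueError):
        Contour(np.asarray(points, dtype=float), closed=closed)


def test_inner_must_lie_inside_outer():
    with pytest.raises(ValueError, match="inside"):
        LayerDelineation("mucosa", circle(1500.0), circle(1000.0))


def test_mixed_open_closed_pair_rejected():
    with pytest.raises(ValueError, match="closed or both open"):
        LayerDelineation("mucosa", circle(1000.0), circle(1500.0, closed=False, span=(0, math.pi)))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def test_resample_circle_uniform_count():
    # perimeter 2π·1000 µm at 14 µm intervals -> floor(6283.2/14) = 448 samples
    rs = resample_contour(circle(1000.0, n=8192), 14.0)
    assert len(rs) == 448
    gaps = np.diff(rs.arc_positions)
    assert np.allclose(gaps, gaps[0])
    assert np.allclose(np.hypot(*rs.tangents.T), 1.0)


def test_resample_open_segment_endpoints():
    pts = np.column_stack([np.linspace(0.0, 140.0, 21), np.zeros(21)])
    rs = resample_contour(Contour(pts, closed=False), 14.0)
    assert len(rs) == 11
    assert np.allclose(rs.arc_positions, np.arange(11) * 14.0)
    assert np.allclose(rs.points[-1], [140.0, 0.0])


def test_resample_count_matches_bruteforce_arclength():
    """Sample count agrees with a 0.1 µm cumulative-length walk, ±1."""
    contour = star_convex_contour(np.random.default_rng(11), base_radius_um=800.0)
    # independent oracle: pure-python segment walk at 0.1 µm resolution
    verts = np.vstack([contour.points, contour.points[:1]])
    total = 0.0
    marks = 0
    next_mark = 14.0
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        seg = math.hypot(x1 - x0, y1 - y0)
        steps = max(int(seg / 0.1), 1)
        for _ in range(steps):
            total += seg / steps
            while total >= next_mark:
                marks += 1
                next_mark += 14.0
    rs = resample_contour(contour, 14.0)
    assert abs(len(rs) - (marks + 1)) <= 1


def test_resample_shorter_than_spacing_errors():
    tiny = Contour(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]), closed=False)
    with pytest.raises(DegenerateContourError):
        resample_contour(tiny, 14.0)


# ---------------------------------------------------------------------------
# thickness measurement
# ---------------------------------------------------------------------------


def test_annulus_thickness_constant(annulus):
    prof = measure_thickness(annulus, 14.0)
    assert prof.thickness_mm.mean() == pytest.approx(0.5, abs=1e-4)
    assert prof.thickness_mm.std() < 1e-6
    assert not prof.fallback.any()


def test_half_annulus_open_arc_mean(annulus):
    half = LayerDelineation(
        "submucosa",
        circle(1000.0, n=2048, closed=False, span=(0, math.pi)),
        circle(1500.0, n=2048, closed=False, span=(0, math.pi)),
    )
    prof = measure_thickness(half, 14.0)
    assert prof.thickness_mm.mean() == pytest.approx(0.5, abs=1e-3)


def test_ellipse_thickness_matches_shapely_ray_oracle():
    """Per-sample ray thickness agrees with an independent dense-polyline oracle."""
    t = np.linspace(0, 2 * math.pi, 4096, endpoint=False)
    inner = Contour(np.column_stack([1200 * np.cos(t), 800 * np.sin(t)]), closed=True)
    outer = Contour(np.column_stack([1500 * np.cos(t), 1100 * np.sin(t)]), closed=True)
    layer = LayerDelineation("mucosa", inner, outer)

    prof = measure_thickness(layer, 100.0)
    # oracle: shapely intersection of each normal ray with a 1e5-point outer polyline
    td = np.linspace(0, 2 * math.pi, 100_000)
    dense = LineString(np.column_stack([1500 * np.cos(td), 1100 * np.sin(td)]))
    rs = resample_contour(inner, 100.0)
    from hdmorph.geometry import _outward_normals

    normals = _outward_normals(rs, inner, outer)
    for p, nvec, measured in zip(rs.points, normals, prof.thickness_mm):
        ray = LineString([p, p + 5000.0 * nvec])
        hit = ray.intersection(dense)
        dist = Point(p).distance(hit) / 1000.0  # nearest intersection, mm
        assert measured == pytest.approx(dist, rel=1e-3)


def test_high_curvature_misses_fall_back_flagged():
    # outer ring much larger and offset: some inner normals still hit, and on
    # an open arc pointing away they are discarded instead
    arc_in = circle(1000.0, n=512, closed=False, span=(0, math.pi / 2))
    arc_out = circle(1400.0, n=512, closed=False, span=(0, math.pi / 2))
    prof = measure_thickness(LayerDelineation("mucosa", arc_in, arc_out), 14.0)
    assert prof.n_discarded >= 0  # discarding never produces fallback samples
    assert len(prof.thickness_mm) >= 1


# ---------------------------------------------------------------------------
# layer statistics
# ---------------------------------------------------------------------------


def test_annulus_closed_forms(annulus):
    m = layer_statistics(annulus, 14.0)
    assert m.mean_thickness == pytest.approx(0.5, abs=1e-4)
    assert m.sd_thickness < 1e-6
    assert m.area == pytest.approx(math.pi * (1.5**2 - 1.0**2), rel=1e-4)
    assert m.inner_length == pytest.approx(2 * math.pi * 1.0, rel=1e-4)
    assert m.outer_length == pytest.approx(2 * math.pi * 1.5, rel=1e-4)
    assert m.coverage_fraction == 1.0


def test_rigid_invariance():
    rng = np.random.default_rng(3)
    inner = star_convex_contour(rng, 900.0, amplitude=0.10)
    outer = Contour(inner.points * 1.45, closed=True)
    base = layer_statistics(LayerDelineation("submucosa", inner, outer), 14.0)
    moved = layer_statistics(
        LayerDelineation(
            "submucosa",
            inner.transformed(rotation_rad=0.73, translation=(1234.5, -987.6)),
            outer.transformed(rotation_rad=0.73, translation=(1234.5, -987.6)),
        ),
        14.0,
    )
    for fld in ("mean_thickness", "sd_thickness", "area", "inner_length", "outer_length"):
        assert getattr(moved, fld) == pytest.approx(getattr(base, fld), rel=1e-9)
    assert moved.n_samples == base.n_samples


@pytest.mark.parametrize("span", [(0, math.pi / 3), (1.0, 2.5), (0, 1.5 * math.pi)])
def test_partial_arc_mean_matches_full_circumference(span):
    """Any angular sub-arc of a rotationally symmetric wall measures the same mean."""
    sub = LayerDelineation(
        "mucosa",
        circle(1000.0, n=2048, closed=False, span=span),
        circle(1500.0, n=2048, closed=False, span=span),
    )
    m = layer_statistics(sub, 14.0)
    assert m.mean_thickness == pytest.approx(0.5, abs=1e-3)
    expected_cov = (span[1] - span[0]) / (2 * math.pi)
    assert m.coverage_fraction == pytest.approx(expected_cov, abs=0.02)


def test_spacing_convergence_on_smooth_contour():
    rng = np.random.default_rng(8)
    inner = star_convex_contour(rng, 1000.0, amplitude=0.08, n=4096)
    outer = Contour(inner.points * 1.4, closed=True)
    layer = LayerDelineation("submucosa", inner, outer)
    m14 = layer_statistics(layer, 14.0).mean_thickness
    m7 = layer_statistics(layer, 7.0).mean_thickness
    assert abs(m14 - m7) / m7 < 1e-3


def test_star_convex_area_matches_pixel_counting_oracle():
    from matplotlib.path import Path as MplPath

    rng = np.random.default_rng(21)
    inner = star_convex_contour(rng, 250.0, amplitude=0.12, n=1024)
    outer = Contour(inner.points * 1.6, closed=True)
    m = layer_statistics(LayerDelineation("submucosa", inner, outer), 14.0)

    # oracle: count 1 µm pixels inside outer but not inside inner
    lo = outer.points.min(axis=0) - 2
    hi = outer.points.max(axis=0) + 2
    xs = np.arange(lo[0], hi[0], 1.0)
    ys = np.arange(lo[1], hi[1], 1.0)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_outer = MplPath(outer.points).contains_points(pts)
    in_inner = MplPath(inner.points).contains_points(pts)
    pixel_area_mm2 = (in_outer & ~in_inner).sum() / 1e6
    assert m.area == pytest.approx(pixel_area_mm2, rel=5e-3)


def test_open_layer_area_between_half_annuli():
    half = LayerDelineation(
        "submucosa",
        circle(1000.0, n=2048, closed=False, span=(0, math.pi)),
        circle(1500.0, n=2048, closed=False, span=(0, math.pi)),
    )
    m = layer_statistics(half, 14.0)
    assert m.area == pytest.approx(0.5 * math.pi * (1.5**2 - 1.0**2), rel=1e-3)


# ---------------------------------------------------------------------------
# folding ratio
# ---------------------------------------------------------------------------


def test_folding_ratio_concentric(annulus):
    assert folding_ratio(annulus) == pytest.approx(2.0 / 3.0, rel=1e-6)


def _folded_inner(amplitude_rel: float, k: int = 40, r: float = 1000.0) -> Contour:
    theta = np.linspace(0, 2 * math.pi, 8192, endpoint=False)
    rr = r * (1.0 + amplitude_rel * np.sin(k * theta))
    return Contour(np.column_stack([rr * np.cos(theta), rr * np.sin(theta)]), closed=True)


def test_folded_boundary_exceeds_unfolded_ratio():
    outer = circle(1500.0)
    folded = LayerDelineation("submucosa", _folded_inner(0.05), outer)
    ratio = folding_ratio(folded)
    # quadrature oracle for the folded arc length
    theta = np.linspace(0, 2 * math.pi, 400_001)
    rr = 1000.0 * (1 + 0.05 * np.sin(40 * theta))
    drr = 1000.0 * 0.05 * 40 * np.cos(40 * theta)
    oracle_len = np.trapezoid(np.sqrt(rr**2 + drr**2), theta)
    assert ratio > 2.0 / 3.0
    assert ratio == pytest.approx(oracle_len / (2 * math.pi * 1500.0), rel=1e-4)


def test_folding_ratio_strictly_increases_with_amplitude():
    outer = circle(1500.0)
    ratios = [
        folding_ratio(LayerDelineation("submucosa", _folded_inner(a), outer))
        for a in (0.0, 0.01, 0.02, 0.04, 0.06)
    ]
    assert all(b > a for a, b in zip(ratios, ratios[1:]))


# ---------------------------------------------------------------------------
# whole-specimen measurement
# ---------------------------------------------------------------------------


def _nested_specimen(radii_mm, labels):
    rings = [circle(r * 1000.0) for r in radii_mm]
    delins = [
        LayerDelineation(lab, rings[i], rings[i + 1]) for i, lab in enumerate(labels)
    ]
    delins.append(LayerDelineation("full_wall", rings[0], rings[-1]))
    return delins


def test_nesting_additivity_on_shared_rays():
    """Concentric layers: full-wall thickness equals the sum of layer thicknesses."""
    labels = ["mucosa", "submucosa", "muscularis_interna", "myenteric", "muscularis_externa"]
    spec = measure_specimen(
        _nested_specimen([1.0, 1.5, 1.6, 2.1, 2.15, 2.5], labels),
        specimen_id="S", segment="ganglionic",
    )
    layer_sum = sum(spec.layers[lab].mean_thickness for lab in labels)
    assert spec.layers["full_wall"].mean_thickness == pytest.approx(1.5, abs=1e-4)
    assert spec.layers["full_wall"].mean_thickness == pytest.approx(layer_sum, abs=2e-4)


def test_mi_me_ratio_from_mean_thicknesses():
    # muscle coats of 0.666 and 0.334 mm -> ratio ≈ 1.994
    delins = [
        LayerDelineation("muscularis_interna", circle(2000.0), circle(2666.0)),
        LayerDelineation("muscularis_externa", circle(2666.0), circle(3000.0)),
    ]
    spec = measure_specimen(delins, specimen_id="S", segment="ganglionic")
    assert spec.mi_me_ratio == pytest.approx(0.666 / 0.334, rel=1e-3)
    assert spec.folding_ratio is None  # no submucosa delineated


def test_missing_layer_leaves_feature_missing():
    labels = ["mucosa", "submucosa", "muscularis_interna", "muscularis_externa"]
    spec = measure_specimen(
        _nested_specimen([1.0, 1.5, 1.6, 2.1, 2.5], labels),
        specimen_id="S", segment="aganglionic",
    )
    assert "myenteric" not in spec.layers
    assert spec.to_features()["myenteric"] is None
    assert spec.mi_me_ratio is not None and spec.folding_ratio is not None


def test_duplicate_layer_rejected(annulus):
    with pytest.raises(ValueError, match="duplicate"):
        measure_specimen([annulus, annulus])
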