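import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from lvquant import (ValidationError, assign_aha_segments, chords_for_stack,
                     compute_centerline, compute_chords, slice_levels_by_thirds,
                     thinned_wall_contours, wall_thickening)
from lvquant.regional_wall import ChordSet
from lvquant._geom import circle_polygon, polygon_vertices

from conftest import ellipse_polygon


# --- centerline ---------------------------------------------------------

def test_centerline_of_concentric_circles_is_mid_circle():
    epi = circle_polygon((5, 5), 3.0, 720)
    endo = circle_polygon((5, 5), 2.0, 720)
    cl = compute_centerline(epi, endo, 100)
    radii = np.hypot(cl[:, 0] - 5, cl[:, 1] - 5)
    assert np.allclose(radii, 2.5, atol=1e-4)


def test_centerline_of_similar_ellipses_matches_mean_ellipse():
    a, b, s = 3.0, 2.85, 2.0 / 3.0
    epi = ellipse_polygon((5, 5), a, b)
    endo = ellipse_polygon((5, 5), s * a, s * b)
    cl = compute_centerline(epi, endo, 100)
    # independent dense brute-force oracle: equidistance from both boundaries
    th = np.arange(20000) * 2 * np.pi / 20000
    ep = np.column_stack([5 + a * np.cos(th), 5 + b * np.sin(th)])
    en = np.column_stack([5 + s * a * np.cos(th), 5 + s * b * np.sin(th)])
    for p in cl:
        d_epi = np.sqrt(((ep - p) ** 2).sum(1)).min()
        d_endo = np.sqrt(((en - p) ** 2).sum(1)).min()
        assert abs(d_epi - d_endo) < 1e-3
    # and the point-wise mean ellipse is an equally good description here
    am, bm = (a + s * a) / 2, (b + s * b) / 2
    me = np.column_stack([5 + am * np.cos(th), 5 + bm * np.sin(th)])
    dev = max(np.sqrt(((me - p) ** 2).sum(1)).min() for p in cl)
    assert dev < 1e-3


def test_centerline_rejects_touching_contours():
    epi = circle_polygon((5, 5), 3.0, 64)
    endo = circle_polygon((5.9, 5), 2.1, 64)  # touches/escapes the epicardium
    with pytest.raises(ValidationError):
        compute_centerline(epi, endo, 50)


# --- chords -------------------------------------------------------------

def test_annulus_chords_exactly_wall_thickness(annulus):
    epi, endo = annulus
    cl = compute_centerline(epi, endo, 100)
    ch = compute_chords(cl, epi, endo)
    np.testing.assert_allclose(ch.wts, 1.0, atol=1e-9)
    assert ch.n_chords == 100
    assert np.all(np.diff(np.unwrap(ch.angles)) > 0)


def test_small_n_annulus_chords(annulus):
    epi, endo = annulus
    cl = compute_centerline(epi, endo, 4)
    ch = compute_chords(cl, epi, endo)
    assert ch.n_chords == 4
    np.testing.assert_allclose(np.diff(np.unwrap(ch.angles)), np.pi / 2, atol=1e-9)
    np.testing.assert_allclose(ch.wts, ch.wts[0], atol=1e-9)


def test_chord_endpoints_lie_on_contours(annulus):
    from shapely.geometry import Point

    epi, endo = annulus
    cl = compute_centerline(epi, endo, 100)
    ch = compute_chords(cl, epi, endo)
    for pt in ch.endo_points:
        assert endo.exterior.distance(Point(pt)) < 1e-6
    for pt in ch.epi_points:
        assert epi.exterior.distance(Point(pt)) < 1e-6


def test_eccentric_annulus_matches_shapely_intersection_oracle():
    epi = circle_polygon((5, 5), 3.0, 512)
    endo = circle_polygon((5.3, 5), 2.0, 512)
    cl = compute_centerline(epi, endo, 100)
    ch = compute_chords(cl, epi, endo)
    c = epi.centroid
    for k in range(100):
        p = cl[k]
        tangent = cl[(k + 1) % 100] - cl[(k - 1) % 100]
        n = np.array([tangent[1], -tangent[0]])
        n = n / np.linalg.norm(n)
        if np.dot(n, p - np.array([c.x, c.y])) < 0:
            n = -n
        probe = LineString([p - 10 * n, p + 10 * n])

        def nearest(poly, side):
            inter = probe.intersection(poly.exterior)
            pts = ([inter] if inter.geom_type == "Point"
                   else list(getattr(inter, "geoms", [])))
            ts = [np.dot(np.array([q.x, q.y]) - p, n) for q in pts]
            ts = [t for t in ts if (t >= 0) == (side == "out")]
            return min(ts, key=abs)

        wts_oracle = nearest(epi, "out") - nearest(endo, "in")
        assert ch.wts[k] == pytest.approx(wts_oracle, abs=1e-4)


# --- wall thickening ----------------------------------------------------

@pytest.mark.parametrize("ed, es, expected", [
    (1.0, 1.0, 0.0),
    (0.5, 1.0, 0.5),     # reported as 50%
    (1.0, 0.8, -0.25),   # systolic thinning yields negative WT
])
def test_wall_thickening_closed_form(ed, es, expected):
    assert wall_thickening(ed, es) == pytest.approx(expected)


def test_wall_thickening_undefined_when_es_zero():
    assert np.isnan(wall_thickening(1.0, 0.0))
    out = wall_thickening([1.0, 0.5], [0.0, 1.0])
    assert np.isnan(out[0]) and out[1] == pytest.approx(0.5)


# --- AHA segments -------------------------------------------------------

def annulus_chordset(n_slices=9, wts_value=1.0, phase_values=None):
    """Chord set over an annulus stack; optionally different ED/ES walls."""
    import dataclasses

    per_phase = {}
    for phase in ("ED", "ES"):
        w = (phase_values or {"ED": wts_value, "ES": wts_value})[phase]
        epi = circle_polygon((5, 5), 2.0 + w, 360)
        endo = circle_polygon((5, 5), 2.0, 360)
        cl = compute_centerline(epi, endo, 100)
        per_phase[phase] = compute_chords(cl, epi, endo, 0, phase)
    chords = {(i, phase): dataclasses.replace(per_phase[phase], slice_index=i)
              for i in range(n_slices) for phase in ("ED", "ES")}
    return ChordSet(chords=chords, n_chords=100)


def test_three_mid_slices_give_about_fifty_chords_per_segment():
    # 300 mid-level chords over six 60-degree segments: 50 on average, with
    # each segment within the 45-50-chords-per-segment range the equal-angle
    # layout produces (100 chords do not divide evenly into 6 bins per slice)
    cs = annulus_chordset(n_slices=3)
    seg = assign_aha_segments(cs, slice_levels={0: "mid", 1: "mid", 2: "mid"})
    mid = seg[seg["level"] == "mid"]
    assert mid["n_chords"].sum() == 300
    assert mid["n_chords"].between(45, 54).all()
    assert seg[seg["level"] != "mid"]["n_chords"].sum() == 0
    assert seg[seg["level"] != "mid"]["mean_wts_es_mm"].isna().all()


def test_constant_wall_gives_constant_segment_means():
    cs = annulus_chordset(n_slices=9)
    seg = assign_aha_segments(cs)
    # 360-gon boundary: inscribed-polygon deficit ~2.5e-5 mm
    np.testing.assert_allclose(seg["mean_wts_es_mm"], 1.0, atol=1e-4)
    np.testing.assert_allclose(seg["mean_wt"], 0.0, atol=1e-9)
    # partition: every chord lands in exactly one segment
    assert seg["n_chords"].sum() == 9 * 100


def test_reference_rotation_permutes_basal_and_mid_labels():
    rng = np.random.default_rng(0)
    # irregular wall: make segment statistics distinguishable
    epi = Polygon(polygon_vertices(circle_polygon((5, 5), 3.0, 360))
                  + 0.05 * rng.standard_normal((360, 2)))
    endo = circle_polygon((5, 5), 1.8, 360)
    chords = {}
    for i in range(6):
        for phase in ("ED", "ES"):
            cl = compute_centerline(epi, endo, 100)
            chords[(i, phase)] = compute_chords(cl, epi, endo, i, phase)
    cs = ChordSet(chords=chords, n_chords=100)
    levels = {i: ("basal" if i >= 3 else "mid") for i in range(6)}
    seg0 = assign_aha_segments(cs, slice_levels=levels, reference_angle=0.0)
    seg1 = assign_aha_segments(cs, slice_levels=levels,
                               reference_angle=np.pi / 3)
    for level in ("basal", "mid"):
        a = seg0[seg0["level"] == level]["mean_wts_es_mm"].to_numpy()
        b = seg1[seg1["level"] == level]["mean_wts_es_mm"].to_numpy()
        np.testing.assert_allclose(np.roll(a, -1), b, atol=1e-9)


def test_negative_wt_propagates_to_segment_means():
    cs = annulus_chordset(n_slices=3, phase_values={"ED": 1.0, "ES": 0.8})
    seg = assign_aha_segments(cs, slice_levels={0: "mid", 1: "mid", 2: "mid"})
    mid = seg[seg["level"] == "mid"]
    np.testing.assert_allclose(mid["mean_wt"], -0.25, atol=1e-6)


def test_slice_level_thirds_assignment():
    assert slice_levels_by_thirds(range(9)) == {
        0: "apical", 1: "apical", 2: "apical", 3: "mid", 4: "mid", 5: "mid",
        6: "basal", 7: "basal", 8: "basal"}
    lv10 = slice_levels_by_thirds(range(10))
    assert sum(v == "basal" for v in lv10.values()) == 4
    lv11 = slice_levels_by_thirds(range(11))
    assert sum(v == "basal" for v in lv11.values()) == 4
    assert sum(v == "mid" for v in lv11.values()) == 4


def test_missing_slice_level_is_an_error():
    cs = annulus_chordset(n_slices=2)
    with pytest.raises(ValidationError, match="without"):
        assign_aha_segments(cs, slice_levels={0: "mid"})


def test_thinned_wedge_recovered_in_covering_segments():
    """A 0.5-mm thinned wedge reads ~0.5 mm in its AHA segment, remote ~1.0."""
    # 60-degree wedge aligned with one mid segment (anteroseptal, bin 1)
    stack = thinned_wall_contours(wedge_start=np.pi / 3, wedge_extent=np.pi / 3,
                                  n_slices=3)
    cs = chords_for_stack(stack)
    seg = assign_aha_segments(cs, slice_levels={0: "mid", 1: "mid", 2: "mid"})
    mid = seg[seg["level"] == "mid"].set_index("name")
    assert mid.loc["anteroseptal", "mean_wts_es_mm"] == pytest.approx(0.5, abs=0.05)
    for name in ("inferior", "inferolateral", "anterolateral"):
        assert mid.loc[name, "mean_wts_es_mm"] == pytest.approx(1.0, abs=0.05)


def test_rigid_rotation_equivariance():
    stack = thinned_wall_contours(wedge_start=0.3, wedge_extent=np.pi / 3,
                                  n_slices=3)
    rot = 0.7

    def rotate(poly):
        v = polygon_vertices(poly) - 5.0
        c, s = np.cos(rot), np.sin(rot)
        rot_matrix = np.array([[c, -s], [s, c]])
        return Polygon(v @ rot_matrix.T + 5.0)

    from lvquant import ContourStack, SliceContours
    rstack = ContourStack(slice_thickness=1.0, contours={
        k: SliceContours(epi=rotate(v.epi), endo=rotate(v.endo))
        for k, v in stack.contours.items()})
    levels = {0: "mid", 1: "mid", 2: "mid"}
    seg = assign_aha_segments(chords_for_stack(stack, reference_angle=0.0),
                              slice_levels=levels, reference_angle=0.0)
    rseg = assign_aha_segments(chords_for_stack(rstack, reference_angle=rot),
                               slice_levels=levels, reference_angle=rot)
    np.testing.assert_allclose(rseg["mean_wts_es_mm"], seg["mean_wts_es_mm"],
                               atol=1e-3)
    assert list(rseg["n_chords"]) == list(seg["n_chords"])
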