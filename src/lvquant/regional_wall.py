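"""Centerline-based regional wall analysis.

For each short-axis slice, a centerline is constructed midway between the
endocardial and epicardial contours; 100 chords are cast perpendicular to
the centerline, their lengths being the local wall thickness (WTS).  Wall
thickening is WT = (WTS_ES - WTS_ED) / WTS_ES, so akinetic or thinning wall
yields negative WT.  Chords are aggregated into the 16-segment AHA layout
(6 basal, 6 mid, 4 apical; the apical cap, segment 17, is excluded).

Conventions: slices are indexed 0 = apex ascending to base; angles are
counterclockwise from +x; ``reference_angle`` marks the anterior segment
boundary and bins proceed counterclockwise anterior -> anteroseptal ->
inferoseptal -> inferior -> inferolateral -> anterolateral (and anterior ->
septal -> inferior -> lateral for the four apical segments).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from ._geom import TWO_PI, line_polygon_intersections, ray_boundary_distance, wrap_angle
from .io_contours import ContourStack, ValidationError

DEFAULT_N_CHORDS = 100

BASAL_MID_NAMES = ("anterior", "anteroseptal", "inferoseptal",
                   "inferior", "inferolateral", "anterolateral")
APICAL_NAMES = ("anterior", "septal", "inferior", "lateral")
LEVELS = ("basal", "mid", "apical")

# guaranteed equidistance is < 1e-3 mm; iterate well past it so downstream
# chord geometry is not limited by centerline placement
EQUIDISTANCE_TOL = 1e-9  # mm


def compute_centerline(epi: Polygon, endo: Polygon, n_points: int = DEFAULT_N_CHORDS,
                       reference_angle: float = 0.0) -> np.ndarray:
    """Closed centerline curve equidistant from both contours.

    Points are found on equal-angle rays from the epicardial centroid: the
    initial guess is the ray midpoint between the two boundary crossings,
    refined by bisection in radius until the point is equidistant from the
    endocardial and epicardial boundaries to within 1e-3 mm.
    Returns an (n_points, 2) array ordered by increasing ray angle.
    """
    if not (epi.contains(endo) and endo.exterior.distance(epi.exterior) > 0):
        raise ValidationError("endocardial contour must lie strictly inside the "
                              "epicardial contour")
    c = epi.centroid
    center = np.array([c.x, c.y])
    angles = reference_angle + np.arange(n_points) * TWO_PI / n_points
    pts = np.empty((n_points, 2))
    endo_b = endo.exterior
    epi_b = epi.exterior
    for k, th in enumerate(angles):
        u = np.array([np.cos(th), np.sin(th)])
        r_endo = ray_boundary_distance(endo, (c.x, c.y), th)
        r_epi = ray_boundary_distance(epi, (c.x, c.y), th)
        lo, hi = r_endo, r_epi

        def imbalance(r: float) -> float:
            from shapely.geometry import Point
            p = Point(center + r * u)
            return endo_b.distance(p) - epi_b.distance(p)

        # imbalance < 0 near the endocardium, > 0 near the epicardium
        r = 0.5 * (lo + hi)
        for _ in range(60):
            f = imbalance(r)
            if abs(f) < EQUIDISTANCE_TOL:
                break
            if f < 0:
                lo = r
            else:
                hi = r
            r = 0.5 * (lo + hi)
        pts[k] = center + r * u
    return pts


@dataclass
class SliceChords:
    """100 centerline-perpendicular wall-thickness chords for one slice/phase."""

    slice_index: int
    phase: str
    angles: np.ndarray        # centerline ray angles, strictly increasing in [0, 2pi)
    endo_points: np.ndarray   # (n, 2) mm
    epi_points: np.ndarray    # (n, 2) mm
    wts: np.ndarray           # chord lengths, mm

    @property
    def n_chords(self) -> int:
        return len(self.wts)


def compute_chords(centerline: np.ndarray, epi: Polygon, endo: Polygon,
                   slice_index: int = 0, phase: str = "ED") -> SliceChords:
    """Cast the local centerline normal at every centerline point; chord
    endpoints are the nearest crossings with the endocardial (inward) and
    epicardial (outward) contours, and WTS is their distance."""
    n = len(centerline)
    c = epi.centroid
    center = np.array([c.x, c.y])
    endo_pts = np.empty((n, 2))
    epi_pts = np.empty((n, 2))
    wts = np.empty(n)
    for k in range(n):
        p = centerline[k]
        tangent = centerline[(k + 1) % n] - centerline[(k - 1) % n]
        normal = np.array([tangent[1], -tangent[0]])
        norm = np.linalg.norm(normal)
        if norm == 0:
            raise ValidationError(f"degenerate centerline at point {k}")
        normal /= norm
        if np.dot(normal, p - center) < 0:
            normal = -normal  # make the normal point outward
        t_endo = line_polygon_intersections(p, normal, endo)
        t_epi = line_polygon_intersections(p, normal, epi)
        t_in = t_endo[t_endo <= 0.0]
        t_out = t_epi[t_epi >= 0.0]
        if t_in.size == 0 or t_out.size == 0:
            raise ValidationError(
                f"centerline normal at point {k} fails to intersect a contour "
                "(gross contour defect)")
        ti = t_in[-1]   # nearest inward crossing
        to = t_out[0]   # nearest outward crossing
        endo_pts[k] = p + ti * normal
        epi_pts[k] = p + to * normal
        wts[k] = to - ti
    angles = wrap_angle(np.arctan2(centerline[:, 1] - c.y, centerline[:, 0] - c.x))
    return SliceChords(slice_index=slice_index, phase=phase, angles=angles,
                       endo_points=endo_pts, epi_points=epi_pts, wts=wts)


@dataclass
class ChordSet:
    """Chords for every slice and phase of a contour stack, paired by
    angular index across phases."""

    chords: dict[tuple[int, str], SliceChords]
    n_chords: int
    reference_angle: float = 0.0

    def get(self, slice_index: int, phase: str) -> SliceChords:
        try:
            return self.chords[(slice_index, phase)]
        except KeyError:
            raise ValidationError(f"no chords for slice {slice_index} phase {phase}") from None

    def slice_indices(self, phase: str) -> list[int]:
        return sorted(i for i, p in self.chords if p == phase)


def chords_for_stack(contours: ContourStack, n_chords: int = DEFAULT_N_CHORDS,
                     reference_angle: float = 0.0) -> ChordSet:
    """Centerline chords for every contoured slice and phase.

    Using the same equal-angle centerline construction in both phases pairs
    ED and ES chords by angular index, which is what makes per-chord wall
    thickening well defined.
    """
    out = {}
    for (idx, phase) in sorted(contours.contours):
        pair = contours.get(idx, phase)
        cl = compute_centerline(pair.epi, pair.endo, n_chords, reference_angle)
        out[(idx, phase)] = compute_chords(cl, pair.epi, pair.endo, idx, phase)
    return ChordSet(chords=out, n_chords=n_chords, reference_angle=reference_angle)


def wall_thickening(wts_ed, wts_es):
    """WT = (WTS_ES - WTS_ED) / WTS_ES, as a fraction.

    Negative values are legitimate (systolic thinning).  Where WTS_ES is
    zero the statistic is undefined and NaN is returned; segment means skip
    such chords.
    """
    wts_ed = np.asarray(wts_ed, dtype=float)
    wts_es = np.asarray(wts_es, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        wt = np.where(wts_es > 0, (wts_es - wts_ed) / wts_es, np.nan)
    return wt if wt.ndim else float(wt)


def slice_levels_by_thirds(slice_indices: list[int]) -> dict[int, str]:
    """Split contoured slices (apex -> base) into apical/mid/basal thirds by
    index, assigning remainder slices basal-first."""
    idx = sorted(slice_indices)
    n = len(idx)
    base = n // 3
    rem = n % 3
    n_basal = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem >= 2 else 0)
    n_apical = base
    levels = {}
    for j, i in enumerate(idx):
        if j < n_apical:
            levels[i] = "apical"
        elif j < n_apical + n_mid:
            levels[i] = "mid"
        else:
            levels[i] = "basal"
    return levels


def _segment_table() -> pd.DataFrame:
    rows = []
    seg = 1
    for level, names in (("basal", BASAL_MID_NAMES), ("mid", BASAL_MID_NAMES),
                         ("apical", APICAL_NAMES)):
        for k, name in enumerate(names):
            rows.append({"segment": seg, "level": level, "name": name, "bin": k})
            seg += 1
    return pd.DataFrame(rows).set_index("segment")


def assign_aha_segments(chord_set: ChordSet,
                        slice_levels: dict[int, str] | None = None,
                        reference_angle: float = 0.0) -> pd.DataFrame:
    """Bin chords into the 16-segment AHA layout and aggregate wall
    statistics.

    Returns a DataFrame indexed by segment id 1-16 with columns
    ``level``, ``name``, ``n_chords``, ``mean_wts_es_mm``, ``mean_wt``.
    Basal and mid levels use six 60-degree bins, the apical level four
    90-degree bins; bins are half-open [start, end) starting at
    ``reference_angle``.  Mean WT is the mean of per-chord WT values
    (chords with undefined WT excluded); empty segments report NaN.
    """
    es_slices = chord_set.slice_indices("ES")
    if not es_slices:
        raise ValidationError("chord set has no ES chords")
    if slice_levels is None:
        slice_levels = slice_levels_by_thirds(es_slices)
    missing = [i for i in es_slices if i not in slice_levels]
    if missing:
        raise ValidationError(f"slices without a basal/mid/apical label: {missing}")
    bad = {lv for lv in slice_levels.values() if lv not in LEVELS}
    if bad:
        raise ValidationError(f"unknown slice levels {sorted(bad)}")

    table = _segment_table()
    acc: dict[int, dict[str, list]] = {s: {"wts_es": [], "wt": []} for s in table.index}
    for i in es_slices:
        level = slice_levels[i]
        es = chord_set.get(i, "ES")
        ed = chord_set.get(i, "ED")
        n_bins = 4 if level == "apical" else 6
        width = TWO_PI / n_bins
        bins = (wrap_angle(es.angles - reference_angle) // width).astype(int) % n_bins
        wt = wall_thickening(ed.wts, es.wts)
        seg_ids = table[(table["level"] == level)].reset_index().set_index("bin")["segment"]
        for k in range(n_bins):
            sel = bins == k
            seg = int(seg_ids[k])
            acc[seg]["wts_es"].extend(es.wts[sel])
            acc[seg]["wt"].extend(np.atleast_1d(wt)[sel])

    out = table.drop(columns="bin").copy()
    out["n_chords"] = [len(acc[s]["wts_es"]) for s in out.index]
    out["mean_wts_es_mm"] = [float(np.mean(a)) if (a := acc[s]["wts_es"]) else np.nan
                             for s in out.index]
    out["mean_wt"] = [float(np.nanmean(a)) if len(a := np.asarray(acc[s]["wt"], dtype=float))
                      and not np.all(np.isnan(a)) else np.nan
                      for s in out.index]
    return out


def chords_to_frame(chord_set: ChordSet) -> pd.DataFrame:
    """Long-format chord table (one row per chord) for CSV export."""
    rows = []
    for (idx, phase), sc in sorted(chord_set.chords.items()):
        for k in range(sc.n_chords):
            rows.append({"slice": idx, "phase": phase, "chord": k,
                         "angle_rad": sc.angles[k], "wts_mm": sc.wts[k]})
    return pd.DataFrame(rows)
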