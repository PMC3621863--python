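"""Synthetic left-ventricular phantom with analytic ground truth.

The LV is modeled as a thick-walled half-ellipsoid of revolution (apex at
slice 0, base at the top of the stack) or, in the cylinder limit, as a
straight annular tube.  End-diastole and end-systole are generated as two
static geometries; an infarct wedge of configurable angular extent and
transmural depth is hyperenhanced on the LGE stack against a remote
myocardium of stated mean/SD.  All truth values (volumes, EF, infarct
fractions, wall thickness) come from closed-form geometry, never from the
voxel grid, so every downstream quantification stage can be checked against
an independent analytic oracle.

Default parameters emulate a healthy-to-infarcted mouse heart at 9.4 T:
cavity radius ~2 mm, wall ~0.8 mm, 9 contiguous 1-mm short-axis slices,
0.15 mm in-plane pixels, heart rate 500 beats/min, and a transmural
anterolateral wedge spanning 90 degrees.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from shapely.geometry import Polygon

from ._geom import (TWO_PI, angle_in_arc, annular_wedge_polygon, arcs_overlap,
                    circle_polygon, wrap_angle)
from .io_contours import ContourStack, ImageStack, SliceContours, ValidationError

SEPTAL_ROI_EXTENT = np.deg2rad(30.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and acquisition parameters of the phantom.

    Lengths are mm, intensities arbitrary units, angles radians
    (counterclockwise from +x in the short-axis plane).
    """

    endo_radius_ed: float = 2.0
    endo_radius_es: float = 1.45
    wall_thickness_ed: float = 0.8
    wall_thickness_es: float = 1.1
    lv_length: float = 9.0
    n_slices: int = 9
    slice_thickness: float = 1.0
    pixel_spacing: float = 0.15
    infarct_angle_start: float = np.pi / 4
    infarct_angle_extent: float = np.pi / 2
    infarct_transmurality: float = 1.0
    infarct_slice_range: tuple[int, int] | None = None  # half-open [lo, hi); None = all slices
    remote_mean: float = 200.0
    remote_sd: float = 20.0
    infarct_enhancement: float = 3.0
    blood_mean: float = 500.0
    noise_sd: float | None = None                   # None -> remote_sd
    heart_rate: float = 500.0
    seed: int = 0
    geometry: Literal["ellipsoid", "cylinder"] = "ellipsoid"
    n_contour_vertices: int = 128

    @property
    def effective_noise_sd(self) -> float:
        """Realized additive noise; defaults to remote_sd so that the septal
        ROI statistics estimate (remote_mean, remote_sd)."""
        return self.remote_sd if self.noise_sd is None else self.noise_sd

    def validate(self) -> None:
        pos = {"endo_radius_ed": self.endo_radius_ed, "endo_radius_es": self.endo_radius_es,
               "wall_thickness_ed": self.wall_thickness_ed,
               "wall_thickness_es": self.wall_thickness_es,
               "lv_length": self.lv_length, "slice_thickness": self.slice_thickness,
               "pixel_spacing": self.pixel_spacing, "heart_rate": self.heart_rate}
        for name, v in pos.items():
            if v <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        if not (0.0 < self.infarct_angle_extent <= TWO_PI):
            raise ValidationError("infarct_angle_extent must be in (0, 2*pi]")
        if not (0.0 <= self.infarct_transmurality <= 1.0):
            raise ValidationError("infarct_transmurality must be in [0, 1]")
        if self.endo_radius_es > self.endo_radius_ed:
            raise ValidationError("endo_radius_es must not exceed endo_radius_ed "
                                  "(the systolic cavity is smaller)")
        if self.effective_noise_sd < 0 or self.remote_sd < 0:
            raise ValidationError("noise/remote SD must be non-negative")
        if self.infarct_enhancement <= 1.0:
            raise ValidationError("infarct_enhancement must exceed 1")
        lo, hi = self.resolved_slice_range
        if not (0 <= lo < hi <= self.n_slices):
            raise ValidationError(f"infarct_slice_range {self.infarct_slice_range} "
                                  f"not within [0, {self.n_slices})")
        if min(self.wall_thickness_ed, self.wall_thickness_es) < 2 * self.pixel_spacing:
            raise ValidationError("image grid too coarse to resolve the wall "
                                  "(wall thickness < 2 pixels)")
        if self.infarct_transmurality > 0 and arcs_overlap(
                self.septal_roi_start, SEPTAL_ROI_EXTENT,
                self.infarct_angle_start, self.infarct_angle_extent):
            raise ValidationError("infarct wedge overlaps the septal ROI; "
                                  "the remote ROI must stay remote")

    @property
    def resolved_slice_range(self) -> tuple[int, int]:
        if self.infarct_slice_range is None:
            return (0, self.n_slices)
        return self.infarct_slice_range

    @property
    def septal_roi_start(self) -> float:
        """Start angle of the 30-degree ROI wedge diametrically opposite the
        infarct wedge centre."""
        center = self.infarct_angle_start + self.infarct_angle_extent / 2 + np.pi
        return wrap_angle(center - SEPTAL_ROI_EXTENT / 2)

    def endo_radii(self, phase: str) -> np.ndarray:
        """Per-slice endocardial radius, slice 0 = apex."""
        a = self.endo_radius_ed if phase == "ED" else self.endo_radius_es
        if self.geometry == "cylinder":
            return np.full(self.n_slices, a)
        h = (np.arange(self.n_slices) + 0.5) * self.slice_thickness  # height above apex
        h = np.minimum(h, self.lv_length)
        frac = (self.lv_length - h) / self.lv_length
        return a * np.sqrt(np.clip(1.0 - frac ** 2, 0.0, None))

    def wall(self, phase: str) -> float:
        return self.wall_thickness_ed if phase == "ED" else self.wall_thickness_es


@dataclass
class PhantomTruth:
    """Analytic ground truth for the phantom, computed from closed-form
    geometry (volumes in microlitres, fractions in percent)."""

    edv: float
    esv: float
    ef: float
    stroke_volume: float
    cardiac_output: float
    true_transmural_infarct_fraction: float
    true_epicardial_infarct_area_fraction: float
    per_slice_wall_thickness_ed: np.ndarray = field(default_factory=lambda: np.array([]))
    per_slice_wall_thickness_es: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if not isinstance(v, np.ndarray)}
        d["per_slice_wall_thickness_ed"] = self.per_slice_wall_thickness_ed.tolist()
        d["per_slice_wall_thickness_es"] = self.per_slice_wall_thickness_es.tolist()
        return d


@dataclass
class PhantomResult:
    cine: dict[str, ImageStack]          # keys "ED", "ES"
    lge: ImageStack
    contours: ContourStack
    truth: PhantomTruth

    @property
    def septal_roi(self) -> dict[int, Polygon]:
        return self.contours.septal_roi


def _cavity_volume(spec: PhantomSpec, phase: str) -> float:
    a = spec.endo_radius_ed if phase == "ED" else spec.endo_radius_es
    if spec.geometry == "cylinder":
        return float(np.pi * a ** 2 * spec.n_slices * spec.slice_thickness)
    return float(2.0 / 3.0 * np.pi * a ** 2 * spec.lv_length)


def truth_volumes(spec: PhantomSpec) -> PhantomTruth:
    """Closed-form cavity volumes, EF, stroke volume, CO and infarct truth.

    Half-ellipsoid cavity volume is (2/3)*pi*a^2*L; the cylinder limit uses
    pi*a^2*(covered length).  Infarct truth integrates exact annulus-wedge
    areas over the sliced geometry, which is what any voxel-based analysis of
    the same stack estimates.
    """
    spec.validate()
    edv = _cavity_volume(spec, "ED")
    esv = _cavity_volume(spec, "ES")
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * spec.heart_rate / 1000.0  # uL/beat * beats/min -> mL/min

    lo, hi = spec.resolved_slice_range
    r_endo = spec.endo_radii("ED")
    w = spec.wall_thickness_ed
    r_epi = r_endo + w
    tau = spec.infarct_transmurality
    ext = spec.infarct_angle_extent
    wall_area = np.pi * (r_epi ** 2 - r_endo ** 2)
    depth = r_endo + tau * w
    wedge_area = np.zeros_like(r_endo)
    wedge_area[lo:hi] = 0.5 * ext * (depth[lo:hi] ** 2 - r_endo[lo:hi] ** 2)
    vol_fraction = 100.0 * wedge_area.sum() / wall_area.sum()

    epi_perim = TWO_PI * r_epi
    infarct_arc = np.zeros_like(r_epi)
    if tau > 0:
        infarct_arc[lo:hi] = ext * r_epi[lo:hi]
    area_fraction = 100.0 * infarct_arc.sum() / epi_perim.sum()

    return PhantomTruth(
        edv=edv, esv=esv, ef=ef, stroke_volume=sv, cardiac_output=co,
        true_transmural_infarct_fraction=float(vol_fraction),
        true_epicardial_infarct_area_fraction=float(area_fraction),
        per_slice_wall_thickness_ed=np.full(spec.n_slices, spec.wall_thickness_ed),
        per_slice_wall_thickness_es=np.full(spec.n_slices, spec.wall_thickness_es),
    )


def _grid(spec: PhantomSpec) -> tuple[int, tuple[float, float]]:
    half = max(spec.endo_radius_ed + spec.wall_thickness_ed,
               spec.endo_radius_es + spec.wall_thickness_es) + 1.0
    n_pix = int(np.ceil(2 * half / spec.pixel_spacing))
    mid = n_pix * spec.pixel_spacing / 2.0
    # offset the LV axis from the grid centre by an irrational sub-pixel
    # amount so no voxel centre sits exactly on a wedge/sector boundary ray
    # (real acquisitions are never lattice-aligned with the anatomy)
    center = (mid + spec.pixel_spacing / np.pi, mid + spec.pixel_spacing / np.e)
    return n_pix, center


def _contour_stack(spec: PhantomSpec, center: tuple[float, float]) -> ContourStack:
    contours = {}
    rois = {}
    for phase in ("ED", "ES"):
        radii = spec.endo_radii(phase)
        w = spec.wall(phase)
        for i, r in enumerate(radii):
            contours[(i, phase)] = SliceContours(
                epi=circle_polygon(center, r + w, spec.n_contour_vertices),
                endo=circle_polygon(center, r, spec.n_contour_vertices),
            )
    radii_ed = spec.endo_radii("ED")
    w = spec.wall_thickness_ed
    for i, r in enumerate(radii_ed):
        rois[i] = annular_wedge_polygon(center, r + 0.25 * w, r + 0.75 * w,
                                        spec.septal_roi_start, SEPTAL_ROI_EXTENT)
    return ContourStack(slice_thickness=spec.slice_thickness,
                        contours=contours, septal_roi=rois)


def _base_slice(spec: PhantomSpec, stack: ContourStack, phase: str,
                slice_index: int, x: np.ndarray, y: np.ndarray,
                center: tuple[float, float], with_infarct: bool) -> np.ndarray:
    from ._geom import points_in_polygon

    pair = stack.get(slice_index, phase)
    inside_epi = points_in_polygon(x, y, pair.epi)
    inside_endo = points_in_polygon(x, y, pair.endo)
    myo = inside_epi & ~inside_endo
    img = np.zeros(x.shape)
    img[inside_endo] = spec.blood_mean
    img[myo] = spec.remote_mean
    if with_infarct and spec.infarct_transmurality > 0:
        lo, hi = spec.resolved_slice_range
        if lo <= slice_index < hi:
            r = np.hypot(x - center[0], y - center[1])
            theta = np.arctan2(y - center[1], x - center[0])
            r_endo = spec.endo_radii(phase)[slice_index]
            depth = r_endo + spec.infarct_transmurality * spec.wall(phase)
            wedge = (myo & angle_in_arc(theta, spec.infarct_angle_start,
                                        spec.infarct_angle_extent)
                     & (r <= depth))
            img[wedge] = spec.remote_mean * spec.infarct_enhancement
    return img


def infarct_wedge_mask(spec: PhantomSpec, stack: ContourStack,
                       lge: ImageStack) -> np.ndarray:
    """Analytic voxel membership of the infarct wedge on the LGE grid
    (independent oracle for threshold-based classification)."""
    from ._geom import points_in_polygon

    x, y = lge.xy_centers()
    _, center = _grid(spec)
    out = np.zeros(lge.voxels.shape, dtype=bool)
    lo, hi = spec.resolved_slice_range
    if spec.infarct_transmurality == 0:
        return out
    for i in range(lo, hi):
        pair = stack.get(i, "ED")
        myo = points_in_polygon(x, y, pair.epi) & ~points_in_polygon(x, y, pair.endo)
        r = np.hypot(x - center[0], y - center[1])
        theta = np.arctan2(y - center[1], x - center[0])
        depth = spec.endo_radii("ED")[i] + spec.infarct_transmurality * spec.wall("ED")
        out[i] = (myo & angle_in_arc(theta, spec.infarct_angle_start,
                                     spec.infarct_angle_extent) & (r <= depth))
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate cine ED/ES stacks, an LGE stack, ground-truth contours, the
    septal ROI, and the analytic truth record.

    The same seed yields bit-identical stacks.  Voxel intensities are the
    deterministic tissue means (blood pool, remote myocardium, enhanced
    infarct wedge) plus additive Gaussian noise of SD ``effective_noise_sd``.
    """
    spec.validate()
    n_pix, center = _grid(spec)
    stack = _contour_stack(spec, center)
    x = (np.arange(n_pix) + 0.5) * spec.pixel_spacing
    xg, yg = np.meshgrid(x, x)

    rng = np.random.default_rng(spec.seed)

    def build(phase: str, with_infarct: bool) -> ImageStack:
        vol = np.stack([_base_slice(spec, stack, phase, i, xg, yg, center, with_infarct)
                        for i in range(spec.n_slices)])
        sd = spec.effective_noise_sd
        if sd > 0:
            vol = vol + rng.normal(0.0, sd, size=vol.shape)
        return ImageStack(vol, spec.pixel_spacing, spec.slice_thickness)

    lge = build("ED", with_infarct=True)
    cine_ed = build("ED", with_infarct=False)
    cine_es = build("ES", with_infarct=False)

    truth = truth_volumes(spec)
    return PhantomResult(cine={"ED": cine_ed, "ES": cine_es}, lge=lge,
                         contours=stack, truth=truth)


def thinned_wall_contours(radius_epi: float = 3.0, wall_remote: float = 1.0,
                          wall_thinned: float = 0.5,
                          wedge_start: float = 0.0,
                          wedge_extent: float = np.pi / 3,
                          taper: float = np.deg2rad(10.0),
                          n_slices: int = 9, slice_thickness: float = 1.0,
                          n_vertices: int = 720,
                          center: tuple[float, float] = (5.0, 5.0)) -> ContourStack:
    """Annular contour stack whose wall is thinned inside an angular wedge.

    Emulates post-infarction wall thinning: the endocardial radius bulges
    outward inside [wedge_start, wedge_start+wedge_extent) so the local wall
    is ``wall_thinned`` instead of ``wall_remote``, with a smooth cosine
    taper of width ``taper`` on either side to keep contours well behaved.
    Both phases share the geometry (a regional wall-thickness fixture, not a
    contraction model).
    """
    th = np.arange(n_vertices) * TWO_PI / n_vertices
    rel = wrap_angle(th - (wedge_start - taper))
    full = wedge_extent + 2 * taper

    def blend(rel_angle: np.ndarray) -> np.ndarray:
        # 0 outside the wedge+taper, 1 in the wedge core, cosine ramps between
        w = np.zeros_like(rel_angle)
        inside = rel_angle < full
        ramp_in = inside & (rel_angle < taper)
        ramp_out = inside & (rel_angle > full - taper)
        core = inside & ~ramp_in & ~ramp_out
        w[core] = 1.0
        w[ramp_in] = 0.5 * (1 - np.cos(np.pi * rel_angle[ramp_in] / taper))
        w[ramp_out] = 0.5 * (1 - np.cos(np.pi * (full - rel_angle[ramp_out]) / taper))
        return w

    wall = wall_remote - (wall_remote - wall_thinned) * blend(rel)
    cx, cy = center
    endo = np.column_stack([cx + (radius_epi - wall) * np.cos(th),
                            cy + (radius_epi - wall) * np.sin(th)])
    contours = {}
    for phase in ("ED", "ES"):
        for i in range(n_slices):
            contours[(i, phase)] = SliceContours(
                epi=circle_polygon(center, radius_epi, n_vertices),
                endo=Polygon(endo),
            )
    return ContourStack(slice_thickness=slice_thickness, contours=contours)
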