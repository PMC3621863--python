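"""Infarct sizing from late-gadolinium-enhancement stacks.

Pipeline: calibrate an intensity threshold from a remote septal ROI
(mean + 5 SD by default), classify hyperintense myocardial voxels, report
the transmural infarct volume fraction, partition each slice into 100
equal-angle circumferential sectors, and convert sectors whose infarct
transmurality exceeds 50% into an epicardial infarct surface area
(arc length x slice thickness).

Both cutoffs are strict inequalities: a voxel exactly at the threshold and
a sector at exactly 50% transmurality are not infarct.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from ._geom import TWO_PI, points_in_polygon, sector_arc_lengths, wrap_angle
from .io_contours import ContourStack, ImageStack, ValidationError

DEFAULT_SD_MULTIPLIER = 5.0
DEFAULT_N_SECTORS = 100
DEFAULT_TRANSMURALITY_CUTOFF = 0.5


@dataclass(frozen=True)
class Threshold:
    """Septal-ROI calibrated intensity threshold: value = mean + k*SD."""

    septal_mean: float
    septal_sd: float
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER

    @property
    def value(self) -> float:
        return self.septal_mean + self.sd_multiplier * self.septal_sd


@dataclass
class InfarctMask:
    """Boolean infarct/myocardium voxel masks congruent with the LGE stack."""

    infarct: np.ndarray       # bool (slice, row, col)
    myocardium: np.ndarray    # bool, the wall annulus
    pixel_spacing: float
    slice_thickness: float

    def __post_init__(self) -> None:
        if self.infarct.shape != self.myocardium.shape:
            raise ValidationError("infarct and myocardium masks are not congruent")
        if np.any(self.infarct & ~self.myocardium):
            raise ValidationError("infarct mask has voxels outside the myocardial annulus")


@dataclass
class SectorProfile:
    """Per-slice circumferential profile: infarct transmurality and
    epicardial arc length for each of ``n_sectors`` equal-angle sectors."""

    transmurality: np.ndarray   # (n_slices, n_sectors) in [0, 1]
    arc_length: np.ndarray      # (n_slices, n_sectors) in mm
    slice_thickness: float
    reference_angle: float = 0.0

    @property
    def n_sectors(self) -> int:
        return self.transmurality.shape[1]


@dataclass
class InfarctSizeResult:
    threshold: Threshold
    transmural_infarct_fraction: float       # percent of wall volume
    epicardial_infarct_area: float           # mm^2
    epicardial_infarct_area_fraction: float  # percent of epicardial surface


def compute_threshold(lge: ImageStack, septal_roi: dict[int, Polygon],
                      sd_multiplier: float = DEFAULT_SD_MULTIPLIER) -> Threshold:
    """Pool LGE intensities over the septal ROI polygons (one global threshold
    per subject) and return mean + sd_multiplier * sample SD."""
    if not septal_roi:
        raise ValidationError("septal ROI is empty")
    x, y = lge.xy_centers()
    samples = []
    for idx, poly in septal_roi.items():
        if not 0 <= idx < lge.n_slices:
            raise ValidationError(f"septal ROI slice {idx} outside the LGE stack")
        inside = points_in_polygon(x, y, poly)
        samples.append(lge.voxels[idx][inside])
    pooled = np.concatenate(samples)
    if pooled.size < 10:
        raise ValidationError(f"septal ROI covers only {pooled.size} voxels; need >= 10")
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    return Threshold(septal_mean=mean, septal_sd=sd, sd_multiplier=sd_multiplier)


def classify_infarct_voxels(lge: ImageStack, contours: ContourStack,
                            thr: Threshold, phase: str = "ED") -> InfarctMask:
    """Voxel is infarct iff its centre lies in the myocardial annulus and its
    intensity strictly exceeds the threshold."""
    slices = contours.slice_indices(phase)
    missing = sorted(set(range(lge.n_slices)) - set(slices))
    if missing:
        raise ValidationError(f"no {phase} contours for LGE slices {missing}")
    x, y = lge.xy_centers()
    myo = np.zeros(lge.voxels.shape, dtype=bool)
    for i in range(lge.n_slices):
        pair = contours.get(i, phase)
        myo[i] = points_in_polygon(x, y, pair.epi) & ~points_in_polygon(x, y, pair.endo)
    infarct = myo & (lge.voxels > thr.value)
    return InfarctMask(infarct=infarct, myocardium=myo,
                       pixel_spacing=lge.pixel_spacing,
                       slice_thickness=lge.slice_thickness)


def transmural_infarct_fraction(mask: InfarctMask) -> float:
    """Infarct volume as a percentage of myocardial wall volume.

    Voxel volume (spacing^2 x slice thickness) is uniform, so the ratio
    reduces to a voxel-count ratio.
    """
    n_wall = int(mask.myocardium.sum())
    if n_wall == 0:
        raise ValidationError("zero myocardial volume")
    return 100.0 * float(mask.infarct.sum()) / n_wall


def sector_transmurality(mask: InfarctMask, contours: ContourStack,
                         n_sectors: int = DEFAULT_N_SECTORS,
                         reference_angle: float = 0.0,
                         phase: str = "ED") -> SectorProfile:
    """Divide each slice's myocardium into equal-angle sectors about the
    epicardial centroid; per sector, transmurality is the infarct/myocardial
    voxel-count ratio."""
    if n_sectors < 4:
        raise ValidationError("n_sectors must be >= 4")
    n_slices = mask.myocardium.shape[0]
    width = TWO_PI / n_sectors
    trans = np.zeros((n_slices, n_sectors))
    arcs = np.zeros((n_slices, n_sectors))
    # reconstruct the pixel-centre grid of the congruent stack
    rows, cols = mask.myocardium.shape[1:]
    xs = (np.arange(cols) + 0.5) * mask.pixel_spacing
    ys = (np.arange(rows) + 0.5) * mask.pixel_spacing
    x, y = np.meshgrid(xs, ys)
    for i in range(n_slices):
        pair = contours.get(i, phase)
        c = pair.epi.centroid
        theta = np.arctan2(y - c.y, x - c.x)
        bins = (wrap_angle(theta - reference_angle) // width).astype(int) % n_sectors
        myo = mask.myocardium[i]
        inf = mask.infarct[i]
        n_myo = np.bincount(bins[myo], minlength=n_sectors)
        n_inf = np.bincount(bins[inf], minlength=n_sectors)
        if np.any(n_myo == 0):
            empty = int(np.flatnonzero(n_myo == 0)[0])
            raise ValidationError(
                f"slice {i} sector {empty} contains no myocardial voxels; "
                "use a finer pixel grid or fewer sectors")
        trans[i] = n_inf / n_myo
        arcs[i] = sector_arc_lengths(pair.epi, (c.x, c.y), reference_angle, n_sectors)
    return SectorProfile(transmurality=trans, arc_length=arcs,
                         slice_thickness=mask.slice_thickness,
                         reference_angle=reference_angle)


def epicardial_infarct_area(profile: SectorProfile,
                            transmurality_cutoff: float = DEFAULT_TRANSMURALITY_CUTOFF,
                            ) -> tuple[float, float]:
    """Epicardial infarct surface area and its percentage of total epicardial
    area.  Sectors count as infarct only when transmurality strictly exceeds
    the cutoff; each infarct sector contributes arc length x slice thickness.
    """
    infarct_sectors = profile.transmurality > transmurality_cutoff
    area = float(profile.arc_length[infarct_sectors].sum() * profile.slice_thickness)
    total = float(profile.arc_length.sum() * profile.slice_thickness)
    if total == 0:
        raise ValidationError("zero epicardial surface area")
    return area, 100.0 * area / total


def quantify_infarct(lge: ImageStack, contours: ContourStack,
                     septal_roi: dict[int, Polygon] | None = None,
                     sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
                     n_sectors: int = DEFAULT_N_SECTORS,
                     transmurality_cutoff: float = DEFAULT_TRANSMURALITY_CUTOFF,
                     reference_angle: float = 0.0,
                     phase: str = "ED") -> InfarctSizeResult:
    """Full infarct-sizing pipeline on one LGE stack."""
    roi = septal_roi if septal_roi is not None else contours.septal_roi
    thr = compute_threshold(lge, roi, sd_multiplier)
    mask = classify_infarct_voxels(lge, contours, thr, phase=phase)
    vol_fraction = transmural_infarct_fraction(mask)
    profile = sector_transmurality(mask, contours, n_sectors, reference_angle, phase)
    area, area_fraction = epicardial_infarct_area(profile, transmurality_cutoff)
    return InfarctSizeResult(threshold=thr,
                             transmural_infarct_fraction=vol_fraction,
                             epicardial_infarct_area=area,
                             epicardial_infarct_area_fraction=area_fraction)
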