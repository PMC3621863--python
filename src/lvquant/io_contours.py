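"""Image-stack and contour I/O with geometric validation.

Images are short-axis stacks stored as NIfTI-1 or multi-page TIFF; contours
are ordered vertex polygons in physical millimetres, stored as JSON (primary)
or long-format CSV.  Every read path validates geometric well-formedness
before anything downstream sees the data: polygons must be closed, simple,
have at least 8 vertices, and each endocardial contour must lie strictly
inside its epicardial partner.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from ._geom import ensure_ccw, polygon_vertices

PHASES = ("ED", "ES")
ROLES = ("epi", "endo", "septal_roi")

MIN_VERTICES = 8


class ValidationError(ValueError):
    """Raised when an input image or contour set is geometrically malformed."""


@dataclass
class ImageStack:
    """A short-axis scalar volume with physical spacing metadata.

    voxels is indexed (slice, row, col); slice 0 is the apex and indices
    ascend toward the base.  Pixel centres map to physical coordinates as
    x = (col + 0.5) * pixel_spacing, y = (row + 0.5) * pixel_spacing.
    """

    voxels: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    slice_order: str = "apex_to_base"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValidationError("voxels must be a 3D (slice, row, col) array with >= 1 slice")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValidationError("pixel_spacing and slice_thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (1 mm^3 == 1 microlitre)."""
        return self.pixel_spacing ** 2 * self.slice_thickness

    def xy_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (x, y) of pixel-centre coordinates in mm, shape (rows, cols)."""
        _, rows, cols = self.voxels.shape
        x = (np.arange(cols) + 0.5) * self.pixel_spacing
        y = (np.arange(rows) + 0.5) * self.pixel_spacing
        return np.meshgrid(x, y)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        affine = np.diag([stack.pixel_spacing, stack.pixel_spacing,
                          stack.slice_thickness, 1.0])
        img = nib.Nifti1Image(np.transpose(stack.voxels, (2, 1, 0)).astype(np.float32),
                              affine)
        nib.save(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        res_per_cm = 10.0 / stack.pixel_spacing  # pixels per centimetre
        tifffile.imwrite(
            str(path),
            stack.voxels.astype(np.float32),
            photometric="minisblack",
            resolution=(res_per_cm, res_per_cm),
            resolutionunit="CENTIMETER",
            description=json.dumps({"slice_thickness_mm": stack.slice_thickness}),
        )
    else:
        raise ValidationError(f"unknown image format for {path.name!r} (use .nii/.nii.gz/.tif)")


def read_image_stack(path: str | Path, fmt: str | None = None) -> ImageStack:
    """Read a NIfTI-1 or multi-page TIFF stack.

    Spacing metadata must be present in the file; it is never silently
    defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        if path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif path.suffix in (".tif", ".tiff"):
            fmt = "tiff"
        else:
            raise ValidationError(f"cannot infer image format from {path.name!r}")

    if fmt == "nifti":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValidationError(f"{path.name}: missing spacing in NIfTI header")
        if abs(zooms[0] - zooms[1]) > 1e-6:
            raise ValidationError(f"{path.name}: non-square in-plane pixels {zooms[:2]}")
        vox = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
        return ImageStack(vox, float(zooms[0]), float(zooms[2]))
    if fmt == "tiff":
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            tags = page.tags
            if "XResolution" not in tags or "ResolutionUnit" not in tags:
                raise ValidationError(f"{path.name}: missing spacing (no TIFF resolution tags)")
            unit = tags["ResolutionUnit"].value
            num, den = tags["XResolution"].value
            if num == 0 or getattr(unit, "value", unit) in (0, 1):
                raise ValidationError(f"{path.name}: missing spacing (resolution unit NONE)")
            res = num / den  # pixels per unit
            unit_mm = {2: 25.4, 3: 10.0}[int(getattr(unit, "value", unit))]
            spacing = unit_mm / res
            desc = page.description or ""
            try:
                thickness = float(json.loads(desc)["slice_thickness_mm"])
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValidationError(
                    f"{path.name}: missing slice thickness in TIFF description") from exc
            vox = tf.asarray()
        if vox.ndim == 2:
            vox = vox[None]
        return ImageStack(vox, float(spacing), thickness)
    raise ValidationError(f"unknown format {fmt!r}")


@dataclass
class SliceContours:
    """Epicardial/endocardial polygon pair for one slice and phase."""

    epi: Polygon
    endo: Polygon


def _validate_polygon(poly: Polygon, label: str) -> Polygon:
    verts = polygon_vertices(poly)
    if len(verts) < MIN_VERTICES:
        raise ValidationError(f"{label}: polygon has {len(verts)} vertices, need >= {MIN_VERTICES}")
    if not poly.is_valid or not poly.exterior.is_simple:
        raise ValidationError(f"{label}: polygon is self-intersecting or otherwise invalid")
    return ensure_ccw(poly)


@dataclass
class ContourStack:
    """Per-slice, per-phase LV contours plus optional per-slice septal ROIs.

    Keys of ``contours`` are (slice_index, phase); slice indices run 0 = apex
    upward, phases are "ED"/"ES".  All polygons are normalized to
    counterclockwise orientation at construction.
    """

    slice_thickness: float
    contours: dict[tuple[int, str], SliceContours] = field(default_factory=dict)
    septal_roi: dict[int, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise ValidationError("slice_thickness must be positive")
        self.validate()

    def validate(self) -> None:
        for (idx, phase), pair in self.contours.items():
            if phase not in PHASES:
                raise ValidationError(f"slice {idx}: unknown phase {phase!r}")
            label = f"slice {idx} phase {phase}"
            pair.epi = _validate_polygon(pair.epi, f"{label} epi")
            pair.endo = _validate_polygon(pair.endo, f"{label} endo")
            if not (pair.epi.contains(pair.endo)
                    and pair.endo.exterior.distance(pair.epi.exterior) > 0):
                raise ValidationError(f"{label}: endocardial contour is not strictly "
                                      "inside the epicardial contour")
        for idx, roi in self.septal_roi.items():
            self.septal_roi[idx] = _validate_polygon(roi, f"slice {idx} septal_roi")

    def phases(self) -> list[str]:
        return sorted({phase for _, phase in self.contours})

    def slice_indices(self, phase: str) -> list[int]:
        idx = sorted(i for i, p in self.contours if p == phase)
        if idx and idx != list(range(idx[0], idx[-1] + 1)):
            raise ValidationError(f"phase {phase}: non-contiguous slice indices {idx}")
        return idx

    def get(self, slice_index: int, phase: str) -> SliceContours:
        try:
            return self.contours[(slice_index, phase)]
        except KeyError:
            raise ValidationError(f"no contour for slice {slice_index} phase {phase}") from None


def write_contours(stack: ContourStack, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        _write_contours_csv(stack, path)
        return
    records = []
    for (idx, phase), pair in sorted(stack.contours.items()):
        for role, poly in (("epi", pair.epi), ("endo", pair.endo)):
            records.append({"slice": idx, "phase": phase, "role": role,
                            "vertices_mm": polygon_vertices(poly).tolist()})
    for idx, roi in sorted(stack.septal_roi.items()):
        records.append({"slice": idx, "phase": None, "role": "septal_roi",
                        "vertices_mm": polygon_vertices(roi).tolist()})
    payload = {"format": "lvquant-contours", "version": 1,
               "slice_thickness_mm": stack.slice_thickness, "contours": records}
    Path(path).write_text(json.dumps(payload))


def _write_contours_csv(stack: ContourStack, path: Path) -> None:
    rows = []
    def emit(idx, phase, role, poly):
        for k, (x, y) in enumerate(polygon_vertices(poly)):
            rows.append((idx, phase, role, k, x, y, stack.slice_thickness))
    for (idx, phase), pair in sorted(stack.contours.items()):
        emit(idx, phase, "epi", pair.epi)
        emit(idx, phase, "endo", pair.endo)
    for idx, roi in sorted(stack.septal_roi.items()):
        emit(idx, "", "septal_roi", roi)
    df = pd.DataFrame(rows, columns=["slice", "phase", "role", "vertex_index",
                                     "x_mm", "y_mm", "slice_thickness_mm"])
    df.to_csv(path, index=False)


def read_contours(path: str | Path) -> ContourStack:
    """Read contours from the JSON schema or the long-format CSV dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        return _read_contours_csv(path)
    payload = json.loads(path.read_text())
    if payload.get("format") != "lvquant-contours":
        raise ValidationError(f"{path.name}: not a recognized contour file")
    return _assemble(payload["slice_thickness_mm"],
                     ((r["slice"], r.get("phase"), r["role"], np.asarray(r["vertices_mm"]))
                      for r in payload["contours"]))


def _read_contours_csv(path: Path) -> ContourStack:
    df = pd.read_csv(path)
    required = {"slice", "phase", "role", "vertex_index", "x_mm", "y_mm", "slice_thickness_mm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path.name}: missing columns {sorted(required - set(df.columns))}")
    thickness = float(df["slice_thickness_mm"].iloc[0])
    entries = []
    for (idx, phase, role), grp in df.groupby(["slice", "phase", "role"], dropna=False):
        grp = grp.sort_values("vertex_index")
        phase = None if pd.isna(phase) or phase == "" else str(phase)
        entries.append((int(idx), phase, role, grp[["x_mm", "y_mm"]].to_numpy()))
    return _assemble(thickness, entries)


def _assemble(slice_thickness: float,
              entries: Iterable[tuple[int, str | None, str, np.ndarray]]) -> ContourStack:
    polys: dict[tuple[int, str], dict[str, Polygon]] = {}
    rois: dict[int, Polygon] = {}
    for idx, phase, role, verts in entries:
        if role not in ROLES:
            raise ValidationError(f"slice {idx}: unknown contour role {role!r}")
        poly = Polygon(verts)
        if role == "septal_roi":
            rois[idx] = poly
        else:
            polys.setdefault((idx, phase), {})[role] = poly
    contours = {}
    for (idx, phase), d in polys.items():
        if "epi" not in d or "endo" not in d:
            raise ValidationError(f"slice {idx} phase {phase}: need both epi and endo contours")
        contours[(idx, phase)] = SliceContours(epi=d["epi"], endo=d["endo"])
    return ContourStack(slice_thickness=slice_thickness, contours=contours, septal_roi=rois)
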