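"""Global LV function from endocardial contours.

Cavity volume is the slice-summation (Simpson) rule: endocardial polygon
area times slice thickness, summed over contoured slices with no inter-slice
interpolation.  Ejection fraction and cardiac output use the standard
definitions EF = 100*(EDV-ESV)/EDV and CO = (EDV-ESV)*HR.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_contours import ContourStack, ValidationError

log = logging.getLogger(__name__)


@dataclass
class GlobalFunctionResult:
    """Volumes in microlitres, EF in percent, CO in mL/min."""

    edv: float
    esv: float
    stroke_volume: float
    ef: float
    cardiac_output: float
    heart_rate: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def cavity_volume(contours: ContourStack, phase: str) -> float:
    """Endocardial cavity volume in microlitres (1 mm^3 == 1 uL) for a phase."""
    slices = contours.slice_indices(phase)
    if not slices:
        raise ValidationError(f"no contours for phase {phase!r}")
    total = 0.0
    for i in slices:
        area = contours.get(i, phase).endo.area
        if area == 0.0:
            log.warning("slice %d phase %s: zero-area endocardial contour", i, phase)
        total += area * contours.slice_thickness
    return total


def global_function(contours: ContourStack, heart_rate: float) -> GlobalFunctionResult:
    """EDV, ESV, stroke volume, EF and CO from a two-phase contour stack.

    Phase labels are trusted; ESV > EDV is flagged as pathological labeling
    with a warning but still computed (negative stroke volume and EF).
    """
    if heart_rate <= 0:
        raise ValidationError("heart_rate must be positive")
    edv = cavity_volume(contours, "ED")
    esv = cavity_volume(contours, "ES")
    if esv > edv:
        log.warning("ESV (%.1f uL) exceeds EDV (%.1f uL): check phase labels", esv, edv)
    if edv == 0:
        raise ValidationError("EDV is zero; cannot compute ejection fraction")
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * heart_rate / 1000.0  # uL -> mL
    return GlobalFunctionResult(edv=edv, esv=esv, stroke_volume=sv, ef=ef,
                                cardiac_output=co, heart_rate=heart_rate)
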