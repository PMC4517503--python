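"""LV functional parameters from a short-axis contour stack.

Volumes use slice summation (Simpson's rule): each slice contributes its
cavity area times the centre-to-centre inter-slice distance, with no
interpolation for missing slices -- omitted slices simply contribute
nothing, so slice omission shows up as volume bias, which is exactly the
phenomenon under study.  Mass is the ED myocardial shell volume
(epicardial minus endocardial) times 1.05 g/ml.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contour_model import StudyContourSet, polygon_area_mm2, rasterize

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


class VolumetricsError(ValueError):
    """Missing contours or physically inconsistent volumes."""


@dataclass(frozen=True)
class LVFunction:
    """EDV, ESV, LVM, EF for one case from one source."""

    case_id: str
    source_id: str
    edv_ml: float
    esv_ml: float
    lvm_g: float
    ef_pct: float


def _slice_area_mm2(contour, geometry, backend: str, factor: int) -> float:
    if backend == "polygon":
        return polygon_area_mm2(contour)
    if backend == "mask":
        return rasterize(contour, geometry, factor).area_mm2()
    raise ValueError(f"unknown area backend {backend!r}")


def stack_volume_ml(cs: StudyContourSet, frame: str, surface: str,
                    backend: str = "polygon", factor: int = 4) -> float:
    """Sum of per-slice cavity area x inter-slice distance, in ml."""
    slices = cs.slices_with(frame, surface)
    if not slices:
        raise VolumetricsError(
            f"no contours for ({frame}, {surface}) in {cs.case_id}/{cs.source_id}"
        )
    total_mm3 = 0.0
    for s in slices:
        contour = cs.get(frame, s, surface)
        total_mm3 += (_slice_area_mm2(contour, cs.geometry, backend, factor)
                      * cs.geometry.slice_spacing_mm)
    return total_mm3 / 1000.0


def lv_mass_g(epi_volume_ml: float, edv_ml: float) -> float:
    """Myocardial mass at ED: (epicardial volume - EDV) x 1.05 g/ml."""
    if epi_volume_ml < edv_ml:
        raise VolumetricsError(
            f"epicardial volume {epi_volume_ml:.1f} ml < EDV {edv_ml:.1f} ml "
            "(surface nesting violated upstream)"
        )
    return (epi_volume_ml - edv_ml) * MYOCARDIAL_DENSITY_G_PER_ML


def ejection_fraction_pct(edv_ml: float, esv_ml: float) -> float:
    """EF = 100 (EDV - ESV) / EDV."""
    if edv_ml <= 0:
        raise VolumetricsError("EDV must be positive")
    return 100.0 * (edv_ml - esv_ml) / edv_ml


def select_es_frame(mid_slice_areas: Sequence[float]) -> int:
    """ES frame index = argmin of mid-slice endocardial cavity area.

    Ties resolve to the earliest frame.  Frames with a missing (non-finite
    or None) area are an error: the selection needs every frame's area.
    """
    areas = list(mid_slice_areas)
    if len(areas) < 2:
        raise VolumetricsError("need at least two frames to select ES")
    if any(a is None or not np.isfinite(a) for a in areas):
        raise VolumetricsError("missing mid-slice area in at least one frame")
    return int(np.argmin(areas))


def compute_lv_function(cs: StudyContourSet, backend: str = "polygon",
                        factor: int = 4) -> LVFunction:
    """EDV/ESV from endocardial stacks, LVM from the ED epicardial stack, EF.

    Requires ED endo, ED epi and ES endo on at least one slice each; the
    error lists absent (frame, surface) requirements.
    """
    required = [("ED", "endo"), ("ED", "epi"), ("ES", "endo")]
    missing = [fs for fs in required if not cs.slices_with(*fs)]
    if missing:
        raise VolumetricsError(
            f"{cs.case_id}/{cs.source_id}: missing contours for {missing}"
        )
    edv = stack_volume_ml(cs, "ED", "endo", backend, factor)
    esv = stack_volume_ml(cs, "ES", "endo", backend, factor)
    epi_volume = stack_volume_ml(cs, "ED", "epi", backend, factor)
    return LVFunction(
        case_id=cs.case_id,
        source_id=cs.source_id,
        edv_ml=edv,
        esv_ml=esv,
        lvm_g=lv_mass_g(epi_volume, edv),
        ef_pct=ejection_fraction_pct(edv, esv),
    )
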