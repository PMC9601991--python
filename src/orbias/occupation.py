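"""Y-view occupation ratio and Thomazeau atrophy staging.

The occupation ratio (OR) is the quotient of the cross-sectional surface
area of the supraspinatus muscle and the supraspinatus fossa area on a
single oblique-sagittal slice (the Y-view, the most lateral slice where the
scapular spine, coracoid and clavicle form a "Y"). Thomazeau stages grade
atrophy from the OR: stage I (>= 0.60, normal or mild), stage II (0.40 to
0.60, moderate), stage III (< 0.40, severe). In phantoms, which have no bony
landmarks, the Y-view is located parametrically as an offset medial to the
lateral fossa edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MeasurementError, YViewRangeError, ZeroFossaAreaError
from .mask import VoxelMask
from .segmetrics import long_short_axes, slice_area

__all__ = ["ORMeasure", "select_y_view", "occupation_ratio", "thomazeau_stage"]


@dataclass(frozen=True)
class ORMeasure:
    """Occupation-ratio measurement on one Y-view slice."""

    yview_index: int
    muscle_area_mm2: float
    fossa_area_mm2: float
    or_value: float
    stage: str
    muscle_cp_mm2: float = float("nan")
    fossa_cp_mm2: float = float("nan")

    @property
    def cp_or_value(self) -> float:
        """Auxiliary OR built from cross-products instead of traced areas."""
        return self.muscle_cp_mm2 / self.fossa_cp_mm2


def select_y_view(fossa: VoxelMask, yview_offset_mm: float) -> int:
    """Index of the constant-x plane ``yview_offset_mm`` medial to the most
    lateral fossa-containing slice.

    Offset 0 selects the lateral fossa edge itself; the selected plane must
    still intersect the fossa.
    """
    present = np.flatnonzero(fossa.data.any(axis=(1, 2)))
    if present.size == 0:
        raise MeasurementError("fossa mask is empty; no Y-view can be selected")
    if yview_offset_mm < 0:
        raise YViewRangeError(f"Y-view offset must be >= 0, got {yview_offset_mm}")
    dx = fossa.spacing_mm[0]
    idx = int(present[-1]) - int(round(yview_offset_mm / dx))
    if idx < int(present[0]):
        raise YViewRangeError(
            f"Y-view offset {yview_offset_mm} mm falls medial of the fossa, which "
            f"spans slices {present[0]}..{present[-1]} at {dx} mm spacing"
        )
    return idx


def occupation_ratio(
    muscle: VoxelMask,
    fossa: VoxelMask,
    yview_index: int,
    compute_cp: bool = True,
) -> ORMeasure:
    """OR = muscle area / fossa area on the Y-view slice, with stage attached.

    Cross-products of both regions are reported as auxiliary columns; the
    canonical OR is built from traced areas.
    """
    if muscle.spacing_mm != fossa.spacing_mm:
        raise ValueError(
            f"muscle spacing {muscle.spacing_mm} != fossa spacing {fossa.spacing_mm}"
        )
    if not 0 <= yview_index < fossa.shape[0]:
        raise YViewRangeError(f"Y-view index {yview_index} outside grid of {fossa.shape[0]} slices")
    inplane = fossa.spacing_mm[1:]
    m_sl = muscle.data[yview_index]
    f_sl = fossa.data[yview_index]
    fossa_area = slice_area(f_sl, inplane)
    if fossa_area == 0.0:
        raise ZeroFossaAreaError(
            f"fossa area is zero on slice {yview_index}; the occupation ratio is undefined"
        )
    muscle_area = slice_area(m_sl, inplane)
    m_cp = f_cp = float("nan")
    if compute_cp:
        f_cp = float(np.prod(long_short_axes(f_sl, inplane)))
        if muscle_area > 0.0:
            m_cp = float(np.prod(long_short_axes(m_sl, inplane)))
        else:
            m_cp = 0.0
    or_value = muscle_area / fossa_area
    return ORMeasure(
        yview_index=int(yview_index),
        muscle_area_mm2=muscle_area,
        fossa_area_mm2=fossa_area,
        or_value=or_value,
        stage=thomazeau_stage(or_value),
        muscle_cp_mm2=m_cp,
        fossa_cp_mm2=f_cp,
    )


def thomazeau_stage(or_value: float) -> str:
    """Thomazeau atrophy stage from the occupation ratio.

    Stage I for OR >= 0.60 (upper boundary inclusive), stage II for
    0.40 <= OR < 0.60, stage III below 0.40.
    """
    if or_value < 0:
        raise ValueError(f"occupation ratio must be >= 0, got {or_value}")
    if or_value >= 0.60:
        return "I"
    if or_value >= 0.40:
        return "II"
    return "III"
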