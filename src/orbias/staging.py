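"""Tear-classification rules used to define cohort subgroups.

Partial-thickness supraspinatus tears are graded after Ellman by tear depth
(< 3 mm, 3-6 mm, > 6 mm) or equivalently by the torn fraction of the tendon
diameter (< 1/4, < 1/2, > 1/2). Full-thickness tears are graded after Patte
by how far the tendon stump has retracted medially: near the bony insertion
(grade 1), at the dome of the humeral head (grade 2), or at the glenoid level
or further medial (grade 3).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TearSpec", "ellman_grade", "patte_grade", "STUMP_POSITIONS"]

STUMP_POSITIONS = ("insertion", "humeral_dome", "glenoid")

_PATTE_BY_POSITION = {pos: grade for grade, pos in enumerate(STUMP_POSITIONS, start=1)}

_ROMAN = {1: "I", 2: "II", 3: "III"}


@dataclass(frozen=True)
class TearSpec:
    """Tear description: intact, partial (depth/fraction), or full (stump)."""

    kind: str
    partial_depth_mm: float | None = None
    partial_fraction: float | None = None
    stump_position: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("intact", "partial", "full"):
            raise ValueError(f"unknown tear kind {self.kind!r}")
        if self.partial_depth_mm is not None and self.partial_depth_mm < 0:
            raise ValueError("tear depth must be >= 0")
        if self.partial_fraction is not None and not 0.0 <= self.partial_fraction <= 1.0:
            raise ValueError("tear fraction must be in [0, 1]")
        if (self.stump_position is not None) != (self.kind == "full"):
            raise ValueError("stump position must be given iff the tear is full-thickness")
        if self.kind == "full" and self.stump_position not in STUMP_POSITIONS:
            raise ValueError(
                f"unknown stump position {self.stump_position!r}; expected one of {STUMP_POSITIONS}"
            )


def ellman_grade(depth_mm: float | None = None, fraction: float | None = None) -> str:
    """Ellman grade of a partial-thickness tear: 'I', 'II' or 'III'.

    Depth boundaries: grade I below 3 mm, grade II for 3-6 mm inclusive,
    grade III above 6 mm. The fraction criterion (of the tendon diameter)
    uses 1/4 and 1/2 as the analogous cut points, with exactly one half
    falling to grade II, mirroring the inclusive 6 mm depth boundary. When
    both are supplied, depth is the primary criterion.
    """
    if depth_mm is None and fraction is None:
        raise ValueError("ellman_grade needs a tear depth or a tendon-diameter fraction")
    if depth_mm is not None:
        if depth_mm < 0:
            raise ValueError(f"tear depth must be >= 0, got {depth_mm}")
        if depth_mm < 3.0:
            return "I"
        if depth_mm <= 6.0:
            return "II"
        return "III"
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"tear fraction must be in [0, 1], got {fraction}")
    if fraction < 0.25:
        return "I"
    if fraction <= 0.5:
        return "II"
    return "III"


def patte_grade(stump_position: str) -> int:
    """Patte retraction grade (1-3) from the tendon-stump landmark."""
    try:
        return _PATTE_BY_POSITION[stump_position]
    except KeyError:
        raise ValueError(
            f"unknown stump position {stump_position!r}; expected one of {STUMP_POSITIONS}"
        ) from None


def roman(grade: int) -> str:
    """Roman-numeral form of a 1-3 grade (report formatting)."""
    return _ROMAN[int(grade)]
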