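"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

AXIS_NAMES = {"x": 0, "y": 1, "z": 2}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed clinical-report style.

    Python's builtin ``round`` uses banker's rounding; report tables in this
    pipeline use conventional half-up rounding (e.g. 50.335 % -> 50.3 %,
    0.125 -> 0.13).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def resolve_axis(axis: int | str) -> int:
    """Map an axis given as index or anatomical letter (x/y/z) to an index."""
    if isinstance(axis, str):
        try:
            return AXIS_NAMES[axis.lower()]
        except KeyError:
            raise ValueError(f"unknown axis {axis!r}; expected x, y, z or 0-2") from None
    axis = int(axis)
    if axis not in (0, 1, 2):
        raise ValueError(f"axis index {axis} out of range for a 3D grid")
    return axis
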