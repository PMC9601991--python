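import numpy as np
import pytest

from orbias.phantom import (
    CohortSpec,
    GridSpec,
    ShoulderPhantomSpec,
    SpindleSpec,
    grid_for_spindle,
    make_spindle,
)


@pytest.fixture(scope="session")
def spindle50() -> SpindleSpec:
    """Mid-sized belly with exactly 50 cm^3 analytic volume."""
    return SpindleSpec.from_volume(50.0)


@pytest.fixture(scope="session")
def spindle50_mask_1mm(spindle50):
    return make_spindle(spindle50, grid_for_spindle(spindle50, (1.0, 1.0, 1.0)))


@pytest.fixture(scope="session")
def shoulder_spec(spindle50) -> ShoulderPhantomSpec:
    return ShoulderPhantomSpec(muscle=spindle50)


@pytest.fixture(scope="session")
def tiny_cohort_spec() -> CohortSpec:
    """Small cohort for fast end-to-end runs."""
    return CohortSpec(
        n_intact=6,
        n_partial=8,
        n_full=6,
        ellman_grade_counts=(4, 3, 1),
        patte_grade_counts=(3, 2, 1),
    )


def digitized_disk(radius_mm: float, pixel_mm: float) -> np.ndarray:
    """Center-inside digitization of a disk, used as a 2D fixture."""
    n = int(np.ceil(2 * radius_mm / pixel_mm)) + 4
    c = n * pixel_mm / 2.0
    ii, jj = np.mgrid[0:n, 0:n]
    x = (ii + 0.5) * pixel_mm - c
    y = (jj + 0.5) * pixel_mm - c
    return x**2 + y**2 <= radius_mm**2


@pytest.fixture(scope="session")
def disk_r10_1mm() -> np.ndarray:
    return digitized_disk(10.0, 1.0)


def brute_force_axes(mask_slice: np.ndarray, pixel_spacing) -> tuple[float, float]:
    """Independent O(n^2) caliper oracle over all foreground pixel corners.

    Long axis: max distance over every pair of pixel corners; ties resolved
    toward the direction closest to the x-axis. Short axis: extent of all
    corners projected perpendicular to the long-axis direction.
    """
    s = np.asarray(pixel_spacing, dtype=float)
    idx = np.argwhere(mask_slice)
    pts = []
    for di in (0, 1):
        for dj in (0, 1):
            pts.append((idx + (di, dj)) * s)
    pts = np.unique(np.concatenate(pts), axis=0)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    best = d2.max()
    pairs = np.argwhere(d2 >= best * (1 - 1e-12))
    chosen, chosen_angle = None, None
    for i, j in pairs:
        if i >= j:
            continue
        v = pts[j] - pts[i]
        a = abs(np.arctan2(v[1], v[0]))
        a = min(a, np.pi - a)
        if chosen is None or a < chosen_angle - 1e-12:
            chosen, chosen_angle = (i, j), a
    v = pts[chosen[1]] - pts[chosen[0]]
    long_axis = float(np.linalg.norm(v))
    n = np.array([-v[1], v[0]]) / long_axis
    proj = pts @ n
    return long_axis, float(proj.max() - proj.min())
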