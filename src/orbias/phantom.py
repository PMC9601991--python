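"""Synthetic shoulder phantoms with analytically known ground truth.

The generator voxelizes spindle-shaped muscle bellies modelled as solids of
revolution about the medial-lateral (x) axis,

    r(x) = R * (1 - (2x/L)^2)^p   for x in [-L/2, L/2],

with maximum radius ``R``, length ``L`` and taper exponent ``p``. The exact
volume of this solid,

    V = pi * R^2 * (L/2) * integral_{-1}^{1} (1 - u^2)^{2p} du,

serves as the ground truth that physical water-displacement volumetry provides
for real specimens. A shoulder phantom pairs an (optionally atrophied) belly
with a static fossa envelope; a full-thickness tear is modelled as a rigid
medial translation of the belly only, which is the retraction mechanism whose
effect on single-slice occupation ratios this package quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

from .errors import DimensionError
from .mask import VoxelMask
from .staging import STUMP_POSITIONS, TearSpec

__all__ = [
    "GridSpec",
    "SpindleSpec",
    "ShoulderPhantomSpec",
    "CohortSpec",
    "taper_integral",
    "make_spindle",
    "make_specimen_set",
    "build_shoulder",
    "grid_for_spindle",
    "grid_for_shoulder",
    "phantom_spec_for_subject",
    "sample_cohort",
]

#: default voxel spacing in mm: 1.0 in-plane, 3.3 along the paracoronal
#: slice-stack axis y (3 mm slice thickness + 0.3 mm interslice gap).
DEFAULT_SPACING_MM = (1.0, 3.3, 1.0)

#: tendon thickness used to convert Ellman tear depth to a fraction of the
#: tendon diameter (depth 6 mm == half the tendon).
TENDON_THICKNESS_MM = 12.0


def taper_integral(shape_exponent: float) -> float:
    """Exact value of ``integral_{-1}^{1} (1 - u^2)^(2p) du``.

    Equals ``sqrt(pi) * Gamma(2p + 1) / Gamma(2p + 3/2)``; 16/15 for p = 1.
    """
    q = 2.0 * shape_exponent
    return math.sqrt(math.pi) * _gamma(q + 1.0) / _gamma(q + 1.5)


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: shape (voxel counts) and per-axis spacing in mm."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three counts >= 1, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"grid spacing must be three positive mm values, got {self.spacing_mm}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        s = self.spacing_mm[axis]
        return (np.arange(self.shape[axis]) + 0.5) * s

    def center_mm(self) -> tuple[float, float, float]:
        return tuple(e / 2.0 for e in self.extent_mm)


@dataclass(frozen=True)
class SpindleSpec:
    """Spindle-shaped belly: solid of revolution r(x) = R (1-(2x/L)^2)^p."""

    length_mm: float
    max_radius_mm: float
    shape_exponent: float = 1.0
    target_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.max_radius_mm <= 0:
            raise ValueError(
                f"spindle length and radius must be positive, got "
                f"L={self.length_mm}, R={self.max_radius_mm}"
            )
        if self.shape_exponent <= 0:
            raise ValueError(f"shape exponent must be positive, got {self.shape_exponent}")
        if self.target_volume_cm3 is not None:
            v = self.analytic_volume_cm3
            if not math.isclose(v, self.target_volume_cm3, rel_tol=1e-6):
                raise ValueError(
                    f"spindle dimensions give {v:.6f} cm^3, inconsistent with "
                    f"target {self.target_volume_cm3} cm^3"
                )

    @property
    def analytic_volume_cm3(self) -> float:
        """Closed-form volume of the solid of revolution, in cm^3."""
        v_mm3 = (
            math.pi
            * self.max_radius_mm**2
            * (self.length_mm / 2.0)
            * taper_integral(self.shape_exponent)
        )
        return v_mm3 / 1000.0

    @classmethod
    def from_volume(
        cls,
        volume_cm3: float,
        aspect_ratio: float = 2.5,
        shape_exponent: float = 1.0,
    ) -> "SpindleSpec":
        """Build a spindle of exact volume at a given elongation.

        ``aspect_ratio`` is length / diameter = L / (2R). With
        V = pi R^2 (L/2) J and L = 2 a R this gives R = (V / (pi a J))^(1/3).
        """
        if volume_cm3 <= 0:
            raise ValueError(f"volume must be positive, got {volume_cm3}")
        if aspect_ratio <= 0:
            raise ValueError(f"aspect ratio must be positive, got {aspect_ratio}")
        j = taper_integral(shape_exponent)
        r = (volume_cm3 * 1000.0 / (math.pi * aspect_ratio * j)) ** (1.0 / 3.0)
        return cls(
            length_mm=2.0 * aspect_ratio * r,
            max_radius_mm=r,
            shape_exponent=shape_exponent,
            target_volume_cm3=volume_cm3,
        )

    def radius_at(self, x_mm: np.ndarray | float) -> np.ndarray:
        """Radius profile r(x), zero outside the support [-L/2, L/2]."""
        x = np.asarray(x_mm, dtype=float)
        u2 = np.clip((2.0 * x / self.length_mm) ** 2, 0.0, 1.0)
        r = self.max_radius_mm * (1.0 - u2) ** self.shape_exponent
        return np.where(np.abs(x) <= self.length_mm / 2.0, r, 0.0)


def _voxelize_profile(
    grid: GridSpec,
    radius_of_x: np.ndarray,
    center_yz: tuple[float, float],
) -> np.ndarray:
    """Binary mask of a solid of revolution from its per-column radius.

    A voxel belongs to the solid iff its center lies inside the continuous
    surface (center-inside rule).
    """
    yy = grid.centers(1) - center_yz[0]
    zz = grid.centers(2) - center_yz[1]
    d2 = yy[:, None] ** 2 + zz[None, :] ** 2
    r = np.asarray(radius_of_x, dtype=float)
    return (d2[None, :, :] <= (r**2)[:, None, None]) & (r > 0)[:, None, None]


def _check_fits(grid: GridSpec, center: tuple[float, float, float], half_extents: tuple[float, float, float], what: str) -> None:
    ext = grid.extent_mm
    for ax in range(3):
        lo = center[ax] - half_extents[ax]
        hi = center[ax] + half_extents[ax]
        if lo < 0.0 or hi > ext[ax]:
            raise DimensionError(
                f"{what} spans [{lo:.1f}, {hi:.1f}] mm on axis {ax} but the grid "
                f"extent is [0, {ext[ax]:.1f}] mm"
            )


def make_spindle(
    spec: SpindleSpec,
    grid: GridSpec,
    seed: int | None = None,
    center_mm: tuple[float, float, float] | None = None,
) -> VoxelMask:
    """Voxelize a spindle belly; the analytic volume is attached as metadata.

    If ``seed`` is given (and no explicit center), the spindle center is
    jittered uniformly within +-half a voxel per axis, emulating arbitrary
    sub-voxel positioning of a physical specimen in the scanner.
    """
    if center_mm is None:
        center = list(grid.center_mm())
        if seed is not None:
            rng = np.random.default_rng(seed)
            for ax in range(3):
                center[ax] += float(rng.uniform(-0.5, 0.5) * grid.spacing_mm[ax])
        center_mm = tuple(center)
    _check_fits(
        grid,
        center_mm,
        (spec.length_mm / 2.0, spec.max_radius_mm, spec.max_radius_mm),
        "spindle",
    )
    xs = grid.centers(0) - center_mm[0]
    data = _voxelize_profile(grid, spec.radius_at(xs), (center_mm[1], center_mm[2]))
    return VoxelMask(
        data,
        grid.spacing_mm,
        meta={
            "analytic_volume_cm3": spec.analytic_volume_cm3,
            "spindle": {
                "length_mm": spec.length_mm,
                "max_radius_mm": spec.max_radius_mm,
                "shape_exponent": spec.shape_exponent,
            },
            "center_mm": tuple(center_mm),
        },
    )


def grid_for_spindle(
    spec: SpindleSpec,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    pad_voxels: int = 2,
) -> GridSpec:
    """Smallest grid (plus padding) that accommodates the spindle."""
    half = (spec.length_mm / 2.0, spec.max_radius_mm, spec.max_radius_mm)
    shape = tuple(
        int(math.ceil(2.0 * h / s)) + 2 * pad_voxels for h, s in zip(half, spacing_mm)
    )
    return GridSpec(shape=shape, spacing_mm=spacing_mm)


def make_specimen_set(
    volumes_cm3: Sequence[float],
    grid: GridSpec | None = None,
    aspect_ratio: float = 2.5,
    shape_exponent: float = 1.0,
    seed: int | None = None,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
) -> list[VoxelMask]:
    """One spindle phantom per requested volume, analytic truth recorded.

    With ``grid=None`` each specimen gets its own snug grid at ``spacing_mm``.
    """
    for v in volumes_cm3:
        if v <= 0:
            raise ValueError(f"specimen volumes must be positive, got {v}")
    masks = []
    ss = np.random.SeedSequence(seed).spawn(len(volumes_cm3)) if seed is not None else None
    for i, v in enumerate(volumes_cm3):
        spec = SpindleSpec.from_volume(v, aspect_ratio=aspect_ratio, shape_exponent=shape_exponent)
        g = grid if grid is not None else grid_for_spindle(spec, spacing_mm)
        sub_seed = int(ss[i].generate_state(1)[0] % (2**31)) if ss is not None else None
        masks.append(make_spindle(spec, g, seed=sub_seed))
    return masks


@dataclass(frozen=True)
class ShoulderPhantomSpec:
    """A belly inside a static fossa envelope.

    ``muscle`` is the reference (pre-atrophy) belly that defines the fossa;
    the actual belly has its radius scaled by ``atrophy_factor`` (<= 1), so
    its volume is ``atrophy_factor^2`` times the reference volume. The fossa
    is the reference belly swept medially by ``fossa_medial_sweep_mm`` (the
    fossa continues medially past the belly) and padded radially by
    ``fossa_margin_mm``. ``retraction_mm`` translates the belly medially,
    rigidly, quantized to whole voxels; the fossa does not move.
    ``yview_offset_mm`` places the measurement plane that many mm medial to
    the lateral fossa edge; ``None`` defers to :func:`default_yview_offset`.
    """

    muscle: SpindleSpec
    fossa_margin_mm: float = 2.0
    fossa_medial_sweep_mm: float = 30.0
    yview_offset_mm: float | None = None
    retraction_mm: float = 0.0
    atrophy_factor: float = 1.0
    tendon_defect: TearSpec | None = None

    def __post_init__(self) -> None:
        if self.fossa_margin_mm <= 0:
            raise ValueError("fossa margin must be positive")
        if self.fossa_medial_sweep_mm < 0:
            raise ValueError("fossa medial sweep must be >= 0")
        if self.retraction_mm < 0:
            raise ValueError("retraction must be >= 0")
        if self.retraction_mm > self.fossa_medial_sweep_mm:
            raise ValueError(
                f"retraction {self.retraction_mm} mm exceeds the fossa medial sweep "
                f"{self.fossa_medial_sweep_mm} mm; the belly would leave the fossa"
            )
        if not 0.0 < self.atrophy_factor <= 1.0:
            raise ValueError(f"atrophy factor must be in (0, 1], got {self.atrophy_factor}")

    @property
    def muscle_volume_cm3(self) -> float:
        """Analytic belly volume after radial atrophy scaling."""
        return self.atrophy_factor**2 * self.muscle.analytic_volume_cm3


#: Y-view plane position as a fraction of the half-length lateral of the
#: belly center. Chosen so that a healthy belly occupies ~72 % of the fossa
#: cross-section on the measurement plane (the normal-range regime).
DEFAULT_YVIEW_FRACTION = 0.12


def default_yview_offset(spec: ShoulderPhantomSpec, fraction: float = DEFAULT_YVIEW_FRACTION) -> float:
    """Offset (mm, medial from the lateral fossa edge) placing the plane at
    ``fraction`` of the half-length lateral of the belly center."""
    half = spec.muscle.length_mm / 2.0
    return spec.fossa_margin_mm + (1.0 - fraction) * half


def grid_for_shoulder(
    spec: ShoulderPhantomSpec,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    pad_voxels: int = 2,
) -> GridSpec:
    """Snug grid holding the fossa (belly + margin + medial sweep)."""
    half_x = spec.muscle.length_mm / 2.0 + spec.fossa_margin_mm + spec.fossa_medial_sweep_mm / 2.0
    half_r = spec.muscle.max_radius_mm + spec.fossa_margin_mm
    shape = tuple(
        int(math.ceil(2.0 * h / s)) + 2 * pad_voxels
        for h, s in zip((half_x, half_r, half_r), spacing_mm)
    )
    return GridSpec(shape=shape, spacing_mm=spacing_mm)


def build_shoulder(
    spec: ShoulderPhantomSpec,
    grid: GridSpec | None = None,
) -> tuple[VoxelMask, VoxelMask]:
    """Voxelize (muscle, fossa) for one subject.

    The fossa envelope is analytic: its radius profile is the medially swept
    reference-belly profile plus the radial margin, so the belly stays inside
    the fossa for any retraction up to the medial sweep. Retraction is applied
    to the belly as an integer-voxel medial shift, conserving its voxel count
    exactly.
    """
    ref = spec.muscle
    if grid is None:
        grid = grid_for_shoulder(spec)
    dx = grid.spacing_mm[0]
    sweep = spec.fossa_medial_sweep_mm
    margin = spec.fossa_margin_mm

    # place the belly so the fossa (incl. medial sweep) fits the grid
    cx = margin + sweep + ref.length_mm / 2.0 + 2 * dx
    cy, cz = grid.extent_mm[1] / 2.0, grid.extent_mm[2] / 2.0
    _check_fits(
        grid,
        (cx - sweep / 2.0, cy, cz),
        (
            ref.length_mm / 2.0 + margin + sweep / 2.0,
            ref.max_radius_mm + margin,
            ref.max_radius_mm + margin,
        ),
        "fossa",
    )

    xs = grid.centers(0) - cx

    # fossa: swept reference profile + margin; flat caps of radius `margin`
    # extend the support by `margin` at both ends
    swept = np.where(
        xs >= 0.0,
        ref.radius_at(xs),
        np.where(xs >= -sweep, ref.max_radius_mm, ref.radius_at(xs + sweep)),
    )
    support = (xs >= -(ref.length_mm / 2.0 + sweep + margin)) & (xs <= ref.length_mm / 2.0 + margin)
    fossa_r = np.where(support, swept + margin, 0.0)
    fossa = VoxelMask(
        _voxelize_profile(grid, fossa_r, (cy, cz)),
        grid.spacing_mm,
        meta={"center_mm": (cx, cy, cz), "margin_mm": margin, "medial_sweep_mm": sweep},
    )

    # belly: atrophied reference, optional tendon defect, then rigid medial shift
    muscle_r = spec.atrophy_factor * ref.radius_at(xs)
    data = _voxelize_profile(grid, muscle_r, (cy, cz))
    if spec.tendon_defect is not None and spec.tendon_defect.kind == "partial":
        data = _apply_partial_defect(data, grid, xs, muscle_r, cz, spec)

    n_shift = int(round(spec.retraction_mm / dx))
    if n_shift > 0:
        fg_x = np.flatnonzero(data.any(axis=(1, 2)))
        if fg_x.size and fg_x[0] < n_shift:
            raise DimensionError(
                f"retraction of {n_shift} voxels pushes the belly outside the grid"
            )
        shifted = np.zeros_like(data)
        shifted[: data.shape[0] - n_shift] = data[n_shift:]
        data = shifted

    muscle = VoxelMask(
        data,
        grid.spacing_mm,
        meta={
            "analytic_volume_cm3": spec.muscle_volume_cm3,
            "atrophy_factor": spec.atrophy_factor,
            "retraction_mm": n_shift * dx,
            "center_mm": (cx - n_shift * dx, cy, cz),
        },
    )
    if not muscle.is_subset_of(fossa):
        raise DimensionError("belly voxels fall outside the fossa envelope")
    return muscle, fossa


def _apply_partial_defect(
    data: np.ndarray,
    grid: GridSpec,
    xs: np.ndarray,
    muscle_r: np.ndarray,
    cz: float,
    spec: ShoulderPhantomSpec,
) -> np.ndarray:
    """Carve a bursal-surface (superior) wedge into the lateral 10 % of the belly.

    Partial tears only notch the tendon end; the belly is neither moved nor
    rescaled, so single-slice measurements medial of the notch are unaffected.
    """
    tear = spec.tendon_defect
    if tear.partial_fraction is not None:
        frac = tear.partial_fraction
    elif tear.partial_depth_mm is not None:
        frac = min(1.0, tear.partial_depth_mm / TENDON_THICKNESS_MM)
    else:
        return data
    zone = xs > spec.muscle.length_mm / 2.0 * 0.8  # lateral 10 % of total length
    if not zone.any() or frac <= 0:
        return data
    zz = grid.centers(2) - cz
    keep_above = (1.0 - frac) * muscle_r  # remove voxels superior of this height
    cut = zone[:, None, None] & (zz[None, None, :] > keep_above[:, None, None])
    return data & ~cut


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------

GROUPS = ("intact", "partial", "full")

#: group mean belly volumes (cm^3) the cohort emulates
GROUP_MEAN_VOLUME_CM3 = {"intact": 56.9, "partial": 43.6, "full": 31.1}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions for a synthetic study cohort.

    Defaults emulate the clinical cohort structure: 39 intact / 75 partial /
    35 full-thickness subjects; Ellman grade counts 45/19/11 among partial
    tears and Patte grade counts 19/10/6 among full-thickness tears. Belly
    size varies log-normally across subjects; atrophy (muscle volume as a
    fraction of the subject's healthy belly volume) follows a Beta law whose
    group means reproduce the group mean volumes 56.9/43.6/31.1 cm^3.
    """

    n_intact: int = 39
    n_partial: int = 75
    n_full: int = 35
    seed: int | None = None

    healthy_volume_mean_cm3: float = 65.0
    healthy_volume_sigma_log: float = 0.04
    atrophy_concentration: float = 15.0
    aspect_ratio: float = 2.5
    shape_exponent: float = 1.0

    ellman_grade_counts: tuple[int, int, int] = (45, 19, 11)
    #: Ellman depth ranges (mm) per grade: <3, 3-6, >6
    ellman_depth_ranges_mm: tuple[tuple[float, float], ...] = ((1.0, 2.9), (3.0, 6.0), (6.1, 9.0))
    patte_grade_counts: tuple[int, int, int] = (19, 10, 6)
    #: medial retraction ranges (mm) per Patte grade (stump near insertion /
    #: humeral dome / glenoid or beyond)
    retraction_ranges_mm: tuple[tuple[float, float], ...] = ((1.0, 6.0), (8.0, 18.0), (18.0, 34.0))

    fossa_margin_mm: float = 2.0
    fossa_medial_sweep_mm: float = 36.0
    yview_fraction: float = DEFAULT_YVIEW_FRACTION
    yview_fraction_jitter: float = 0.02

    def __post_init__(self) -> None:
        for name in ("n_intact", "n_partial", "n_full"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_partial and sum(self.ellman_grade_counts) != self.n_partial:
            raise ValueError(
                f"Ellman grade counts {self.ellman_grade_counts} do not sum to "
                f"n_partial={self.n_partial}"
            )
        if self.n_full and sum(self.patte_grade_counts) != self.n_full:
            raise ValueError(
                f"Patte grade counts {self.patte_grade_counts} do not sum to "
                f"n_full={self.n_full}"
            )
        if not 0 < self.yview_fraction < 1:
            raise ValueError("yview fraction must be in (0, 1)")
        for lo, hi in self.retraction_ranges_mm:
            if not 0 <= lo <= hi:
                raise ValueError("retraction ranges must be ordered and non-negative")

    def atrophy_mean(self, group: str) -> float:
        return GROUP_MEAN_VOLUME_CM3[group] / self.healthy_volume_mean_cm3


def sample_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort; reproducible given the seed.

    Returns one row per subject with group label, tear grades, sampled belly
    geometry, atrophy and retraction. ``seed`` overrides ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows: list[dict] = []
    counts = {"intact": spec.n_intact, "partial": spec.n_partial, "full": spec.n_full}

    ellman_grades = np.repeat([1, 2, 3], spec.ellman_grade_counts)
    rng.shuffle(ellman_grades)
    patte_grades = np.repeat([1, 2, 3], spec.patte_grade_counts)
    rng.shuffle(patte_grades)
    stump_by_grade = {g + 1: pos for g, pos in enumerate(STUMP_POSITIONS)}

    i_partial = i_full = 0
    sid = 0
    mu_log = math.log(spec.healthy_volume_mean_cm3) - spec.healthy_volume_sigma_log**2 / 2.0
    for group in GROUPS:
        mu = spec.atrophy_mean(group)
        nu = spec.atrophy_concentration
        for _ in range(counts[group]):
            sid += 1
            healthy = float(rng.lognormal(mu_log, spec.healthy_volume_sigma_log))
            atrophy = float(rng.beta(mu * nu, (1.0 - mu) * nu))
            row = {
                "subject": f"S{sid:03d}",
                "group": group,
                "healthy_volume_cm3": healthy,
                "atrophy_fraction": atrophy,
                "target_volume_cm3": atrophy * healthy,
                "yview_fraction": float(
                    rng.uniform(
                        spec.yview_fraction - spec.yview_fraction_jitter,
                        spec.yview_fraction + spec.yview_fraction_jitter,
                    )
                ),
                "ellman_grade": 0,
                "ellman_depth_mm": float("nan"),
                "patte_grade": 0,
                "stump_position": "",
                "retraction_mm": 0.0,
            }
            if group == "partial":
                g = int(ellman_grades[i_partial])
                i_partial += 1
                lo, hi = spec.ellman_depth_ranges_mm[g - 1]
                row["ellman_grade"] = g
                row["ellman_depth_mm"] = float(rng.uniform(lo, hi))
            elif group == "full":
                g = int(patte_grades[i_full])
                i_full += 1
                lo, hi = spec.retraction_ranges_mm[g - 1]
                row["patte_grade"] = g
                row["stump_position"] = stump_by_grade[g]
                row["retraction_mm"] = float(rng.uniform(lo, hi))
            rows.append(row)
    return pd.DataFrame(rows)


def phantom_spec_for_subject(row: pd.Series | dict, cohort: CohortSpec) -> ShoulderPhantomSpec:
    """Shoulder phantom parameters for one cohort-table row.

    The subject's healthy belly defines the fossa; atrophy enters as a radial
    scale ``sqrt(atrophy_fraction)`` so the belly volume is ``atrophy_fraction``
    times the healthy volume. The Y-view offset scales with the subject's
    belly length (bigger shoulders have proportionally bigger scapulae).
    """
    ref = SpindleSpec.from_volume(
        row["healthy_volume_cm3"],
        aspect_ratio=cohort.aspect_ratio,
        shape_exponent=cohort.shape_exponent,
    )
    tear = None
    if row["group"] == "partial":
        tear = TearSpec(kind="partial", partial_depth_mm=float(row["ellman_depth_mm"]))
    elif row["group"] == "full":
        tear = TearSpec(kind="full", stump_position=str(row["stump_position"]))
    offset = cohort.fossa_margin_mm + (1.0 - float(row["yview_fraction"])) * ref.length_mm / 2.0
    return ShoulderPhantomSpec(
        muscle=ref,
        fossa_margin_mm=cohort.fossa_margin_mm,
        fossa_medial_sweep_mm=cohort.fossa_medial_sweep_mm,
        yview_offset_mm=offset,
        retraction_mm=float(row["retraction_mm"]),
        atrophy_factor=math.sqrt(float(row["atrophy_fraction"])),
        tendon_defect=tear,
    )
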