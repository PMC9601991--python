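"""Published reference measurements packaged as plain-data fixtures.

These are the printed results of the clinical validation study of MR-based
supraspinatus volumetry that this pipeline models: the ex vivo water
displacement vs software volumetry series, the cohort composition, the
group-level volume and occupation-ratio summaries, and the single-slice
surface ratio entering the overestimation arithmetic. They are inputs to
the reporting/verification stage, not outputs of this package.
"""

from __future__ import annotations

#: ex vivo series: (specimen, water displacement mL, software volumetry mL)
EXVIVO_SERIES: tuple[tuple[int, float, float], ...] = (
    (1, 10.0, 9.97),
    (2, 20.0, 19.48),
    (3, 30.0, 30.29),
    (4, 40.0, 39.68),
    (5, 50.0, 49.81),
    (6, 60.0, 61.62),
    (7, 70.0, 69.25),
    (8, 80.0, 80.34),
    (9, 90.0, 89.71),
    (10, 100.0, 99.88),
)

WATER_DISPLACEMENT_ML: tuple[float, ...] = tuple(r[1] for r in EXVIVO_SERIES)
SOFTWARE_VOLUMETRY_ML: tuple[float, ...] = tuple(r[2] for r in EXVIVO_SERIES)

#: cohort composition: subjects per tendon-status group
GROUP_COUNTS: dict[str, int] = {"intact": 39, "partial": 75, "full": 35}
N_SUBJECTS: int = 149

#: Ellman grade counts among partial tears (grades I, II, III)
ELLMAN_COUNTS: tuple[int, int, int] = (45, 19, 11)
#: Patte grade counts among full-thickness tears (grades 1, 2, 3)
PATTE_COUNTS: tuple[int, int, int] = (19, 10, 6)

#: group mean 3D muscle volumes (cm^3)
GROUP_MEAN_VOLUME_CM3: dict[str, float] = {"intact": 56.9, "partial": 43.6, "full": 31.1}

#: group mean occupation ratios with observed ranges
GROUP_OR: dict[str, dict] = {
    "intact": {"mean": 0.72, "range": (0.49, 0.89), "stage_counts": (34, 5, 0)},
    "partial": {"mean": 0.54, "range": (0.26, 0.79), "stage_counts": (31, 38, 6)},
    "full": {"mean": 0.40, "range": (0.11, 0.71), "stage_counts": (1, 16, 18)},
}

#: Y-view muscle surface of full-thickness tears relative to intact tendons
FULL_VS_INTACT_SURFACE_RATIO: float = 0.472

#: reported correlations
REPORTED_EXVIVO_PEARSON_R: float = 0.95
REPORTED_INTERREADER_R: float = 0.92
REPORTED_OR_VOLUME_R: dict[str, float] = {"intact": 0.84, "partial": 0.93, "full": 0.68}
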