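"""Cohort statistics: correlations, group comparisons, reader simulation,
and the atrophy-overestimation statistic.

The overestimation statistic compares two group-level ratios between the
full-thickness-tear and intact groups: the relative 3D muscle volume
rv = mean(V_full) / mean(V_intact) and the relative single-slice (Y-view)
muscle surface rs = mean(S_full) / mean(S_intact). When the belly retracts
medially, the fixed Y-view samples a thinner part of the muscle, so rs drops
below rv; the normalized excess (rv - rs) / rv is the fraction by which the
single-slice method overstates atrophy relative to true volumetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .occupation import thomazeau_stage
from .utils import round_half_up

__all__ = [
    "OverestimationResult",
    "AnovaResult",
    "ReaderSimulation",
    "pearson",
    "anova_bonferroni",
    "simulate_readers",
    "overestimation",
    "overestimation_from_ratios",
    "summarize_groups",
]


@dataclass(frozen=True)
class OverestimationResult:
    """Group-level volume vs single-slice surface ratios (full vs intact)."""

    rv: float  # relative volume: mean V_full / mean V_intact
    rs: float  # relative Y-view surface: mean S_full / mean S_intact
    diff: float  # rv - rs
    normalized: float  # (rv - rs) / rv

    def report(self) -> dict[str, float]:
        """Percent figures rounded stage-by-stage as a printed report rounds.

        Each ratio is first rounded half-up to one decimal percent; the
        normalized excess is then computed from the rounded percentages
        (e.g. 54.7 - 47.2 = 7.5; 7.5 / 54.7 = 13.7 %). Full-precision values
        stay on the dataclass fields.
        """
        rv_pct = round_half_up(100.0 * self.rv, 1)
        rs_pct = round_half_up(100.0 * self.rs, 1)
        diff_pct = round_half_up(rv_pct - rs_pct, 1)
        norm_pct = round_half_up(100.0 * diff_pct / rv_pct, 1)
        return {
            "rv_pct": rv_pct,
            "rs_pct": rs_pct,
            "diff_pct": diff_pct,
            "normalized_pct": norm_pct,
        }


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise_p_adjusted: dict[tuple[int, int], float]


@dataclass(frozen=True)
class ReaderSimulation:
    reader_a: np.ndarray
    reader_b: np.ndarray
    pearson_r: float


def pearson(x, y) -> float:
    """Pearson correlation coefficient of two equally long vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"expected two equally long 1D vectors, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: one of the vectors has zero variance")
    return float(_stats.pearsonr(x, y).statistic)


def anova_bonferroni(groups: list) -> AnovaResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise post hoc t tests.

    Pairwise p values are multiplied by the number of comparisons and capped
    at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    f, p = _stats.f_oneway(*arrays)
    pairs = list(combinations(range(len(arrays)), 2))
    pairwise: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        t = _stats.ttest_ind(arrays[i], arrays[j])
        pairwise[(i, j)] = min(1.0, float(t.pvalue) * len(pairs))
    return AnovaResult(float(f), float(p), pairwise)


def simulate_readers(
    values, noise_sigma: float = 0.05, seed: int | None = None
) -> ReaderSimulation:
    """Two independent readers as multiplicative log-normal perturbations.

    Each reader's measurement is value * exp(N(0, sigma)); the inter-reader
    Pearson r of the two perturbed series is reported. sigma = 0 reproduces
    the input exactly (r = 1).
    """
    if noise_sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {noise_sigma}")
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    a = v * np.exp(rng.normal(0.0, noise_sigma, size=v.shape))
    b = v * np.exp(rng.normal(0.0, noise_sigma, size=v.shape))
    r = 1.0 if noise_sigma == 0 else pearson(a, b)
    return ReaderSimulation(a, b, r)


def overestimation(
    mean_v_intact: float,
    mean_v_full: float,
    mean_s_intact: float,
    mean_s_full: float,
) -> OverestimationResult:
    """Overestimation of atrophy by the single-slice method, from group means."""
    if mean_v_intact <= 0 or mean_s_intact <= 0:
        raise ZeroDivisionError(
            "intact-group means must be positive to form full/intact ratios"
        )
    return overestimation_from_ratios(
        rv=mean_v_full / mean_v_intact, rs=mean_s_full / mean_s_intact
    )


def overestimation_from_ratios(rv: float, rs: float) -> OverestimationResult:
    """Same statistic when the full/intact ratios are already known."""
    if rv <= 0:
        raise ZeroDivisionError(f"relative volume ratio must be positive, got {rv}")
    diff = rv - rs
    return OverestimationResult(rv=rv, rs=rs, diff=diff, normalized=diff / rv)


def summarize_groups(
    cohort: pd.DataFrame,
    group_col: str = "group",
    volume_col: str = "volume_cm3",
    or_col: str = "or_value",
    group_order: tuple[str, ...] = ("intact", "partial", "full"),
) -> pd.DataFrame:
    """Per-group n, percentages, volume/OR means and ranges, stage counts.

    Percentages are rounded half-up to one decimal, as printed reports do.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    unknown = set(cohort[group_col]) - set(group_order)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    total = len(cohort)
    rows = []
    for g in group_order:
        sub = cohort[cohort[group_col] == g]
        if sub.empty:
            continue
        stages = [thomazeau_stage(v) for v in sub[or_col]]
        n = len(sub)
        row = {
            "group": g,
            "n": n,
            "pct": round_half_up(100.0 * n / total, 1),
            "volume_mean_cm3": float(sub[volume_col].mean()),
            "volume_min_cm3": float(sub[volume_col].min()),
            "volume_max_cm3": float(sub[volume_col].max()),
            "or_mean": float(sub[or_col].mean()),
            "or_min": float(sub[or_col].min()),
            "or_max": float(sub[or_col].max()),
        }
        for st in ("I", "II", "III"):
            k = stages.count(st)
            row[f"stage_{st}_n"] = k
            row[f"stage_{st}_pct"] = round_half_up(100.0 * k / n, 1)
        rows.append(row)
    return pd.DataFrame(rows)
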