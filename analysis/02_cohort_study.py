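"""Synthetic cohort comparison: Y-view occupation ratio vs 3D volumetry.

Samples a 149-subject cohort (39 intact / 75 partial / 35 full-thickness),
builds one shoulder phantom per subject, measures the 3D muscle volume and
the Y-view occupation ratio, and reports group summaries, per-group
OR-volume correlations, a simulated inter-reader reliability, and the
overestimation statistic driven by the medial retraction of the belly in
full-thickness tears.
"""

import argparse
from pathlib import Path

from orbias.experiments import RunConfig, run_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    result = run_cohort(RunConfig(experiment="cohort", seed=args.seed))
    result.write(args.out)

    print(result.group_summary.round(3).to_string(index=False))
    r = result.or_volume_r
    print(
        f"\nOR-volume Pearson r: intact {r['intact']:.2f}, partial {r['partial']:.2f}, "
        f"full-thickness {r['full']:.2f}"
    )
    rep = result.overestimation.report()
    print(
        f"Relative volume (full/intact) {rep['rv_pct']} % vs relative Y-view surface "
        f"{rep['rs_pct']} %: the single-slice method overstates atrophy by "
        f"{rep['diff_pct']} points, i.e. {rep['normalized_pct']} % of the volume ratio."
    )
    print(f"Simulated inter-reader reliability r = {result.interreader_r:.2f}")
    print(
        f"ANOVA on group volumes: F = {result.anova.f_statistic:.1f}, "
        f"p = {result.anova.p_value:.2e}"
    )
    print(f"wrote {args.out}/cohort_subjects.csv, cohort_group_summary.csv, cohort_stats.json")


if __name__ == "__main__":
    main()
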