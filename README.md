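# orbias

Voxel-phantom analysis of how the single-slice **occupation ratio (OR)**
overstates supraspinatus (SSP) muscle atrophy relative to true 3D MR
volumetry when the myotendinous unit retracts medially after a
full-thickness tendon tear.

## The problem

Clinical MRI protocols usually estimate SSP atrophy from one oblique-sagittal
slice, the *Y-view*, as the occupation ratio

```
OR = A_muscle / A_fossa
```

(cross-sectional muscle area over supraspinatus fossa area), staged after
Thomazeau: I (OR ≥ 0.60), II (0.40 ≤ OR < 0.60), III (OR < 0.40). True 3D
volumetry instead integrates the traced muscle areas slice by slice
(slab-stack / Cavalieri, with 3 mm slices and a 0.3 mm interslice gap):

```
V = Σᵢ Aᵢ · (t + g),   t = 3 mm, g = 0.3 mm
```

After a full-thickness tear the whole muscle belly translates medially
(Patte grades 1–3), so the fixed lateral Y-view samples a thinner part of
the muscle: the OR falls even though the volume barely changes. The
group-level bias is quantified as

```
rv = mean(V_full) / mean(V_intact)        (relative 3D volume)
rs = mean(S_full) / mean(S_intact)        (relative Y-view muscle surface)
overestimation = (rv − rs) / rv
```

This package reproduces that analysis end to end on synthetic voxel
phantoms: spindle-shaped muscle bellies (solids of revolution with exactly
known volume), a static fossa envelope, parametrized atrophy and retraction,
a sampled 149-subject cohort (39 intact / 75 partial / 35 full-thickness),
per-slice geometry measurements (area, maximum Feret long axis,
perpendicular short axis, cross-products), Ellman/Patte/Thomazeau staging,
and the statistics stage (Pearson correlations, one-way ANOVA with
Bonferroni post hoc, simulated inter-reader reliability, overestimation).

It is aimed at readers who want to probe the retraction-bias mechanism under
controlled geometric conditions, or reuse the measurement primitives
(gap-aware volumetry, caliper axes, OR staging) on their own masks.

## Worked example

```python
from orbias import overestimation

# published group means: intact 56.9 cm^3, full-thickness 31.1 cm^3,
# relative Y-view muscle surface 47.2 %
res = overestimation(mean_v_intact=56.9, mean_v_full=31.1,
                     mean_s_intact=1.0, mean_s_full=0.472)
print(res.report())
```

prints

```
{'rv_pct': 54.7, 'rs_pct': 47.2, 'diff_pct': 7.5, 'normalized_pct': 13.7}
```

i.e. the full-thickness group keeps 54.7 % of the intact volume but only
47.2 % of the intact Y-view surface; the single-slice method therefore
overstates atrophy by 7.5 points, 13.7 % of the volume ratio.

The two experiment drivers (also exposed as `orbias exvivo` / `orbias
cohort` on the command line):

```sh
python analysis/01_exvivo_validation.py --seed 1   # phantom accuracy of slab-stack volumetry
python analysis/02_cohort_study.py     --seed 1    # cohort comparison incl. overestimation
python analysis/03_reference_arithmetic.py         # arithmetic on the packaged reference tables
```

With seed 1 the ex vivo run recovers all ten analytic volumes (10–100 cm³)
within 0.47 % (Pearson r = 1.0000), and the cohort run prints OR–volume
correlations of 0.94 (intact), 0.96 (partial) and 0.62 (full-thickness) with
a simulated overestimation of 21.2 % — the full-thickness decoupling pattern
the retraction mechanism predicts. Tables land in `results/`.

A thin CLI covers the individual stages as well
(`orbias phantom | volume | or | stage | report | exvivo | cohort`); masks
travel as NIfTI, tables as CSV, summaries as JSON, configuration as YAML
(see `configs/`).

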