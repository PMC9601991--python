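# Methods

## Geometric model

### Muscle belly

The belly is a spindle: a solid of revolution about the medial–lateral axis
x with radius profile

    r(x) = R · (1 − (2x/L)²)^p,   x ∈ [−L/2, L/2],

length `L`, maximum radius `R`, taper exponent `p`. Its volume has the
closed form

    V = π R² (L/2) · J(p),   J(p) = ∫₋₁¹ (1−u²)^{2p} du = √π Γ(2p+1)/Γ(2p+3/2),

(J(1) = 16/15), which plays the role that physical water-displacement
volumetry plays for real specimens: an exact, independent ground truth.
Default `p = 1` gives a smooth paraboloid-like taper; the elongation
`aspect_ratio = L/2R` defaults to 2.5, so a 50 cm³ belly is ≈ 91 mm long
with an 18 mm maximal radius — proportions in the range of a human SSP
belly. Both are free parameters of the generator since real specimens are
described only qualitatively as spindle-shaped.

### Voxelization

A voxel belongs to a solid iff its **center** lies inside the continuous
surface. This is the simplest unambiguous rule; its discretization error is
oscillatory in the grid phase, which is why convergence tests average the
error over seeded sub-voxel placements of the phantom (the seed models the
arbitrary position of a specimen in the scanner). The default grid spacing
is 1.0 mm in-plane and 3.3 mm along the paracoronal slice-stack axis y
(3 mm slice thickness + 0.3 mm gap). At that geometry a 10 cm³ spindle is
recovered within ≈ 0.5 %.

### Fossa and retraction

The fossa is a static envelope built from the subject's *reference*
(pre-atrophy) belly: the belly profile swept medially by
`fossa_medial_sweep_mm` (the bony fossa continues medially past the belly;
default 36 mm) and padded radially by `fossa_margin_mm` (default 2 mm),
with flat end caps. Atrophy scales the belly radius by `atrophy_factor = √α`
so that the belly volume is a fraction α of the reference volume while the
fossa — defined by bone — is unchanged; the Y-view OR of a non-retracted
belly is then approximately α · (r_v/(r_v+m))² where r_v is the reference
radius at the view plane and m the margin.

A full-thickness tear retracts the whole myotendinous unit: the belly is
translated medially as a rigid body, quantized to whole voxels along x, so
its voxel count (volume) is conserved *exactly* and any OR change is purely
the sampling effect under study. Partial tears only carve a superior wedge
into the lateral 10 % of the belly; they neither move nor rescale it, which
is deliberate: single-slice ORs should keep tracking volume in partial
tears.

### Y-view

Phantoms have no scapular spine/coracoid/clavicle, so the Y-view is
parametric: a constant-x plane `yview_offset_mm` medial to the most lateral
fossa-containing slice. The default places the plane at 12 % of the
half-length lateral of the belly center (offset ≈ margin + 0.88·L/2),
scaled per subject so bigger shoulders get proportionally more lateral
planes. At that position a healthy belly occupies ≈ 72 % of the fossa
cross-section — the normal-range regime — and the plane is lateral of the
belly apex for every sampled subject, which guarantees the OR is
non-increasing in retraction.

## Cohort generator

Defaults emulate the clinical study population:

| parameter | default | meaning |
|---|---|---|
| group sizes | 39 / 75 / 35 | intact / partial / full-thickness |
| Ellman grade counts | 45 / 19 / 11 | partial tears; depths U(1, 2.9) / U(3, 6) / U(6.1, 9) mm |
| Patte grade counts | 19 / 10 / 6 | full tears; retraction U(1, 6) / U(8, 18) / U(18, 34) mm |
| healthy belly volume | lognormal, mean 65 cm³, σ_log 0.04 | subject size variation |
| atrophy fraction α | Beta, means 0.875 / 0.671 / 0.478, conc. 15 | group mean volumes 56.9 / 43.6 / 31.1 cm³ |
| Y-view fraction | 0.12 ± 0.02 (uniform) | per-subject plane placement |
| reader noise σ | 0.05 (lognormal, multiplicative) | inter-reader simulation |

The atrophy-fraction means are exactly the group mean volumes divided by the
mean healthy volume, so the sampled cohort reproduces the reported group
mean volumes in expectation. The retraction bands map the three Patte
landmarks (stump near insertion / humeral dome / glenoid) onto increasing
medial shifts on a ≈ 100 mm belly. The remaining dispersion parameters
(σ_log, Beta concentration, plane jitter, retraction band widths) were fixed
once, during generator design, by requiring the simulated cohort to sit in
the reported correlation regime — OR–volume Pearson r high in the intact
(≈ 0.90) and partial (≈ 0.96) groups, markedly lower (≈ 0.68 on average)
in the full-thickness group — and were then frozen.

What the generator does *not* emulate: MR signal formation (no T1/T2
contrast, bias field, or partial-volume blur), fatty infiltration,
non-circular fossa cross-sections, anatomic bony landmarks, and real
segmentation variability beyond the multiplicative reader-noise model.
Passing tests therefore demonstrate the geometric sampling mechanism and the
correctness of the measurement pipeline, not clinical performance on real
images.

## Measurements

* **Slice area**: foreground-pixel count × pixel area, matching rasterized
  manual tracing.
* **Long axis**: maximum Feret diameter over the vertices of the
  pixel-corner boundary polygon (computed on the convex hull of the corner
  points; ties in direction broken toward the smallest angle to the
  x-axis). **Short axis**: caliper extent of the whole region perpendicular
  to the long-axis direction (RECIST-style; it need not intersect the
  long-axis segment). A single 1 mm pixel thus measures √2 × √2. On a
  digitized disk the corner convention overshoots the continuous diameter
  by up to ≈ 1.3 pixel — this is a property of the convention, not an
  implementation error, and the cross-product/area ratio still converges to
  4/π within 2 % at fine resolution.
* **Cross-product**: long × short axis, the rectangle bound on the area
  (CP ≥ area for convex slices).
* **Volume**: V = Σ Aᵢ (t+g) over slices perpendicular to the chosen axis,
  default t+g = 3.3 mm. Both t and g are explicit so integration with or
  without the gap can be compared.
* **OR**: traced-area quotient on the Y-view slice; cross-product-based OR
  is emitted as an auxiliary column only. Thomazeau boundaries are
  upper-inclusive (OR = 0.60 → stage I, OR = 0.40 → stage II), consistent
  with "below 0.40" defining stage III.
* **Ellman**: depth < 3 mm → I, 3–6 mm (inclusive) → II, > 6 mm → III; the
  fraction criterion uses 1/4 and 1/2 with exactly one half → II (mirroring
  the inclusive 6 mm boundary); depth wins when both are given.

## Statistics

Pearson correlation and one-way ANOVA delegate to scipy; Bonferroni post hoc
multiplies pairwise t-test p values by the number of comparisons, capped at
1. The overestimation statistic uses group *means* (not per-subject ratios)
because the published arithmetic is group-level. Report percentages round
half-up to one decimal **stage by stage** — rv and rs are rounded first, the
difference and the normalized excess are computed from the rounded values
(54.7 − 47.2 = 7.5; 7.5/54.7 → 13.7 %) — while full-precision values remain
on the result object. Half-up rounding (not banker's) matches printed
clinical tables.

## Problem sizes and determinism

The ex vivo run uses ten phantoms (10–100 cm³) on snug per-specimen grids;
the cohort run builds 149 phantoms on per-subject grids of roughly
190 × 17 × 50 voxels. Both complete in seconds on one CPU, so no
down-scaling is needed anywhere. All randomness (sub-voxel placement,
cohort sampling, reader noise) flows from a single integer seed through
`numpy.random.SeedSequence`; reruns with the same seed produce
byte-identical CSV/JSON outputs.

## Known limitations

* Circular cross-sections make OR collapse faster under large retraction
  than in real anatomy, so the simulated overestimation (≈ 20 %) exceeds
  the clinically reported one; the mechanism and its direction are the
  object of study, not the exact magnitude.
* The fossa moves with the subject's reference belly rather than being an
  independent bony structure; inter-subject fossa variability is therefore
  underestimated.
* The Y-view plane is parametric, not landmark-driven; offsets beyond the
  fossa raise an explicit range error rather than falling back to a
  neighboring slice.
* Ellman depth/fraction criteria can disagree on pathological inputs; depth
  takes precedence by design.
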