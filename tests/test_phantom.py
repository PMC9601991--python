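"""Phantom generator: analytic volumes, voxelization and cohort sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from orbias.errors import DimensionError
from orbias.phantom import (
    CohortSpec,
    GridSpec,
    ShoulderPhantomSpec,
    SpindleSpec,
    build_shoulder,
    grid_for_spindle,
    make_specimen_set,
    make_spindle,
    phantom_spec_for_subject,
    sample_cohort,
)


class TestSpindleSpec:
    def test_closed_form_matches_numerical_integral(self):
        """V = pi R^2 (L/2) J must equal the quadrature of pi r(x)^2 dx."""
        for p in (0.5, 1.0, 2.0):
            spec = SpindleSpec.from_volume(50.0, shape_exponent=p)
            v_quad = (
                quad(
                    lambda x: np.pi * float(spec.radius_at(x)) ** 2,
                    -spec.length_mm / 2,
                    spec.length_mm / 2,
                )[0]
                / 1000.0
            )
            assert spec.analytic_volume_cm3 == pytest.approx(v_quad, rel=1e-9)
            assert spec.analytic_volume_cm3 == pytest.approx(50.0, rel=1e-9)

    @pytest.mark.parametrize("bad", [dict(length_mm=0.0, max_radius_mm=10.0),
                                     dict(length_mm=50.0, max_radius_mm=-1.0),
                                     dict(length_mm=50.0, max_radius_mm=10.0, shape_exponent=0.0)])
    def test_degenerate_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            SpindleSpec(**bad)

    def test_inconsistent_target_volume_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SpindleSpec(length_mm=50.0, max_radius_mm=10.0, target_volume_cm3=99.0)


class TestMakeSpindle:
    def test_voxel_volume_near_analytic_at_1mm(self, spindle50_mask_1mm):
        assert spindle50_mask_1mm.volume_cm3 == pytest.approx(50.0, rel=0.01)
        assert spindle50_mask_1mm.meta["analytic_volume_cm3"] == pytest.approx(50.0)

    def test_volume_scales_linearly(self):
        masks = {
            v: make_spindle(
                SpindleSpec.from_volume(v),
                grid_for_spindle(SpindleSpec.from_volume(v), (1.0, 1.0, 1.0)),
            )
            for v in (10.0, 100.0)
        }
        assert masks[100.0].volume_cm3 / masks[10.0].volume_cm3 == pytest.approx(10.0, rel=0.01)

    def test_spindle_must_fit_grid(self, spindle50):
        small = GridSpec(shape=(20, 20, 20), spacing_mm=(1.0, 1.0, 1.0))
        with pytest.raises(DimensionError):
            make_spindle(spindle50, small)

    @pytest.mark.parametrize("volume", [10.0, 50.0])
    def test_halving_spacing_reduces_error(self, volume):
        """Voxel-count volume converges to the closed form as spacing shrinks.

        The error is averaged over seeded sub-voxel placements because a
        single placement's error oscillates with grid phase.
        """
        spec = SpindleSpec.from_volume(volume)

        def mean_err(h):
            errs = [
                abs(
                    make_spindle(spec, grid_for_spindle(spec, (h, h, h)), seed=s).volume_cm3
                    - volume
                )
                / volume
                for s in range(8)
            ]
            return np.mean(errs)

        assert mean_err(1.5) < mean_err(3.0)
        assert mean_err(0.75) < mean_err(1.5)


class TestSpecimenSet:
    def test_requested_volumes_recorded_as_analytic_truth(self):
        vols = [float(v) for v in range(10, 101, 10)]
        masks = make_specimen_set(vols)
        assert len(masks) == 10
        assert [m.meta["analytic_volume_cm3"] for m in masks] == pytest.approx(vols)

    def test_empty_request(self):
        assert make_specimen_set([]) == []

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            make_specimen_set([50.0, 0.0])

    def test_coarser_grid_has_larger_error(self):
        fine = make_specimen_set([50.0], spacing_mm=(0.5, 0.5, 0.5))[0]
        coarse = make_specimen_set([50.0], spacing_mm=(2.5, 2.5, 2.5))[0]
        assert abs(coarse.volume_cm3 - 50.0) > abs(fine.volume_cm3 - 50.0)


class TestBuildShoulder:
    def test_no_retraction_matches_plain_spindle(self, spindle50):
        spec = ShoulderPhantomSpec(muscle=spindle50)
        muscle, fossa = build_shoulder(spec)
        plain = make_spindle(spindle50, GridSpec(muscle.shape, muscle.spacing_mm),
                             center_mm=muscle.meta["center_mm"])
        assert np.array_equal(muscle.data, plain.data)

    @pytest.mark.parametrize("retraction", [10.0, 20.0])
    def test_retraction_conserves_voxel_volume(self, spindle50, retraction):
        base, _ = build_shoulder(ShoulderPhantomSpec(muscle=spindle50))
        moved, _ = build_shoulder(
            ShoulderPhantomSpec(muscle=spindle50, retraction_mm=retraction)
        )
        assert moved.voxel_count == base.voxel_count
        assert moved.meta["retraction_mm"] == pytest.approx(retraction)

    def test_muscle_inside_fossa(self, spindle50):
        for retraction in (0.0, 12.0, 30.0):
            muscle, fossa = build_shoulder(
                ShoulderPhantomSpec(muscle=spindle50, retraction_mm=retraction,
                                    fossa_medial_sweep_mm=30.0)
            )
            assert muscle.is_subset_of(fossa)

    def test_retraction_beyond_sweep_rejected(self, spindle50):
        with pytest.raises(ValueError, match="sweep"):
            ShoulderPhantomSpec(muscle=spindle50, retraction_mm=50.0,
                                fossa_medial_sweep_mm=30.0)

    def test_atrophy_scales_volume_quadratically(self, spindle50):
        shrunk, _ = build_shoulder(
            ShoulderPhantomSpec(muscle=spindle50, atrophy_factor=0.8)
        )
        assert shrunk.meta["analytic_volume_cm3"] == pytest.approx(0.64 * 50.0)
        assert shrunk.volume_cm3 == pytest.approx(0.64 * 50.0, rel=0.02)

    def test_partial_defect_confined_to_lateral_tenth(self, spindle50):
        from orbias.staging import TearSpec

        intact, _ = build_shoulder(ShoulderPhantomSpec(muscle=spindle50))
        torn, _ = build_shoulder(
            ShoulderPhantomSpec(
                muscle=spindle50,
                tendon_defect=TearSpec(kind="partial", partial_fraction=0.5),
            )
        )
        diff = intact.data != torn.data
        changed_x = np.flatnonzero(diff.any(axis=(1, 2)))
        assert diff.any(), "a 50 % defect must remove some voxels"
        cx = intact.meta["center_mm"][0]
        zone_start = cx + 0.8 * spindle50.length_mm / 2.0
        xs = (changed_x + 0.5) * intact.spacing_mm[0]
        assert (xs > zone_start).all()


class TestSampleCohort:
    def test_default_group_sizes(self):
        table = sample_cohort(CohortSpec(), seed=1)
        assert len(table) == 149
        counts = table["group"].value_counts()
        assert (counts["intact"], counts["partial"], counts["full"]) == (39, 75, 35)

    def test_seeded_sampling_is_reproducible(self, tiny_cohort_spec):
        a = sample_cohort(tiny_cohort_spec, seed=7)
        b = sample_cohort(tiny_cohort_spec, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_intact_subjects_never_retracted(self):
        table = sample_cohort(CohortSpec(), seed=3)
        assert (table.loc[table["group"] != "full", "retraction_mm"] == 0).all()

    def test_no_full_group_means_no_retraction(self):
        spec = CohortSpec(n_intact=5, n_partial=4, n_full=0,
                          ellman_grade_counts=(2, 1, 1), patte_grade_counts=(0, 0, 0))
        table = sample_cohort(spec, seed=2)
        assert (table["retraction_mm"] == 0).all()

    def test_grade_counts_mismatch_rejected(self):
        with pytest.raises(ValueError, match="Patte"):
            CohortSpec(n_full=10, patte_grade_counts=(1, 1, 1))

    def test_subject_phantoms_respect_fossa_containment(self, tiny_cohort_spec):
        table = sample_cohort(tiny_cohort_spec, seed=5)
        for _, row in table.iterrows():
            muscle, fossa = build_shoulder(phantom_spec_for_subject(row, tiny_cohort_spec))
            assert muscle.is_subset_of(fossa)
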