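"""Synthetic phantoms and cohorts: shapes, calibration, determinism."""

import numpy as np
import pytest

from gbmalt import (AcquisitionConfig, CohortConfig, apply_accrual_filters,
                    compute_adc, compute_iauc, compute_iauc_map,
                    detect_arrival, extract_features, flag_signal_loss,
                    generate_cohort, generate_dsc_series, generate_dwi_pair,
                    generate_si_curve, generate_study, normalize_baseline,
                    simulate_reader_mask)
from gbmalt.errors import BoundsError, ConfigurationError, DomainError
from gbmalt.maps import compute_ncbv
from gbmalt.synthetic import artifact_subregion, ellipsoid_mask


class TestSiCurve:
    def test_no_enhancement_is_flat_baseline(self, acq):
        c = generate_si_curve(0.0, acq, noise_sd=0.0, baseline=100.0)
        assert np.allclose(c, 100.0)

    def test_curve_length_matches_acquisition(self, acq):
        assert generate_si_curve(5.0, acq, 0.0).shape == (120,)

    def test_noiseless_iauc_equals_requested_amplitude(self, acq):
        c = generate_si_curve(8.64, acq, noise_sd=0.0)
        norm = normalize_baseline(c, acq.n_baseline)
        arrival = detect_arrival(norm, acq.dt, acq.n_baseline)
        assert compute_iauc(norm, arrival, acq.dt) == pytest.approx(
            8.64, abs=1e-6)

    def test_baseline_expectation(self, acq):
        reps = np.stack([generate_si_curve(6.0, acq, 2.0, seed=s)
                         for s in range(300)])
        base = reps[:, :acq.n_baseline].mean()
        assert base == pytest.approx(100.0, abs=0.5)

    def test_invalid_acquisition_rejected(self):
        with pytest.raises(ConfigurationError):
            AcquisitionConfig(dt=-1.0)
        with pytest.raises(DomainError):
            generate_si_curve(-1.0, AcquisitionConfig(), 0.0)


class TestDwiPair:
    def test_unit_adc_decay(self):
        pair = generate_dwi_pair(np.full((4, 4, 2), 1.0), s0=1000.0, b=1000.0)
        assert pair.sb == pytest.approx(1000.0 / np.e)

    def test_zero_adc_no_decay(self):
        pair = generate_dwi_pair(np.zeros((4, 4, 2)), s0=800.0, b=1000.0)
        assert np.all(pair.sb == 800.0)

    def test_negative_adc_rejected(self):
        with pytest.raises(DomainError):
            generate_dwi_pair(np.full((2, 2, 2), -0.1))


class TestDscSeries:
    def test_no_artifact_no_nil(self, acq):
        region = np.zeros(acq.grid_shape, dtype=bool)
        dsc = generate_dsc_series(acq, "none", region)
        nawm = np.zeros(acq.grid_shape, dtype=bool)
        nawm[:2] = True
        ncbv = compute_ncbv(dsc, nawm)
        lesion = np.zeros(acq.grid_shape, dtype=bool)
        lesion[10:20, 10:20, 2:6] = True
        verdict = flag_signal_loss(ncbv, lesion)
        assert verdict.interpretable and verdict.nil_fraction == 0.0

    def test_half_covered_lesion_nil_fraction(self, acq):
        lesion = ellipsoid_mask(acq.grid_shape, (16, 16, 3.5), (4.5, 4.5, 2.5))
        region = artifact_subregion(lesion, 0.5, "hemorrhage")
        dsc = generate_dsc_series(acq, "hemorrhage", region)
        nawm = np.zeros(acq.grid_shape, dtype=bool)
        nawm[:2] = True
        verdict = flag_signal_loss(compute_ncbv(dsc, nawm), lesion)
        n = lesion.sum()
        assert verdict.nil_fraction == pytest.approx(0.5, abs=1.0 / n + 1e-12)
        assert not verdict.interpretable

    def test_artifact_si_below_nil_threshold_every_dynamic(self, acq):
        lesion = ellipsoid_mask(acq.grid_shape, (16, 16, 3.5), (4.5, 4.5, 2.5))
        region = artifact_subregion(lesion, 1.0, "hemorrhage")
        dsc = generate_dsc_series(acq, "hemorrhage", region, baseline=600.0)
        assert np.all(dsc.si[region] < 0.05 * 600.0)

    def test_bolus_dip_outside_artifact(self, acq):
        region = np.zeros(acq.grid_shape, dtype=bool)
        dsc = generate_dsc_series(acq, "none", region, baseline=600.0)
        curve = dsc.si[5, 5, 2]
        assert curve[:acq.n_baseline_dsc] == pytest.approx(600.0)
        assert curve.min() < 600.0 * 0.9

    def test_region_shape_mismatch_is_bounds_error(self, acq):
        with pytest.raises(BoundsError):
            generate_dsc_series(acq, "hemorrhage", np.zeros((2, 2, 2), bool))


class TestReaderMask:
    def _cube(self):
        m = np.zeros((14, 14, 14), dtype=bool)
        m[2:12, 2:12, 2:12] = True
        return m

    def test_zero_flip_identity(self):
        m = self._cube()
        assert np.array_equal(simulate_reader_mask(m, 0.0, seed=1), m)

    def test_changes_confined_to_boundary(self):
        from scipy import ndimage
        m = self._cube()
        out = simulate_reader_mask(m, 0.3, seed=2)
        interior = ndimage.binary_erosion(m)
        exterior = ~ndimage.binary_dilation(m)
        assert np.array_equal(out & interior, interior)
        assert not (out & exterior).any()

    def test_jaccard_above_08_at_flip_02(self):
        m = self._cube()   # 10^3 voxels
        out = simulate_reader_mask(m, 0.2, seed=3)
        jaccard = (m & out).sum() / (m | out).sum()
        assert jaccard > 0.8

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError):
            simulate_reader_mask(np.zeros((4, 4, 4), bool), 0.1)


class TestCohort:
    def test_default_accrual_counts(self):
        records, _ = generate_cohort(CohortConfig(), seed=5)
        kept, report = apply_accrual_filters(records)
        assert report.n_input == 71
        assert report.n_dsc_uninterpretable_hemorrhage == 54
        assert report.n_dsc_uninterpretable_skull_base == 17
        assert report.n_dwi_interpretable == 51
        assert report.n_dce_interpretable == 59
        assert report.n_both_interpretable == 51
        assert report.n_final == len(kept) == 45
        labels = [r.label for r in kept]
        assert labels.count("recurrence") == 20
        assert labels.count("post_treatment") == 25

    def test_dwi_uninterpretable_cause_split(self):
        records, _ = generate_cohort(CohortConfig(), seed=6)
        bad_dwi = [r for r in records if not r.dwi_interpretable]
        assert len(bad_dwi) == 20
        causes = [r.dwi_artifact_cause for r in bad_dwi]
        assert causes.count("skull_base") == 14
        assert causes.count("hemorrhage") == 6

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_dce_losses_nested_in_dwi_losses_with_hemorrhage(self, seed):
        records, _ = generate_cohort(CohortConfig(), seed=seed)
        for r in records:
            if not r.dce_interpretable:
                assert not r.dwi_interpretable
                assert r.artifact_cause == "hemorrhage"

    def test_zero_artifacts_all_survive(self):
        config = CohortConfig(
            n_total=71, n_dsc_hemorrhage=54, n_dsc_skull_base=17,
            n_dwi_uninterp_skull_base=0, n_dwi_uninterp_hemorrhage=0,
            n_dce_uninterp=0, n_steroid=0, n_no_followup=0,
            n_recurrence_final=32, n_post_treatment_final=39)
        records, _ = generate_cohort(config, seed=0)
        kept, report = apply_accrual_filters(records)
        assert len(kept) == 71

    def test_inconsistent_nesting_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_dce_uninterp=25)   # exceeds the 20 DWI losses

    def test_identical_seeds_bit_identical(self, small_cohort_config):
        a, _ = generate_cohort(small_cohort_config, seed=7, with_images=True)
        b, _ = generate_cohort(small_cohort_config, seed=7, with_images=True)
        assert [s.record for s in a] == [s.record for s in b]
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.dce.si, sb.dce.si)
            assert np.array_equal(sa.dwi.sb, sb.dwi.sb)
            assert np.array_equal(sa.dsc.si, sb.dsc.si)
            assert np.array_equal(sa.lesion_mask_reader2,
                                  sb.lesion_mask_reader2)

    def test_feature_target_calibration_over_200_cohorts(self):
        # the injected per-class lesion features are the generator's ground
        # truth; their sample mean must sit within 2 SE of the configured mean
        config = CohortConfig()
        iauc = {"recurrence": [], "post_treatment": []}
        for seed in range(200):
            records, _ = generate_cohort(config, seed=seed)
            for r in records:
                iauc[r.label].append(r.target_iauc90)
        for label, params in (("recurrence", config.recurrence),
                              ("post_treatment", config.post_treatment)):
            x = np.asarray(iauc[label])
            se = params.iauc90_sd / np.sqrt(x.size)
            assert abs(x.mean() - params.iauc90_mean) < 2 * se


class TestStudyImages:
    def test_pipeline_recovers_injected_features(self, small_cohort_config):
        # lesion IAUC90/ADC10 measured from the images must track the
        # injected targets to within mask-jitter and smoothing effects
        records, _ = generate_cohort(small_cohort_config, seed=12)
        kept, _ = apply_accrual_filters(records)
        for record in kept[:6]:
            study = generate_study(record, small_cohort_config)
            adc = compute_adc(study.dwi)
            iauc = compute_iauc_map(study.dce,
                                    lesion_mask=study.lesion_mask_reader1)
            fs = extract_features(adc, iauc, study.lesion_mask_reader1,
                                  reader="1", patient=record.id)
            t_iauc = max(record.target_iauc90, 0.1)
            t_adc = max(record.target_adc10, 0.2)
            assert abs(fs.iauc90 - t_iauc) < 0.05 * t_iauc + 0.2
            assert abs(fs.adc10 - t_adc) < 0.06

    def test_uninterpretable_dwi_lesion_is_mostly_nil(self, small_cohort_config):
        records, _ = generate_cohort(small_cohort_config, seed=12)
        bad = next(r for r in records if not r.dwi_interpretable)
        study = generate_study(bad, small_cohort_config)
        adc = compute_adc(study.dwi)
        verdict = flag_signal_loss(adc, study.lesion_mask_true)
        assert not verdict.interpretable

    def test_masks_disjoint_and_nonempty(self, small_cohort_config):
        records, _ = generate_cohort(small_cohort_config, seed=1)
        study = generate_study(records[0], small_cohort_config)
        assert study.lesion_mask_reader1.any() and study.nawm_mask.any()
        assert not (study.lesion_mask_reader1 & study.nawm_mask).any()
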