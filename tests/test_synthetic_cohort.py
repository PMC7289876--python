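"""Synthetic cohort generator: determinism, distributions, anatomy, I/O."""

import numpy as np
import pandas as pd
import pytest

from voxdose import synthetic_cohort as sc
from voxdose.organ_dosimetry import organs_for_sex


class TestPatients:
    def test_same_seed_identical_records(self):
        assert sc.generate_patient(7) == sc.generate_patient(7)

    def test_different_seeds_differ(self):
        assert sc.generate_patient(1) != sc.generate_patient(2)

    def test_bmi_consistent_with_height_weight(self):
        p = sc.generate_patient(3)
        implied = p.weight / (p.height / 100.0) ** 2
        assert abs(implied - p.bmi) <= 0.5

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sc.CohortSpec(age_sd=-1.0)
        with pytest.raises(ValueError):
            sc.CohortSpec(female_fraction=1.5)
        with pytest.raises(ValueError):
            sc.CohortSpec(bmi_range=(30.0, 20.0))

    def test_cohort_recovers_age_distribution(self):
        # Monte Carlo check of the generator against its own specification:
        # with n = 1000 the sample mean age must sit within 3 standard errors
        # of the specified 57.3 y.
        spec = sc.CohortSpec()
        cohort = sc.generate_cohort(1000, seed=42, spec=spec)
        ages = np.array([p.age for p in cohort])
        se = spec.age_sd / np.sqrt(len(ages))
        assert abs(ages.mean() - spec.age_mean) < 3 * se
        frac_f = np.mean([p.sex == "female" for p in cohort])
        assert abs(frac_f - spec.female_fraction) < 0.05

    def test_record_validation(self):
        with pytest.raises(ValueError):
            sc.PatientRecord(id="x", age=-5, sex="male", weight=80, bmi=25)
        with pytest.raises(ValueError):
            sc.PatientRecord(id="x", age=50, sex="other", weight=80, bmi=25)
        with pytest.raises(ValueError):  # inconsistent BMI
            sc.PatientRecord(id="x", age=50, sex="male", weight=80, bmi=20, height=178)


class TestPhantom:
    def test_male_phantom_has_no_female_organs(self, male_phantom):
        present = male_phantom.present_organs()
        assert "uterus" not in present and "breast" not in present
        assert set(present) == set(organs_for_sex("male"))

    def test_female_phantom_has_no_prostate(self, female_phantom):
        present = female_phantom.present_organs()
        assert "prostate" not in present
        assert set(present) == set(organs_for_sex("female"))

    def test_omitted_organ_variant(self, male_patient):
        ph = sc.generate_phantom(male_patient, resolution=48, seed=5, omit=("spleen",))
        present = ph.present_organs()
        assert "spleen" not in present
        assert set(present) == set(organs_for_sex("male")) - {"spleen"}

    def test_seed_changes_geometry_not_inventory(self, male_patient):
        a = sc.generate_phantom(male_patient, resolution=32, seed=1)
        b = sc.generate_phantom(male_patient, resolution=32, seed=2)
        assert not np.array_equal(a.labels, b.labels)
        assert set(a.present_organs()) == set(b.present_organs())

    def test_same_seed_bit_identical(self, male_patient):
        a = sc.generate_phantom(male_patient, resolution=32, seed=9)
        b = sc.generate_phantom(male_patient, resolution=32, seed=9)
        assert np.array_equal(a.hu, b.hu) and np.array_equal(a.labels, b.labels)

    def test_resolution_too_small_rejected(self, male_patient):
        with pytest.raises(sc.PhantomError):
            sc.generate_phantom(male_patient, resolution=8, seed=0)

    def test_unknown_omission_rejected(self, male_patient):
        with pytest.raises(sc.PhantomError):
            sc.generate_phantom(male_patient, resolution=32, seed=0, omit=("thymus",))

    def test_tissue_hounsfield_plausibility(self, male_phantom):
        hu, lab, lm = male_phantom.hu, male_phantom.labels, male_phantom.label_map
        assert hu[lab == lm["lung"]].mean() < -400
        assert hu[lab == lm["bone_surface"]].mean() > 500
        assert 0 < hu[lab == lm["liver"]].mean() < 200
        assert hu[lab == lm["kidney"]].mean() > 100  # contrast enhanced
        assert np.all(hu >= -1000)

    def test_hollow_organ_wall_only(self, male_patient):
        # the stomach interior must not carry the stomach label
        ph = sc.generate_phantom(male_patient, resolution=64, seed=3)
        mask = ph.organ_mask("stomach")
        assert mask.sum() > 0
        idx = np.argwhere(mask)
        center = idx.mean(axis=0).round().astype(int)
        assert not mask[tuple(center)]

    def test_organ_volume_scales_with_bmi(self):
        slim = sc.PatientRecord(id="a", age=50, sex="male", weight=55.4, bmi=17.0, height=180.5)
        obese = sc.PatientRecord(id="b", age=50, sex="male", weight=117.3, bmi=36.0, height=180.5)
        ph_s = sc.generate_phantom(slim, resolution=48, seed=4)
        ph_o = sc.generate_phantom(obese, resolution=48, seed=4)
        # same grid resolution but larger FOV: compare physical volumes
        vol_s = ph_s.organ_mask("liver").sum() * np.prod(ph_s.spacing)
        vol_o = ph_o.organ_mask("liver").sum() * np.prod(ph_o.spacing)
        assert vol_o > vol_s


class TestScannerEmulation:
    def test_effective_mas_monotone_in_bmi(self):
        lo = sc.PatientRecord(id="a", age=50, sex="male", weight=65, bmi=65 / 1.8**2, height=180)
        hi = sc.PatientRecord(id="b", age=50, sex="male", weight=95, bmi=95 / 1.8**2, height=180)
        r_lo = sc.emulate_scanner_report(lo, seed=11)
        r_hi = sc.emulate_scanner_report(hi, seed=11)
        assert r_hi.effective_mAs > r_lo.effective_mAs
        assert sc.expected_effective_mas(30.0) > sc.expected_effective_mas(20.0)

    def test_dlp_consistent_with_ctdi_and_length(self):
        p = sc.generate_patient(5)
        r = sc.emulate_scanner_report(p, seed=5)
        assert r.dlp == pytest.approx(r.ctdi_vol * sc.SCAN_FRACTION * p.height_cm, rel=0.02)

    def test_cohort_bmi_dlp_correlation(self):
        from voxdose.cohort_stats import spearman

        cohort = sc.generate_cohort(100, seed=8)
        reports = [sc.emulate_scanner_report(p, seed=i) for i, p in enumerate(cohort)]
        bmi = [p.bmi for p in cohort]
        rho_dlp, _ = spearman(bmi, [r.dlp for r in reports])
        rho_mas, _ = spearman(bmi, [r.effective_mAs for r in reports])
        assert rho_dlp > 0.9 and rho_mas > 0.9

    def test_anchor_row_dlp_scale(self):
        # normal-weight anchor: BMI 21.6 must land within a factor 2 of the
        # reference 675 mGy cm
        p = sc.PatientRecord(id="a", age=30, sex="female", weight=70.0, bmi=21.6, height=180.0)
        r = sc.emulate_scanner_report(p, seed=1)
        assert 675 / 2 < r.dlp < 675 * 2

    def test_air_kerma_scales_with_tube_output(self):
        p = sc.generate_patient(6)
        r = sc.emulate_scanner_report(p, seed=6)
        scan = sc.scan_parameters_for(p, r)
        assert scan.air_kerma == pytest.approx(
            sc.AIR_KERMA_REF * r.effective_mAs / sc.AIR_KERMA_REF_MAS
        )


class TestCohortTable:
    def test_packaged_fixture_first_row(self, cohort_df):
        row = cohort_df.iloc[0]
        assert row["age_y"] == 30 and row["sex"] == "female"
        assert row["dlp_mGycm"] == 675 and row["ed_mc_mSv"] == 11.1

    def test_fixture_round_trips_losslessly(self, cohort_df, tmp_path):
        out = tmp_path / "cohort.csv"
        cohort_df.to_csv(out, index=False)
        again = sc.load_cohort_table(out)
        pd.testing.assert_frame_equal(cohort_df, again)

    def test_empty_file_gives_empty_cohort(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("")
        assert len(sc.load_cohort_table(f)) == 0

    def test_invalid_rows_reported_with_index(self, cohort_df, tmp_path):
        bad = cohort_df.copy()
        bad.loc[3, "dlp_mGycm"] = -10.0
        f = tmp_path / "bad.csv"
        bad.to_csv(f, index=False)
        with pytest.raises(sc.CohortValidationError, match="row 3"):
            sc.load_cohort_table(f)
        bad = cohort_df.copy()
        bad.loc[5, "ed_mc_mSv"] = -1.0
        bad.to_csv(f, index=False)
        with pytest.raises(sc.CohortValidationError, match="row 5"):
            sc.load_cohort_table(f)


class TestPhantomIO:
    def test_nifti_round_trip(self, male_patient, tmp_path):
        ph = sc.generate_phantom(male_patient, resolution=24, seed=2)
        prefix = str(tmp_path / "ph")
        sc.save_phantom(ph, prefix)
        back = sc.load_phantom(prefix)
        assert np.allclose(back.hu, ph.hu, atol=1e-4)
        assert np.array_equal(back.labels, ph.labels)
        assert back.label_map == ph.label_map
        assert back.sex == ph.sex
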