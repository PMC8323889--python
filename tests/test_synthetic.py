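"""Generator contracts: geometry, reporting errors, income structure,
instrument validity, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from shapeincome.meshes import mesh_volume_mm3
from shapeincome.synthetic import (
    CohortConfig,
    LatentProfile,
    apply_reporting_error,
    deform_template,
    derive_measurements,
    draw_income_and_instruments,
    generate_cohort,
    make_template_mesh,
    theoretical_ols_stature_bias,
    write_cohort,
)


class TestTemplate:
    def test_vertex_count_is_rings_times_segments(self):
        m = make_template_mesh("male", 40, 24)
        assert m.n_vertices == 960
        assert 3 * m.n_vertices == 2880

    def test_same_topology_across_genders(self):
        male = make_template_mesh("male", 40, 24)
        female = make_template_mesh("female", 40, 24)
        np.testing.assert_array_equal(male.faces, female.faces)
        assert not np.allclose(male.vertices, female.vertices)

    def test_bitwise_deterministic(self):
        a = make_template_mesh("female", 16, 12)
        b = make_template_mesh("female", 16, 12)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.faces, b.faces)

    def test_calibrated_to_base_height_and_weight(self, male_template):
        meas = derive_measurements(male_template)
        assert meas.height_cm == pytest.approx(175.0, abs=1e-9)
        assert meas.weight_kg == pytest.approx(78.0, rel=1e-9)

    @pytest.mark.parametrize("rings,segments", [(4, 12), (16, 5)])
    def test_too_coarse_grid_rejected(self, rings, segments):
        with pytest.raises(ValueError, match=">= 8"):
            make_template_mesh("male", rings, segments)


class TestDeformation:
    def test_zero_factors_zero_noise_is_identity(self, male_template):
        lp = LatentProfile(0.0, 0.0, 0.0, "male")
        out = deform_template(male_template, lp, 0.0)
        np.testing.assert_array_equal(out.vertices, male_template.vertices)

    def test_stature_increases_height(self, male_template):
        base = derive_measurements(male_template).height_cm
        tall = deform_template(male_template, LatentProfile(1.0, 0.0, 0.0, "male"), 0.0)
        assert derive_measurements(tall).height_cm > base

    def test_hipwaist_raises_girth_ratio_not_stature(self, male_template):
        base = derive_measurements(male_template)
        hw = deform_template(male_template, LatentProfile(0.0, 0.0, 1.0, "male"), 0.0)
        meas = derive_measurements(hw)
        assert meas.hip_cm / meas.waist_cm > base.hip_cm / base.waist_cm
        assert meas.height_cm == pytest.approx(base.height_cm, abs=1e-9)

    def test_weight_monotone_in_obesity(self, male_template):
        weights = [
            derive_measurements(
                deform_template(male_template,
                                LatentProfile(0.0, o, 0.0, "male"), 0.0)).weight_kg
            for o in np.linspace(-2, 2, 7)
        ]
        assert np.all(np.diff(weights) > 0)


class TestMeasurements:
    def test_uniform_scaling_law(self, male_template):
        from shapeincome.meshes import Mesh

        big = Mesh(male_template.vertices * 2.0, male_template.faces,
                   rings=male_template.rings, segments=male_template.segments)
        m0 = derive_measurements(male_template)
        m2 = derive_measurements(big)
        assert m2.height_cm == pytest.approx(2 * m0.height_cm, rel=1e-12)
        assert m2.weight_kg == pytest.approx(8 * m0.weight_kg, rel=1e-12)

    def test_volume_sign_convention_outward(self, male_template):
        assert mesh_volume_mm3(male_template) > 0


class TestReportingErrors:
    def setup_method(self):
        self.cfg = CohortConfig(n_subjects=10, seed=0)
        self.cfg.noise_scales["reporting_height_cm"] = 0.0
        self.cfg.noise_scales["reporting_weight_kg"] = 0.0
        self.rng = np.random.default_rng(0)

    def test_male_pivot_weight_error_is_zero(self):
        h, w = apply_reporting_error(
            np.array([175.0]), np.array([75.0]), np.array(["male"]),
            self.cfg, self.rng)
        assert w[0] - 75.0 == pytest.approx(0.0, abs=1e-12)

    def test_female_over_then_under_report(self):
        _, w = apply_reporting_error(
            np.array([160.0, 160.0]), np.array([40.0, 80.0]),
            np.array(["female", "female"]), self.cfg, self.rng)
        assert w[0] > 40.0 and w[1] < 80.0

    def test_null_error_config_reports_truth(self):
        self.cfg.height_over_report_cm = 0.0
        self.cfg.female_height_extra_slope = 0.0
        self.cfg.weight_error_slope = 0.0
        h, w = apply_reporting_error(
            np.array([150.0, 180.0]), np.array([55.0, 90.0]),
            np.array(["female", "male"]), self.cfg, self.rng)
        np.testing.assert_array_equal(h, [150.0, 180.0])
        np.testing.assert_array_equal(w, [55.0, 90.0])

    def test_short_women_over_report_height_more(self):
        h, _ = apply_reporting_error(
            np.array([150.0, 170.0]), np.array([60.0, 60.0]),
            np.array(["female", "female"]), self.cfg, self.rng)
        assert (h[0] - 150.0) > (h[1] - 170.0)


class TestIncomeAndInstruments:
    def test_noiseless_income_is_exact_linear_form(self):
        cfg = CohortConfig(n_subjects=50, seed=3, endogeneity_strength=0.0)
        cfg.noise_scales["income"] = 0.0
        c = generate_cohort(cfg, include_meshes=False)
        co = cfg.income_coefficients
        t, lat = c.table, c.latents
        expect = np.full(len(t), co["intercept"])
        expect += co["education_years"] * t["education_years"].to_numpy()
        ex = t["experience_years"].to_numpy()
        expect += co["experience_years"] * ex + co["experience_sq"] * ex ** 2
        expect += co["n_children"] * t["n_children"].to_numpy()
        for col in ("race", "marital_status", "occupation"):
            expect += np.array([co[col][v] for v in t[col]])
        for fac in ("stature", "obesity", "hipwaist"):
            beta = np.array([co["beta"][g][fac] for g in t["gender"]])
            expect += beta * lat[f"{fac}_factor"].to_numpy()
        np.testing.assert_allclose(t["log_family_income"], expect, atol=1e-10)

    def test_zero_strength_instrument_uncorrelated_with_stature(self):
        cfg = CohortConfig(n_subjects=4000, seed=9, instrument_strengths=(0.0, 0.6, 0.7))
        c = generate_cohort(cfg, include_meshes=False)
        r = np.corrcoef(c.table["shoe_size"], c.latents["stature_factor"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(c.table))

    def test_exclusion_restriction_instruments_independent_of_ability(self):
        # valid instruments: correlated with stature, not with the confounder
        n = 5000
        for seed in range(5):
            c = generate_cohort(CohortConfig(n_subjects=n, seed=seed),
                                include_meshes=False)
            a = c.latents["ability"].to_numpy()
            for col in ("shoe_size", "garment_size", "pants_size"):
                r = np.corrcoef(c.table[col], a)[0, 1]
                assert abs(r) < 3 / np.sqrt(n), (seed, col, r)
            r_s = np.corrcoef(c.table["shoe_size"],
                              c.latents["stature_factor"])[0, 1]
            assert r_s > 0.3

    def test_dimension_mismatch_raises(self):
        cfg = CohortConfig(n_subjects=10, seed=0)
        c = generate_cohort(cfg, include_meshes=False)
        with pytest.raises(ValueError, match="equal length"):
            draw_income_and_instruments(
                c.latents, c.table.iloc[:5], cfg, np.random.default_rng(0))


class TestCohortAssembly:
    def test_reproducible_from_seed(self):
        cfg = CohortConfig(n_subjects=10, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
        for ma, mb in zip(a.meshes, b.meshes):
            np.testing.assert_array_equal(ma.vertices, mb.vertices)

    def test_quota_mode_reproduces_published_gender_counts(self):
        c = generate_cohort(CohortConfig(n_subjects=2383, seed=0),
                            include_meshes=False)
        counts = c.table["gender"].value_counts()
        assert counts["male"] == 1122
        assert counts["female"] == 1261

    def test_binomial_mode_varies_counts(self):
        cfg = CohortConfig(n_subjects=500, seed=1, gender_mode="binomial")
        c = generate_cohort(cfg, include_meshes=False)
        n_male = (c.table["gender"] == "male").sum()
        assert 180 < n_male < 320  # ~Binomial(500, 0.47), not the exact quota

    def test_bmi_identity_holds(self, small_cohort):
        t = small_cohort.table
        np.testing.assert_allclose(
            t["bmi"], t["measured_weight"] / (t["measured_height"] / 100) ** 2,
            rtol=1e-9)

    def test_degenerate_cohort_all_identical(self):
        cfg = CohortConfig(n_subjects=6, seed=5, male_fraction=1.0,
                           endogeneity_strength=0.0,
                           factor_sds={"stature": 0.0, "obesity": 0.0})
        for k in cfg.noise_scales:
            cfg.noise_scales[k] = 0.0
        c = generate_cohort(cfg)
        assert c.table["measured_height"].nunique() == 1
        assert c.table["measured_weight"].nunique() == 1
        for m in c.meshes[1:]:
            np.testing.assert_array_equal(m.vertices, c.meshes[0].vertices)

    def test_written_csv_is_byte_identical_across_runs(self, tmp_path):
        cfg = CohortConfig(n_subjects=20, seed=8)
        write_cohort(generate_cohort(cfg), tmp_path / "a", write_meshes=False)
        write_cohort(generate_cohort(cfg), tmp_path / "b", write_meshes=False)
        assert ((tmp_path / "a" / "subjects.csv").read_bytes()
                == (tmp_path / "b" / "subjects.csv").read_bytes())

    def test_ability_not_in_observable_table(self, small_cohort):
        assert "ability" not in small_cohort.table.columns
        assert "stature_base" not in small_cohort.table.columns


def test_ols_bias_formula_limits():
    assert theoretical_ols_stature_bias(0.0) == 0.0
    assert theoretical_ols_stature_bias(0.6) == pytest.approx(0.36 / 1.36)
    assert theoretical_ols_stature_bias(1e6) == pytest.approx(1.0, abs=1e-9)
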