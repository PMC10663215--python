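"""Surface-density model: fitting, mass/ratio estimation, evaluation protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caneseg.density import (
    DEFAULT_SURFACE_DENSITY,
    MATERIAL_CLASSES,
    ClassDensity,
    MassPixelSample,
    SurfaceDensityModel,
    UndefinedRatioError,
    count_class_pixels,
    estimate_mass,
    estimate_ratios,
    evaluate_ratio_tables,
    fit_surface_density,
    fit_surface_density_model,
    read_mass_csv,
    regress_estimated_vs_measured,
    relative_error,
    select_confidence_interval,
    write_mass_csv,
)
from caneseg.synthdata import PALETTE, make_mass_dataset


def make_sample(i, pixels, masses):
    return MassPixelSample(sample_id=f"s{i}", pixels=pixels, masses=masses)


class TestMassPixelSample:
    def test_rejects_negative_pixels_and_masses(self):
        with pytest.raises(ValueError):
            make_sample(0, {"cane": -1}, {})
        with pytest.raises(ValueError):
            make_sample(0, {"cane": 10}, {"cane": -0.1})

    def test_rejects_mass_without_pixels(self):
        with pytest.raises(ValueError, match="zero pixels"):
            make_sample(0, {"cane": 0}, {"cane": 5.0})


class TestCountClassPixels:
    def test_single_class_raster(self):
        mask = np.full((10, 10), 1, dtype=np.uint8)  # all cane
        counts = count_class_pixels(mask, PALETTE)
        assert counts == {"background": 0, "cane": 100, "broken_cane": 0, "top": 0, "leaf": 0}

    def test_mixed_raster_counts_by_enumeration(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask.flat[:30] = 1  # cane
        mask.flat[30:50] = 2  # broken cane
        counts = count_class_pixels(mask, PALETTE)
        assert counts["cane"] == 30 and counts["broken_cane"] == 20
        assert counts["top"] == 0 and counts["leaf"] == 0
        assert counts["background"] == 50
        assert sum(counts.values()) == 100

    def test_rgb_raster_with_unknown_color_is_an_error(self):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[0, 0] = (7, 7, 7)
        with pytest.raises(ValueError, match=r"\(7, 7, 7\)"):
            count_class_pixels(rgb, PALETTE)

    def test_rgb_raster_counts_match_index_raster(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[:2] = 1
        mask[2] = 4
        rgb = np.zeros((6, 6, 3), dtype=np.uint8)
        for idx, name in enumerate(PALETTE):
            rgb[mask == idx] = PALETTE[name]
        assert count_class_pixels(rgb, PALETTE) == count_class_pixels(mask, PALETTE)

    def test_unknown_index_is_an_error(self):
        mask = np.full((3, 3), 9, dtype=np.uint8)
        with pytest.raises(ValueError, match="9"):
            count_class_pixels(mask, PALETTE)


class TestFitSurfaceDensity:
    def test_constant_densities_give_mu_and_zero_sigma(self):
        samples = [make_sample(i, {"cane": 1000 * (i + 1)},
                               {"cane": 1.52e-3 * 1000 * (i + 1)}) for i in range(5)]
        fit = fit_surface_density(samples, "cane")
        assert fit.mu == pytest.approx(1.52e-3, rel=1e-9)
        assert fit.sigma == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("m,s", [(1.5e-3, 2e-4), (7.4e-4, 1e-4)])
    def test_recovers_gaussian_parameters_within_sampling_error(self, m, s, rng):
        d = rng.normal(m, s, 300)
        d = np.abs(d)
        samples = [make_sample(i, {"cane": 10000}, {"cane": float(v) * 10000})
                   for i, v in enumerate(d)]
        fit = fit_surface_density(samples, "cane")
        assert abs(fit.mu - d.mean()) < 1e-12  # moment match is exact
        assert abs(fit.mu - m) < 3 * s / np.sqrt(300)

    def test_well_sampled_gaussian_histogram_agrees_with_pdf(self, rng):
        d = np.abs(rng.normal(8.8e-4, 1.5e-4, 1000))
        samples = [make_sample(i, {"top": 5000}, {"top": float(v) * 5000})
                   for i, v in enumerate(d)]
        fit = fit_surface_density(samples, "top", bins=12)
        assert fit.r2 > 0.95

    def test_histogram_method_close_to_moments_on_clean_data(self, rng):
        d = np.abs(rng.normal(1e-3, 1e-4, 2000))
        samples = [make_sample(i, {"cane": 1000}, {"cane": float(v) * 1000})
                   for i, v in enumerate(d)]
        fm = fit_surface_density(samples, "cane", method="moments")
        fh = fit_surface_density(samples, "cane", method="histogram", bins=20)
        assert fh.mu == pytest.approx(fm.mu, rel=0.05)
        assert fh.sigma == pytest.approx(fm.sigma, rel=0.15)

    def test_zero_pixel_samples_are_excluded_with_warning(self):
        samples = [make_sample(0, {"cane": 0}, {}),
                   make_sample(1, {"cane": 100}, {"cane": 0.15}),
                   make_sample(2, {"cane": 100}, {"cane": 0.16})]
        with pytest.warns(UserWarning, match="excluded 1"):
            fit = fit_surface_density(samples, "cane")
        assert fit.n_samples == 2

    def test_too_few_samples_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_surface_density([make_sample(0, {"cane": 10}, {"cane": 0.01})], "cane")

    def test_parameter_recovery_bias_over_replicates(self):
        # mean bias of the fitted mu over 100 seeded replicates of n=300
        m, s, n, reps = 1.52e-3, 2e-4, 300, 100
        estimates = []
        for r in range(reps):
            rr = np.random.default_rng(5000 + r)
            d = np.abs(rr.normal(m, s, n))
            samples = [make_sample(i, {"cane": 1000}, {"cane": float(v) * 1000})
                       for i, v in enumerate(d)]
            estimates.append(fit_surface_density(samples, "cane").mu)
        bias = np.mean(estimates) - m
        se_of_mean = s / np.sqrt(n * reps)
        assert abs(bias) < 3 * se_of_mean


class TestEstimateMass:
    def test_zero_pixels_give_zero_mass(self):
        est = estimate_mass({c: 0 for c in MATERIAL_CLASSES})
        assert est.total() == 0.0

    def test_reference_density_hand_values(self):
        est = estimate_mass({"cane": 100_000, "broken_cane": 0, "top": 0, "leaf": 1_000_000})
        assert est["cane"] == pytest.approx(152.0)
        assert est["leaf"] == pytest.approx(30.0)

    def test_negative_count_is_an_error(self):
        with pytest.raises(ValueError, match="negative"):
            estimate_mass({"cane": -5})

    def test_scale_equivariance_of_masses_and_ratio_invariance(self):
        pixels = {"cane": 5000, "broken_cane": 2500, "top": 1000, "leaf": 8000}
        scaled = {c: 7 * p for c, p in pixels.items()}
        e1, e7 = estimate_mass(pixels), estimate_mass(scaled)
        for c in MATERIAL_CLASSES:
            assert e7[c] == pytest.approx(7 * e1[c], rel=1e-12)
        r1, r7 = estimate_ratios(e1), estimate_ratios(e7)
        assert r7.breakage == pytest.approx(r1.breakage, rel=1e-12)
        assert r7.impurity == pytest.approx(r1.impurity, rel=1e-12)


class TestEstimateRatios:
    def test_zero_numerators(self):
        r = estimate_ratios({"cane": 10.0, "broken_cane": 0.0, "top": 0.0, "leaf": 0.0})
        assert r.breakage == 0.0 and r.impurity == 0.0

    def test_equal_cane_and_broken_gives_half(self):
        r = estimate_ratios({"cane": 3.3, "broken_cane": 3.3})
        assert r.breakage == pytest.approx(0.5)

    def test_pixel_form_hand_value(self):
        est = estimate_mass({"cane": 100_000, "broken_cane": 100_000, "top": 0, "leaf": 0})
        r = estimate_ratios(est)
        assert r.breakage == pytest.approx(7.4e-4 / (1.52e-3 + 7.4e-4), rel=1e-9)
        assert r.breakage == pytest.approx(0.3274, abs=5e-5)
        assert r.impurity == 0.0

    def test_all_zero_masses_raise_typed_error_not_nan(self):
        with pytest.raises(UndefinedRatioError):
            estimate_ratios({c: 0.0 for c in MATERIAL_CLASSES})

    def test_unit_invariance_g_vs_kg(self):
        masses = {"cane": 120.0, "broken_cane": 30.0, "top": 20.0, "leaf": 2.0}
        kg = {c: m / 1000.0 for c, m in masses.items()}
        rg, rkg = estimate_ratios(masses), estimate_ratios(kg)
        assert rg.breakage == pytest.approx(rkg.breakage, rel=1e-12)
        assert rg.impurity == pytest.approx(rkg.impurity, rel=1e-12)

    def test_measured_and_sigma_zero_synthetic_masses_agree(self):
        # masses generated from a sigma = 0 model equal mu * pixels, so the
        # measured-mass and estimated-mass ratio paths coincide exactly
        pixels = {"cane": 40_000, "broken_cane": 9_000, "top": 6_000, "leaf": 20_000}
        model = SurfaceDensityModel.reference()
        generated = {c: model.mu(c) * p for c, p in pixels.items()}
        assert estimate_ratios(generated) == estimate_ratios(estimate_mass(pixels, model))


class TestRelativeError:
    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_identity_is_zero(self, x):
        assert relative_error(x, x) == 0.0

    def test_printed_table_sample(self):
        assert round(relative_error(0.328, 0.319), 3) == 0.027

    def test_hand_value(self):
        assert relative_error(0.100, 0.150) == pytest.approx(0.5)

    def test_zero_measured_is_an_error(self):
        with pytest.raises(ValueError):
            relative_error(0.0, 0.1)


class TestEvaluateRatioTables:
    def test_identical_columns_give_zero_mean_error(self):
        pairs = [(0.2, 0.2), (0.3, 0.3), (0.45, 0.45)]
        rep = evaluate_ratio_tables(pairs)
        assert rep.mean_relative_error == 0.0

    def test_mean_equals_elementwise_relative_error_mean(self, rng):
        pairs = [(float(m), float(e)) for m, e in
                 zip(rng.uniform(0.05, 0.5, 25), rng.uniform(0.05, 0.5, 25))]
        rep = evaluate_ratio_tables(pairs)
        expected = np.mean([relative_error(m, e) for m, e in pairs])
        assert rep.mean_relative_error == pytest.approx(expected, rel=1e-12)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_ratio_tables([])


class TestRegression:
    def test_perfect_identity_fit(self):
        pairs = [(x, x) for x in (0.1, 0.2, 0.3, 0.4)]
        r = regress_estimated_vs_measured(pairs)
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r2 == pytest.approx(1.0)
        assert r.ss_residual == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols(self):
        r = regress_estimated_vs_measured([(0, 0), (1, 2), (2, 4), (3, 6)])
        assert r.slope == pytest.approx(2.0)
        assert r.r2 == pytest.approx(1.0)

    def test_anova_decomposition_identity(self, rng):
        pairs = [(float(x), float(y)) for x, y in
                 zip(rng.uniform(0, 1, 40), rng.uniform(0, 1, 40))]
        r = regress_estimated_vs_measured(pairs)
        assert r.ss_total == pytest.approx(r.ss_regression + r.ss_residual, rel=1e-9)
        assert r.df_regression == 1 and r.df_residual == 38

    def test_significance_matches_scipy_f_distribution(self, rng):
        from scipy import stats

        x = rng.uniform(0, 1, 30)
        y = 2 * x + rng.normal(0, 0.2, 30)
        r = regress_estimated_vs_measured(list(zip(x, y)))
        assert r.significance == pytest.approx(
            float(stats.f.sf(r.f_statistic, 1, 28)), rel=1e-9)

    def test_degenerate_x_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            regress_estimated_vs_measured([(0.2, 0.1), (0.2, 0.2), (0.2, 0.3)])


class TestConfidenceSelection:
    def test_level_one_limit_retains_everything(self):
        samples = make_mass_dataset(50, seed=3)
        kept = select_confidence_interval(samples, level=1 - 1e-12)
        assert len(kept) == 50

    def test_bad_level_is_an_error(self):
        samples = make_mass_dataset(10, seed=3)
        with pytest.raises(ValueError):
            select_confidence_interval(samples, level=1.5)

    def test_per_class_retention_near_level(self):
        # i.i.d. Gaussian densities per class: each class individually keeps
        # about 95% of samples (binomial error around 0.95 * n)
        samples = make_mass_dataset(400, seed=7, class_correlation=0.0)
        model = fit_surface_density_model(samples)
        from scipy import stats

        z = stats.norm.ppf(0.975)
        for cls in MATERIAL_CLASSES:
            cd = model.classes[cls]
            frac = np.mean([abs(s.density(cls) - cd.mu) <= z * cd.sigma for s in samples])
            assert abs(frac - 0.95) < 3 * np.sqrt(0.95 * 0.05 / 400)

    def test_calibration_set_retention(self):
        # 300-sample calibration emulation keeps roughly 285 samples
        samples = make_mass_dataset(300, seed=11)
        kept = select_confidence_interval(samples, level=0.95)
        assert 270 <= len(kept) <= 297


class TestMassCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        samples = make_mass_dataset(5, seed=2)
        path = tmp_path / "mass.csv"
        write_mass_csv(samples, path)
        back = read_mass_csv(path)
        assert [s.sample_id for s in back] == [s.sample_id for s in samples]
        for a, b in zip(samples, back):
            assert a.pixels == b.pixels
            for c in MATERIAL_CLASSES:
                assert b.masses[c] == pytest.approx(a.masses[c], rel=1e-12)

    def test_missing_columns_is_an_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="columns"):
            read_mass_csv(p)


class TestDefaults:
    def test_reference_constants(self):
        model = SurfaceDensityModel.reference()
        assert model.mu("cane") == 1.52e-3
        assert model.mu("broken_cane") == 7.4e-4
        assert model.mu("top") == 8.8e-4
        assert model.mu("leaf") == 3e-5

    def test_class_density_validation(self):
        with pytest.raises(ValueError):
            ClassDensity(mu=0.0)
        with pytest.raises(ValueError):
            ClassDensity(mu=1.0, sigma=-1.0)
        with pytest.raises(ValueError):
            ClassDensity(mu=1.0, r2=1.5)
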