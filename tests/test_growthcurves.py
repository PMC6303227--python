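"""PSA assembly, hybrid calibration, smoothing, rates, water use and WUI."""

import numpy as np
import pandas as pd
import pytest

from saltphenome.growthcurves import (
    DEFAULT_ENDPOINTS,
    CalibrationFit,
    PSASeries,
    build_hybrid_series,
    calibrate_hybrid,
    compute_psa,
    compute_water_use,
    compute_wui,
    derive_rates,
    fit_smoothing_spline,
    interval_summaries,
    interval_wui,
)
from saltphenome.simulate import (
    ObservationModel,
    observe_experiment,
    simulate_growth,
)


def _img(rows):
    return pd.DataFrame(rows, columns=["plant", "das", "camera", "view", "area_kpx"])


def _series(das, psa, plant="p"):
    return PSASeries(plant=plant, das=np.asarray(das), psa=np.asarray(psa, float))


class TestComputePSA:
    def test_rgb_sums_three_views(self):
        img = _img([("p", 4, "RGB", "SV0", 10), ("p", 4, "RGB", "SV90", 12),
                    ("p", 4, "RGB", "TV", 3)])
        out = compute_psa(img, "RGB")
        assert out["p"].at(4) == pytest.approx(25.0)

    def test_fluo_sums_two_views(self):
        img = _img([("p", 4, "FLUO", "SV0", 10), ("p", 4, "FLUO", "SV90", 12)])
        out = compute_psa(img, "FLUO")
        assert out["p"].at(4) == pytest.approx(22.0)

    def test_duplicate_view_is_an_error_naming_the_row(self):
        img = _img([("p", 4, "RGB", "SV0", 10), ("p", 4, "RGB", "SV0", 11),
                    ("p", 4, "RGB", "SV90", 12), ("p", 4, "RGB", "TV", 3)])
        with pytest.raises(ValueError, match="das=4"):
            compute_psa(img, "RGB")

    def test_missing_view_drops_day_with_warning(self, caplog):
        img = _img([("p", 4, "RGB", "SV0", 10), ("p", 4, "RGB", "SV90", 12),
                    ("p", 5, "RGB", "SV0", 10), ("p", 5, "RGB", "SV90", 12),
                    ("p", 5, "RGB", "TV", 4)])
        with caplog.at_level("WARNING"):
            out = compute_psa(img, "RGB")
        assert out["p"].das.tolist() == [5]
        assert any("day dropped" in r.message for r in caplog.records)

    def test_simulator_round_trip(self, logistic_latents):
        model = ObservationModel(cv_rgb=0.0, cv_fluo=0.0, rgb_last_valid_das=30)
        imaging, _ = observe_experiment({"p": logistic_latents}, model)
        rgb = compute_psa(imaging, "RGB")["p"]
        truth = np.array([s.true_area for s in logistic_latents])
        np.testing.assert_allclose(rgb.psa, truth, rtol=1e-12)


class TestCalibration:
    def _pair(self, fluo_of_rgb, n=10, das=20):
        rng = np.random.default_rng(0)
        rgb, fluo = {}, {}
        for i in range(n):
            v = 50 + 20 * i + rng.uniform(0, 5)
            rgb[f"p{i}"] = _series([das], [v], f"p{i}")
            fluo[f"p{i}"] = _series([das], [fluo_of_rgb(v)], f"p{i}")
        return rgb, fluo

    def test_exact_double_gives_half_slope(self):
        rgb, fluo = self._pair(lambda v: 2 * v)
        fit = calibrate_hybrid(rgb, fluo, 20)
        assert fit.slope == pytest.approx(0.5, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)

    def test_identity_has_unit_r_squared(self):
        rgb, fluo = self._pair(lambda v: v)
        fit = calibrate_hybrid(rgb, fluo, 20)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        rgb, fluo = self._pair(lambda v: v, n=2)
        with pytest.raises(ValueError, match=">= 3"):
            calibrate_hybrid(rgb, fluo, 20)

    def test_zero_variance_fluo_rejected(self):
        rgb = {f"p{i}": _series([20], [50 + i], f"p{i}") for i in range(5)}
        fluo = {f"p{i}": _series([20], [100.0], f"p{i}") for i in range(5)}
        with pytest.raises(ValueError, match="variance"):
            calibrate_hybrid(rgb, fluo, 20)

    def test_recovers_generative_relation(self, control_genotype, no_salt):
        """FLUO = 5 + 1.5*RGB with 3% noise: fitted map close to the inverse
        over the range of areas the calibration sees."""
        rng = np.random.default_rng(42)
        latents = {
            f"p{i:03d}": simulate_growth(
                control_genotype, no_salt, days=22, plant_id=f"p{i:03d}",
                a0_scale=float(rng.lognormal(0, 0.4)), transp_cv=0.0)
            for i in range(150)
        }
        model = ObservationModel(fluo_intercept=5.0, fluo_slope=1.5,
                                 cv_rgb=0.03, cv_fluo=0.03, seed=9)
        imaging, _ = observe_experiment(latents, model)
        fluo = compute_psa(imaging, "FLUO")
        fit = calibrate_hybrid(compute_psa(imaging, "RGB"), fluo, 20)
        assert fit.slope == pytest.approx(1 / 1.5, rel=0.05)
        vals = np.array([s.at(20) for s in fluo.values()])
        grid = np.linspace(vals.min(), vals.max(), 25)
        np.testing.assert_allclose(fit(grid), (grid - 5.0) / 1.5, rtol=0.05)


class TestHybrid:
    def test_identity_calibration_identical_cameras(self):
        das = list(range(4, 31))
        psa = np.linspace(20, 200, len(das))
        rgb = {"p": _series(das, psa)}
        fluo = {"p": _series(das, psa)}
        fit = CalibrationFit(0.0, 1.0, 20, 5, 1.0)
        hybrid = build_hybrid_series(rgb, fluo, fit)["p"]
        np.testing.assert_allclose(hybrid.psa, psa, rtol=1e-12)

    def test_sources_switch_at_splice_day(self):
        das = list(range(10, 25))
        rgb = {"p": _series(das, np.linspace(10, 100, 15))}
        fluo = {"p": _series(das, np.linspace(10, 100, 15))}
        fit = CalibrationFit(0.0, 1.0, 20, 5, 1.0)
        hybrid = build_hybrid_series(rgb, fluo, fit)["p"]
        src = dict(zip(hybrid.das.tolist(), hybrid.source))
        assert src[19] == "RGB" and src[20] == "FLUO-calibrated"

    def test_covers_full_range_when_rgb_stops_at_19(self):
        rgb = {"p": _series(range(4, 20), np.linspace(10, 80, 16))}
        fluo = {"p": _series(range(4, 31), np.linspace(12, 220, 27))}
        fit = CalibrationFit(0.0, 1.0, 20, 5, 1.0)
        hybrid = build_hybrid_series(rgb, fluo, fit)["p"]
        assert hybrid.das.min() == 4 and hybrid.das.max() == 30


class TestRates:
    def test_linear_series_has_constant_agr(self):
        das = np.arange(0, 20)
        sm = fit_smoothing_spline(_series(das, 10 + 7.0 * das), df=5)
        sm = derive_rates(sm)
        np.testing.assert_allclose(sm.s_agr[1:], 7.0, atol=1e-6)
        assert np.all(np.diff(sm.s_rgr[1:]) < 0)  # RGR of a line decreases

    def test_exponential_series_has_constant_rgr(self):
        das = np.arange(0, 25)
        sm = fit_smoothing_spline(_series(das, 3.0 * np.exp(0.1 * das)), df=5)
        sm = derive_rates(sm)
        np.testing.assert_allclose(sm.s_rgr[1:], 0.1, atol=1e-6)

    def test_early_rgr_recovers_intrinsic_rate(self, control_genotype, no_salt):
        """Control genotype with r0=0.12: early-interval mean RGR within 10%."""
        states = simulate_growth(control_genotype, no_salt, days=30, transp_cv=0.0)
        das = np.array([s.das for s in states])
        psa = np.array([s.true_area for s in states])
        sm = derive_rates(fit_smoothing_spline(_series(das, psa), df=5))
        early = sm.s_rgr[(sm.das >= 1) & (sm.das <= 9)]
        assert np.nanmean(early) == pytest.approx(0.12, rel=0.10)

    def test_nonpositive_psa_rejected(self):
        s = _series([1, 2, 3, 4, 5], [1.0, 2.0, -1.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            derive_rates(fit_smoothing_spline(s, df=3))


class TestWater:
    def _watering(self, rows):
        return pd.DataFrame(rows, columns=["plant", "das", "weight_before_g",
                                           "weight_after_g", "water_added_mL"])

    def test_water_use_is_weight_difference(self):
        w = self._watering([("p", 0, 1900, 2000, 100), ("p", 1, 1850, 2000, 150)])
        ws = compute_water_use(w, df=2)
        assert ws["p"].water_use[1] == pytest.approx(150.0)

    def test_negative_use_becomes_missing(self, caplog):
        w = self._watering([("p", 0, 1900, 1800, 0), ("p", 1, 1900, 2000, 100)])
        with caplog.at_level("WARNING"):
            ws = compute_water_use(w, df=2)
        assert np.isnan(ws["p"].water_use[1])
        assert any("negative water-use" in r.message for r in caplog.records)

    def test_round_trip_recovers_transpiration(self, logistic_latents):
        _, watering = observe_experiment({"p": logistic_latents},
                                         ObservationModel())
        ws = compute_water_use(watering)["p"]
        transp = np.array([s.transpiration for s in logistic_latents[:-1]])
        np.testing.assert_allclose(ws.water_use[1:], transp, rtol=1e-12)

    def test_unordered_days_rejected(self):
        w = self._watering([("p", 1, 1900, 2000, 100), ("p", 1, 1850, 2000, 150)])
        with pytest.raises(ValueError):
            compute_water_use(w, df=2)


class TestWUI:
    def _smoothed_linear(self, slope=10.0, n=30):
        das = np.arange(0, n)
        sm = fit_smoothing_spline(_series(das, 5 + slope * das), df=5)
        return derive_rates(sm)

    def _water(self, das, use):
        from saltphenome.growthcurves import WaterSeries
        return WaterSeries(plant="p", das=np.asarray(das),
                           water_use=np.asarray(use, float))

    def test_daily_wui_is_agr_over_water(self):
        sm = self._smoothed_linear(slope=10.0)
        ws = self._water(sm.das, np.full(sm.das.size, 200.0))
        out = compute_wui(sm, ws)
        np.testing.assert_allclose(out.wui[1:], 0.05, atol=1e-6)

    def test_zero_water_day_gives_missing_not_inf(self):
        sm = self._smoothed_linear()
        use = np.full(sm.das.size, 200.0)
        use[5] = 0.0
        out = compute_wui(sm, self._water(sm.das, use))
        assert np.isnan(out.wui[5]) and np.isfinite(out.wui[6])

    def test_all_missing_water_rejected(self):
        sm = self._smoothed_linear()
        with pytest.raises(ValueError, match="all missing"):
            compute_wui(sm, self._water(sm.das, np.full(sm.das.size, np.nan)))

    def test_interval_wui_matches_definition(self):
        rng = np.random.default_rng(5)
        sm = self._smoothed_linear(slope=8.0)
        use = rng.uniform(100, 300, sm.das.size)
        ws = self._water(sm.das, use)
        got = interval_wui(sm, ws, 4, 9)
        expected = (sm.s_psa_at(9) - sm.s_psa_at(4)) / use[5:10].sum()
        assert got == pytest.approx(expected, abs=1e-9)


class TestIntervals:
    def _smoothed(self, n_plants=3):
        rng = np.random.default_rng(1)
        out = {}
        das = np.arange(0, 31)
        for i in range(n_plants):
            psa = 5 * np.exp(0.1 * das) * (1 + 0.02 * rng.standard_normal(das.size))
            out[f"p{i}"] = derive_rates(fit_smoothing_spline(
                _series(das, psa, f"p{i}"), df=5))
        return out

    def test_five_intervals_for_default_endpoints(self):
        summary = interval_summaries(self._smoothed(1), DEFAULT_ENDPOINTS)
        assert len(summary) == 5
        assert summary["interval"].tolist() == ["4-9", "9-14", "14-19", "19-23",
                                                "23-28"]

    def test_single_endpoint_gives_empty_summary(self):
        summary = interval_summaries(self._smoothed(1), (4,))
        assert summary.empty

    def test_telescoping_reconstructs_total_change(self):
        smoothed = self._smoothed(3)
        summary = interval_summaries(smoothed, DEFAULT_ENDPOINTS)
        for plant, sm in smoothed.items():
            rows = summary[summary["plant"] == plant]
            total = float(((rows["end"] - rows["start"]) * rows["agr_kpx_day"]).sum())
            assert total == pytest.approx(sm.s_psa_at(28) - sm.s_psa_at(4),
                                          abs=1e-9)

    def test_endpoint_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            interval_summaries(self._smoothed(1), (4, 40))


class TestHybridInvariance:
    def test_pipeline_identical_on_rgb_or_hybrid_when_cameras_agree(
            self, control_genotype, no_salt):
        """Noiseless, exactly linear cameras: AGR/RGR identical either way."""
        latents = {
            f"p{i}": simulate_growth(control_genotype, no_salt, days=30,
                                     plant_id=f"p{i}", a0_scale=1.0 + 0.2 * i,
                                     transp_cv=0.0)
            for i in range(5)
        }
        model = ObservationModel(fluo_intercept=3.0, fluo_slope=1.4,
                                 cv_rgb=0.0, cv_fluo=0.0, rgb_last_valid_das=30)
        imaging, _ = observe_experiment(latents, model)
        rgb = compute_psa(imaging, "RGB")
        fluo = compute_psa(imaging, "FLUO")
        fit = calibrate_hybrid(rgb, fluo, 20)
        hybrid = build_hybrid_series(rgb, fluo, fit)
        for p in latents:
            sm_h = derive_rates(fit_smoothing_spline(hybrid[p], df=5))
            sm_r = derive_rates(fit_smoothing_spline(rgb[p], df=5))
            np.testing.assert_allclose(sm_h.s_agr[1:], sm_r.s_agr[1:], rtol=1e-6)
            np.testing.assert_allclose(sm_h.s_rgr[1:], sm_r.s_rgr[1:], rtol=1e-6)
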