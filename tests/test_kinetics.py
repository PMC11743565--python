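import numpy as np
import pytest

from mfcbalance.kinetics import (
    ConcentrationSeries,
    align_series,
    fit_first_order,
    fits_table,
    infer_substrate_remaining,
    read_vfa_csv,
    windowed_rate,
)


def exponential_series(r0, k, times, species="acetate"):
    return ConcentrationSeries(times, r0 * np.exp(-k * np.asarray(times, float)),
                               species)


class TestFirstOrderFit:
    @pytest.mark.parametrize("k", [0.01, 0.0411, 0.0045])
    def test_noiseless_decay_recovered_exactly(self, k):
        """ln-linear OLS inverts R0*exp(-kt) to machine precision."""
        fit = fit_first_order(exponential_series(100.0, k, np.arange(0, 73, 3)))
        assert fit.k_per_h == pytest.approx(k, rel=1e-10)
        assert fit.ln_r0 == pytest.approx(np.log(100.0), rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series_has_zero_rate(self):
        fit = fit_first_order(ConcentrationSeries([0, 3, 6], [50, 50, 50], "acetate"))
        assert fit.k_per_h == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_points_below_detection_are_excluded_not_substituted(self):
        times = np.arange(0, 73, 3)
        values = 100.0 * np.exp(-0.05 * times)
        series = ConcentrationSeries(times, values, "acetate", detection_limit=0.2)
        fit = fit_first_order(series)
        assert fit.n_points == int(np.sum(values > 0.2))
        assert fit.k_per_h == pytest.approx(0.05, rel=1e-10)

    def test_too_few_usable_points_rejected_with_count(self):
        series = ConcentrationSeries([0, 3, 6, 9], [50.0, 0.1, 0.1, 0.05], "acetate")
        with pytest.raises(ValueError, match="got 1"):
            fit_first_order(series)

    def test_all_below_detection_rejected(self):
        with pytest.raises(ValueError, match="got 0"):
            fit_first_order(ConcentrationSeries([0, 3, 6], [0.1, 0.1, 0.1], "acetate"))

    def test_rescaling_only_shifts_intercept(self):
        times = np.arange(0, 48, 4)
        a = fit_first_order(exponential_series(100.0, 0.03, times))
        b = fit_first_order(exponential_series(700.0, 0.03, times))
        assert b.k_per_h == pytest.approx(a.k_per_h, rel=1e-10)
        assert b.ln_r0 - a.ln_r0 == pytest.approx(np.log(7.0), rel=1e-9)

    def test_noisy_recovery_has_small_median_bias(self):
        """5% multiplicative noise, n=20: median k-hat within 5% of truth."""
        rng = np.random.default_rng(42)
        k_true, times = 0.0411, np.linspace(0, 72, 20)
        rel_err = []
        for _ in range(200):
            values = 150.0 * np.exp(-k_true * times) * (
                1 + 0.05 * rng.standard_normal(times.size))
            fit = fit_first_order(ConcentrationSeries(times, np.abs(values), "acetate"))
            rel_err.append((fit.k_per_h - k_true) / k_true)
        assert abs(np.median(rel_err)) < 0.05


class TestWindowedRate:
    def test_two_point_consumption_slope(self):
        series = ConcentrationSeries([0.0, 24.0], [150.0, 100.0], "acetate")
        rate, direction = windowed_rate(series, 0.0, 24.0)
        assert rate == pytest.approx(50.0 / 24.0, rel=1e-9)
        assert direction == "consumption"

    def test_flat_series_rate_zero(self):
        series = ConcentrationSeries([0, 12, 24], [80.0, 80.0, 80.0], "acetate")
        rate, _ = windowed_rate(series, 0, 24)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_accumulation_reported_with_direction_flag(self):
        series = ConcentrationSeries([4.5, 28.0], [0.0, 22.6], "acetate")
        rate, direction = windowed_rate(series, 0.0, 30.0)
        assert rate == pytest.approx(0.96, abs=0.005)
        assert direction == "accumulation"

    def test_linearity_in_the_series(self):
        times = np.array([0.0, 6.0, 12.0, 24.0])
        a = ConcentrationSeries(times, [100, 90, 85, 60.0], "acetate")
        b = ConcentrationSeries(times, [40, 35, 20, 10.0], "propionate")
        total = ConcentrationSeries(times, a.values + b.values, "sum")
        ra = windowed_rate(a, 0, 24)[0]
        rb = windowed_rate(b, 0, 24)[0]
        rt = windowed_rate(total, 0, 24)[0]
        assert rt == pytest.approx(ra + rb, rel=1e-9)

    def test_too_few_points_rejected(self):
        series = ConcentrationSeries([0.0, 24.0], [150.0, 100.0], "acetate")
        with pytest.raises(ValueError, match=">=2"):
            windowed_rate(series, 5.0, 20.0)


class TestInferredSubstrate:
    def test_plain_subtraction(self, species_table):
        times = [0.0, 24.0]
        # 93.8 mg/L acetate ~ 100 mgCOD/L
        acetate = ConcentrationSeries(times, [0.0, 100.0 / species_table["acetate"].cod_per_mg],
                                      "acetate")
        remaining = infer_substrate_remaining(250.0, [acetate], species_table)
        assert remaining.values[0] == pytest.approx(250.0)
        assert remaining.values[1] == pytest.approx(150.0, rel=1e-9)
        assert remaining.unit == "mgCOD/L"
        assert not remaining.floored

    def test_no_accumulation_keeps_feed(self, species_table):
        acetate = ConcentrationSeries([0, 12, 24], [0.0, 0.0, 0.0], "acetate")
        remaining = infer_substrate_remaining(250.0, [acetate], species_table)
        np.testing.assert_allclose(remaining.values, 250.0)

    def test_overshoot_floors_at_zero_with_flag(self, species_table):
        acetate = ConcentrationSeries(
            [0.0, 24.0], [0.0, 260.0 / species_table["acetate"].cod_per_mg], "acetate")
        remaining = infer_substrate_remaining(250.0, [acetate], species_table)
        assert remaining.values[1] == 0.0
        assert remaining.floored

    def test_unknown_species_rejected(self, species_table):
        series = ConcentrationSeries([0.0, 24.0], [0.0, 5.0], "citrate")
        with pytest.raises(KeyError):
            infer_substrate_remaining(250.0, [series], species_table)

    def test_mg_l_mode_skips_cod_conversion(self, species_table):
        acetate = ConcentrationSeries([0.0, 24.0], [0.0, 100.0], "acetate")
        remaining = infer_substrate_remaining(250.0, [acetate], species_table,
                                              cod_units=False)
        assert remaining.values[1] == pytest.approx(150.0)

    def test_consumption_correction_restores_produced_pool(self, species_table):
        """If acetate is produced at p(t) and consumed at k*Ac, the corrected
        subtraction Ac + k*int(Ac) recovers cumulative production exactly."""
        k = 0.05
        times = np.linspace(0, 100, 201)
        # production p(t) = 2 mgCOD/L/h constant; Ac' = p - k Ac
        ac_cod = 2.0 / k * (1 - np.exp(-k * times))
        sp = species_table["acetate"]
        acetate = ConcentrationSeries(times, ac_cod / sp.cod_per_mg, "acetate")
        remaining = infer_substrate_remaining(250.0, [acetate], species_table,
                                              consumption_correction_k=k)
        produced = 2.0 * times
        np.testing.assert_allclose(250.0 - remaining.values, produced, atol=0.05)


class TestIO:
    def test_wide_csv_round_trip(self, tmp_path):
        path = tmp_path / "vfa.csv"
        path.write_text("time_h,acetate,propionate\n0,10.0,1.0\n24,5.0,2.0\n")
        series = read_vfa_csv(path)
        assert [s.species for s in series] == ["acetate", "propionate"]
        np.testing.assert_allclose(series[0].values, [10.0, 5.0])

    def test_missing_time_column_diagnosed(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("hours,acetate\n0,10.0\n")
        with pytest.raises(ValueError, match="time_h"):
            read_vfa_csv(path)

    def test_align_series_intersects_times(self):
        a = ConcentrationSeries([0, 12, 24], [1.0, 2.0, 3.0], "acetate")
        b = ConcentrationSeries([0, 24, 48], [4.0, 5.0, 6.0], "propionate")
        aa, bb = align_series([a, b])
        np.testing.assert_allclose(aa.times_h, [0, 24])
        np.testing.assert_allclose(bb.values, [4.0, 5.0])

    def test_fits_table_layout(self):
        fit = fit_first_order(exponential_series(100.0, 0.02, np.arange(0, 48, 4)))
        df = fits_table({"stirred_acetate/acetate_consumption": fit})
        assert list(df.columns) == ["condition", "pathway", "k_per_h", "stderr_k",
                                    "r_squared", "n_points"]
        assert df.loc[0, "condition"] == "stirred_acetate"
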