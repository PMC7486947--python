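import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beringmse import forcing as fc


def make_series(scenario, start, values_by_index):
    years = np.arange(start, start + len(next(iter(values_by_index.values()))))
    return fc.ClimateIndexSeries(scenario, years, {k: np.array(v, float) for k, v in values_by_index.items()})


class TestGenerator:
    def test_degenerate_generator_is_constant(self):
        cfg = fc.ForcingGeneratorConfig(
            hindcast_trend=0.0, temp_noise_sd=0.0, zoop_noise_sd=0.0,
            cold_pool_noise_sd=0.0,
            scenarios=[fc.ScenarioSpec("flat", warming_rate=0.0)],
        )
        hind, proj = fc.generate_forcing(cfg)
        assert np.all(hind.indices["bottom_temp"] == cfg.base_temp)
        assert np.all(proj.indices["bottom_temp"] == cfg.base_temp)

    def test_warming_brackets_in_expectation(self):
        """Trend-implied end-minus-start warming lands in the configured
        moderate (~1-2.5 degC) and high (~2-4.5 degC) tiers over ~80 yr."""
        cfg = fc.ForcingGeneratorConfig(
            temp_noise_sd=0.0, scenarios=[
                fc.ScenarioSpec("moderate", warming_rate=0.022),
                fc.ScenarioSpec("high", warming_rate=0.04),
            ],
        )
        _, mod, high = fc.generate_forcing(cfg)
        span = mod.years[-1] - mod.years[0]
        warm_mod = mod.indices["bottom_temp"][-1] - mod.indices["bottom_temp"][0]
        warm_high = high.indices["bottom_temp"][-1] - high.indices["bottom_temp"][0]
        assert span >= 80
        assert 1.0 <= warm_mod <= 2.5
        assert 2.0 <= warm_high <= 4.5

    def test_fixed_seed_reproducible(self):
        cfg = fc.ForcingGeneratorConfig(scenarios=[fc.ScenarioSpec("a", 0.03)], seed=7)
        r1 = fc.generate_forcing(cfg)
        r2 = fc.generate_forcing(cfg)
        for s1, s2 in zip(r1, r2):
            for k in s1.indices:
                np.testing.assert_array_equal(s1.indices[k], s2.indices[k])

    def test_zooplankton_declines_with_warming(self):
        cfg = fc.ForcingGeneratorConfig(
            temp_noise_sd=0.0, zoop_noise_sd=0.0,
            scenarios=[fc.ScenarioSpec("warm", warming_rate=0.05)],
        )
        _, warm = fc.generate_forcing(cfg)
        z = warm.indices["zoop_spring"]
        assert z[-1] < z[0]

    def test_temperature_trend_recovers_rate_as_noise_vanishes(self):
        cfg = fc.ForcingGeneratorConfig(
            temp_noise_sd=1e-6, scenarios=[fc.ScenarioSpec("w", warming_rate=0.03)]
        )
        _, w = fc.generate_forcing(cfg)
        slope = np.polyfit(w.years.astype(float), w.indices["bottom_temp"], 1)[0]
        assert slope == pytest.approx(0.03, abs=1e-6)

    def test_invalid_spans_rejected(self):
        with pytest.raises(fc.ForcingError):
            fc.ForcingGeneratorConfig(hindcast_start=2000, hindcast_end=1990)
        with pytest.raises(fc.ForcingError):
            fc.ForcingGeneratorConfig(temp_noise_sd=-1.0)


class TestBiasCorrect:
    cfg = fc.BiasCorrectionConfig(ref_start=2006, ref_end=2008)

    def test_identity_when_projection_equals_hindcast(self):
        hind = make_series("hindcast", 2006, {"bottom_temp": [1.0, 2.0, 3.0, 1.5]})
        fut = make_series("fut", 2006, {"bottom_temp": [1.0, 2.0, 3.0, 1.5]})
        out = fc.bias_correct(fut, hind, self.cfg)
        np.testing.assert_allclose(out.indices["bottom_temp"], fut.indices["bottom_temp"], atol=1e-12)

    def test_pure_shift_removed(self):
        base = [1.0, 2.0, 3.0, 2.5]
        hind = make_series("hindcast", 2006, {"bottom_temp": base})
        fut = make_series("fut", 2006, {"bottom_temp": [v + 3.0 for v in base]})
        out = fc.bias_correct(fut, hind, self.cfg)
        np.testing.assert_allclose(out.indices["bottom_temp"], base, atol=1e-12)

    def test_hand_computed_case(self):
        """hind ref {1,2,3}, fut ref {4,6,8}, fut value 10 -> 2 + (1/2)(10-6) = 4."""
        hind = make_series("hindcast", 2006, {"bottom_temp": [1.0, 2.0, 3.0]})
        fut = make_series("fut", 2006, {"bottom_temp": [4.0, 6.0, 8.0, 10.0]})
        out = fc.bias_correct(fut, hind, self.cfg)
        assert out.indices["bottom_temp"][-1] == pytest.approx(4.0, abs=1e-12)

    @given(
        shift=st.floats(-5, 5), scale=st.floats(0.2, 4.0),
        seed=st.integers(0, 1000),
    )
    def test_reference_moments_and_idempotence(self, shift, scale, seed):
        """Corrected series reproduces hindcast ref mean/SD to 1e-10 and a
        second application is a no-op."""
        rng = np.random.default_rng(seed)
        hind = make_series("hindcast", 2000, {"bottom_temp": rng.normal(1, 1, 18)})
        fut_vals = shift + scale * rng.normal(1, 1, 30)
        fut = make_series("fut", 2000, {"bottom_temp": fut_vals})
        cfg = fc.BiasCorrectionConfig(ref_start=2005, ref_end=2016)
        out = fc.bias_correct(fut, hind, cfg)
        ref = np.isin(out.years, cfg.ref_years)
        href = np.isin(hind.years, cfg.ref_years)
        target_mean = np.mean(hind.indices["bottom_temp"][href])
        target_sd = np.std(hind.indices["bottom_temp"][href], ddof=1)
        assert abs(np.mean(out.indices["bottom_temp"][ref]) - target_mean) <= 1e-10 * max(1, abs(target_mean))
        assert abs(np.std(out.indices["bottom_temp"][ref], ddof=1) - target_sd) <= 1e-10 * target_sd
        twice = fc.bias_correct(out, hind, cfg)
        np.testing.assert_allclose(
            twice.indices["bottom_temp"], out.indices["bottom_temp"], rtol=1e-12, atol=1e-12
        )

    def test_degenerate_projection_variance_rejected(self):
        hind = make_series("hindcast", 2006, {"bottom_temp": [1.0, 2.0, 3.0]})
        fut = make_series("fut", 2006, {"bottom_temp": [5.0, 5.0, 5.0]})
        with pytest.raises(fc.ForcingError, match="degenerate"):
            fc.bias_correct(fut, hind, self.cfg)

    def test_missing_reference_years_rejected(self):
        hind = make_series("hindcast", 2006, {"bottom_temp": [1.0, 2.0, 3.0]})
        fut = make_series("fut", 2010, {"bottom_temp": [1.0, 2.0, 3.0]})
        with pytest.raises(fc.ForcingError, match="reference years"):
            fc.bias_correct(fut, hind, self.cfg)

    def test_cold_pool_clipped_into_bounds(self, caplog):
        import logging

        hind = make_series("hindcast", 2006, {"cold_pool": [0.2, 0.5, 0.8]})
        fut = make_series("fut", 2006, {"cold_pool": [0.4, 0.45, 0.5, 0.9]})
        with caplog.at_level(logging.WARNING):
            out = fc.bias_correct(fut, hind, self.cfg)
        assert np.all(out.indices["cold_pool"] <= 1.0)
        assert any("clipped" in r.getMessage() for r in caplog.records)


class TestPersistence:
    def test_constant_at_reference_mean(self):
        hind = make_series("hindcast", 2006, {"bottom_temp": [1.5, 1.9, 1.7]})
        cfg = fc.BiasCorrectionConfig(ref_start=2006, ref_end=2008)
        pers = fc.make_persistence(hind, cfg, np.arange(2018, 2031))
        assert pers.scenario_id == "persistence"
        np.testing.assert_allclose(pers.indices["bottom_temp"], 1.7, atol=1e-12)
        assert np.ptp(pers.indices["bottom_temp"]) == 0.0

    def test_empty_projection_rejected(self):
        hind = make_series("hindcast", 2006, {"bottom_temp": [1.5, 1.9, 1.7]})
        with pytest.raises(fc.ForcingError):
            fc.make_persistence(hind, fc.BiasCorrectionConfig(2006, 2008), np.array([]))


class TestSeriesValidation:
    def test_non_contiguous_years_rejected(self):
        with pytest.raises(fc.ForcingError):
            fc.ClimateIndexSeries("x", np.array([2000, 2002]), {"bottom_temp": np.array([1.0, 2.0])})

    def test_cold_pool_bounds_enforced(self):
        with pytest.raises(fc.ForcingError):
            fc.ClimateIndexSeries("x", np.array([2000, 2001]), {"cold_pool": np.array([0.5, 1.4])})

    def test_roundtrip_through_long_frame(self):
        s = make_series("abc", 2000, {"bottom_temp": [1.0, 2.0], "cold_pool": [0.1, 0.2]})
        back = fc.ClimateIndexSeries.from_frame(s.to_frame(), "abc")
        np.testing.assert_array_equal(back.years, s.years)
        for k in s.indices:
            np.testing.assert_array_equal(back.indices[k], s.indices[k])
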