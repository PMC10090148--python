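"""Benefit-transfer cleaning, discounting algebra, SCC resolution, costs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from escost.synthetic import (generate_country_table, generate_scc_table,
                              generate_valuation_records)
from escost.valuation import (CarbonPrice, HabitatServiceValue, PriceScheme,
                              clean_records, climate_cost, discount_hsv,
                              floor_costs, habitat_baseline, habitat_cost,
                              national_factor, prolongate_hsv, resolve_scc)


def records(values, service="recreation", biome="tropical rain forest"):
    return pd.DataFrame({
        "service": service, "biome": biome,
        "value_usd_per_ha_yr": list(values),
        "year": 2000,
    })


class TestCleaning:
    def test_drop_report_matches_injection_truth(self):
        raw, truth = generate_valuation_records(n=246, n_duplicates=10,
                                                n_missing=5, seed=6)
        cleaned, report = clean_records(raw)
        assert report["n_missing"] == truth["n_missing"] == 5
        assert report["n_duplicates"] == truth["n_duplicates"] == 10
        assert report["n_climate_regulation"] == truth["n_climate"]
        assert report["n_provisioning"] == truth["n_provisioning"]
        assert report["n_retained"] == len(cleaned)
        total = sum(report[k] for k in ("n_missing", "n_duplicates",
                                        "n_climate_regulation",
                                        "n_provisioning", "n_outlier_trimmed",
                                        "n_retained"))
        assert total == report["n_input"]

    def test_injected_outliers_all_trimmed(self):
        # few enough outliers that all of them fall above the 95% quantile
        raw, truth = generate_valuation_records(n=400, outlier_fraction=0.02,
                                                seed=7)
        cleaned, _ = clean_records(raw)
        out_vals = raw.loc[truth["outlier_rows"], "value_usd_per_ha_yr"]
        assert not cleaned["value_usd_per_ha_yr"].isin(out_vals).any()

    def test_quantile_band_100_distinct_keeps_90(self):
        vals = np.sort(np.random.default_rng(1).lognormal(5, 2, 100))
        cleaned, report = clean_records(records(vals))
        assert report["n_outlier_trimmed"] == 10
        # exactly the 5th..94th order statistics survive (inclusive band)
        assert np.array_equal(np.sort(cleaned["value_usd_per_ha_yr"]),
                              vals[5:95])

    def test_only_excluded_services_is_error(self):
        raw = records([10, 20, 30], service="food")
        with pytest.raises(ValueError, match="service exclusions"):
            clean_records(raw)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            clean_records(pd.DataFrame({"service": ["a"]}))

    def test_second_pass_drops_no_categorical_rows(self):
        """After one pass no missing/duplicate/excluded rows remain."""
        raw, _ = generate_valuation_records(n=246, seed=6)
        cleaned, _ = clean_records(raw)
        _, report2 = clean_records(cleaned)
        assert report2["n_missing"] == 0
        assert report2["n_duplicates"] == 0
        assert report2["n_climate_regulation"] == 0
        assert report2["n_provisioning"] == 0

    def test_idempotent_on_constant_values(self):
        df = records([5.0] * 40)
        df["year"] = np.arange(1960, 2000)  # distinct rows, constant values
        cleaned, report = clean_records(df)
        assert report["n_outlier_trimmed"] == 0
        assert len(cleaned) == 40


class TestHabitatBaseline:
    def test_single_biome_single_service(self):
        assert habitat_baseline(records([10, 20])) == pytest.approx(15.0)

    def test_mean_of_per_biome_sums(self):
        df = pd.concat([records([100], biome="A"), records([300], biome="B")],
                       ignore_index=True)
        assert habitat_baseline(df) == pytest.approx(200.0)

    def test_three_by_three_spreadsheet_oracle(self):
        rng = np.random.default_rng(17)
        rows = []
        for b in "ABC":
            for s in ("s1", "s2", "s3"):
                for v in rng.lognormal(3, 1, rng.integers(1, 5)):
                    rows.append((s, b, v, 2000))
        df = pd.DataFrame(rows, columns=["service", "biome",
                                         "value_usd_per_ha_yr", "year"])
        expected = np.mean([
            sum(df[(df.biome == b) & (df.service == s)]
                ["value_usd_per_ha_yr"].mean()
                for s in df[df.biome == b]["service"].unique())
            for b in "ABC"])
        assert habitat_baseline(df) == pytest.approx(expected, rel=1e-12)

    def test_inflation_factor_scales(self):
        df = records([10, 20])
        assert habitat_baseline(df, 1.1) == pytest.approx(16.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            habitat_baseline(records([]))


class TestDiscountingAlgebra:
    def test_prolongation_factor(self):
        assert prolongate_hsv(100.0, 0.02) == pytest.approx(
            100.0 * 1.02 ** 16, rel=1e-12)

    def test_discount_factor(self):
        assert discount_hsv(100.0, 0.02) == pytest.approx(
            100.0 / 1.02 ** 70, rel=1e-12)

    @pytest.mark.parametrize("fn", [prolongate_hsv, discount_hsv])
    def test_zero_rate_identity_and_zero_value(self, fn):
        assert fn(123.4, 0.0) == pytest.approx(123.4)
        assert fn(0.0, 0.05) == 0.0

    @pytest.mark.parametrize("fn", [prolongate_hsv, discount_hsv])
    def test_negative_rate_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(100.0, -0.01)

    @settings(derandomize=True, deadline=None)
    @given(st.floats(0.01, 1e5), st.floats(0, 0.1), st.integers(1, 100))
    def test_compose_to_identity_over_equal_spans(self, hsv, d, span):
        assert discount_hsv(prolongate_hsv(hsv, d, span), d, span) == \
            pytest.approx(hsv, rel=1e-9)

    def test_resolved_hsv_orderings(self):
        h = HabitatServiceValue.resolve(100.0, 0.02)
        assert h.hsv_historical > h.hsv_2015 > h.hsv_future
        h0 = HabitatServiceValue.resolve(100.0, 0.0)
        assert h0.hsv_historical == h0.hsv_2015 == h0.hsv_future


class TestResolveSCC:
    def make_table(self, values):
        rows = []
        for (year, rate), vs in values.items():
            for i, v in enumerate(vs):
                rows.append((year, "SSP1", rate, f"DF{i+1}", v))
        return pd.DataFrame(rows, columns=["year", "ssp", "discount_rate",
                                           "damage_function",
                                           "scc_usd_per_tco2"])

    def test_damage_function_mean(self):
        t = self.make_table({(2015, 0.02): [10, 20, 30],
                             (2085, 0.02): [40, 50, 60]})
        p = resolve_scc(t, "SSP1", discounted=True)
        assert p.scc_historical == pytest.approx(20.0)
        assert p.scc_future == pytest.approx(50.0)

    def test_undiscounted_holds_2085_value_constant(self):
        t = self.make_table({(2085, 0.0): [75.0]})
        p = resolve_scc(t, "SSP1", discounted=False)
        assert p.scc_historical == p.scc_future == pytest.approx(75.0)

    def test_missing_cell_names_gap(self):
        t = self.make_table({(2015, 0.02): [10.0]})
        with pytest.raises(ValueError, match="2085"):
            resolve_scc(t, "SSP1", discounted=True)

    def test_generated_table_resolves(self):
        scc = generate_scc_table(seed=3)
        disc = resolve_scc(scc, "SSP3", discounted=True)
        undisc = resolve_scc(scc, "SSP3", discounted=False)
        assert disc.scc_future > disc.scc_historical   # SCC rises over time
        assert undisc.scc_historical == undisc.scc_future
        # the lower the rate, the higher the cost
        assert undisc.scc_future > disc.scc_future


class TestCosts:
    def test_no_discounting_full_stability_costs_nothing(self):
        hsv = HabitatServiceValue.resolve(1000.0, 0.0)
        assert habitat_cost(100.0, hsv) == pytest.approx(0.0)

    def test_no_discounting_partial_stability(self):
        hsv = HabitatServiceValue.resolve(1000.0, 0.0)
        assert habitat_cost(60.0, hsv) == pytest.approx(400.0)

    def test_discounted_cost_positive_even_at_full_stability(self):
        hsv = HabitatServiceValue.resolve(100.0, 0.02)
        cost = habitat_cost(100.0, hsv)
        assert cost == pytest.approx(100 * 1.02 ** 16 - 100 / 1.02 ** 70,
                                     rel=1e-9)
        assert cost > 0

    @settings(derandomize=True, deadline=None)
    @given(st.floats(0, 100))
    def test_discounted_cost_positive_for_all_stability(self, s):
        hsv = HabitatServiceValue.resolve(500.0, 0.02)
        assert habitat_cost(s, hsv) > 0

    def test_strictly_decreasing_in_stability(self):
        hsv = HabitatServiceValue.resolve(500.0, 0.02)
        s = np.linspace(0, 100, 101)
        costs = habitat_cost(s, hsv)
        assert np.all(np.diff(costs) < 0)

    def test_stability_out_of_range_rejected(self):
        hsv = HabitatServiceValue.resolve(500.0, 0.0)
        with pytest.raises(ValueError):
            habitat_cost(101.0, hsv)

    def test_climate_cost_cases(self):
        p = CarbonPrice(50.0, 50.0, "SSP1", 0.0)
        assert climate_cost(10.0, 10.0, p) == pytest.approx(0.0)
        assert climate_cost(10.0, 8.0, p) == pytest.approx(100.0)
        raw = climate_cost(8.0, 10.0, p)
        assert raw < 0 and floor_costs(raw) == 0.0

    def test_climate_cost_increasing_in_decline(self):
        p = CarbonPrice(50.0, 50.0, "SSP1", 0.0)
        declines = np.linspace(-2, 2, 41)
        costs = climate_cost(10.0, 10.0 - declines, p)
        assert np.all(np.diff(costs) > 0)

    def test_non_finite_rejected(self):
        p = CarbonPrice(50.0, 50.0, "SSP1", 0.0)
        with pytest.raises(ValueError):
            climate_cost(np.nan, 1.0, p)


class TestPriceSchemes:
    def test_national_factor_examples(self):
        assert national_factor(10_000, 10_000) == pytest.approx(1.0)
        assert national_factor(20_000, 10_000) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            national_factor(-1.0, 10_000)

    def test_nine_country_factors_equal_hand_ratios(self):
        tab = generate_country_table(seed=5)
        scheme = PriceScheme.resolve("national", tab)
        for row in tab.itertuples():
            assert scheme.factors[row.country] == pytest.approx(
                row.gdp_per_capita / row.world_gdp_per_capita)

    def test_global_mode_is_all_ones(self):
        tab = generate_country_table(seed=5)
        scheme = PriceScheme.resolve("global", tab)
        assert np.allclose(scheme.factors.to_numpy(), 1.0)

    def test_factor_map_lookup(self):
        tab = generate_country_table(("AA", "BB"), seed=1)
        tab.loc[0, "gdp_per_capita"] = 2 * tab.loc[0, "world_gdp_per_capita"]
        tab.loc[1, "gdp_per_capita"] = tab.loc[1, "world_gdp_per_capita"]
        scheme = PriceScheme.resolve("national", tab)
        cmap = np.array([[0, 1], [1, 0]])
        fmap = scheme.factor_map(cmap, ("AA", "BB"))
        assert np.allclose(fmap, [[2.0, 1.0], [1.0, 2.0]])
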