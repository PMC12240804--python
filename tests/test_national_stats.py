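import numpy as np
import pandas as pd
import pytest

from regrowage.national_stats import (
    DEFAULT_BINS,
    age_distribution,
    country_summary,
    project_carbon,
    regional_summary,
    share_ratio,
    tabulate_by_country,
)
from regrowage.stack_io import AgeMap, GeoRef
from regrowage.synthetic_landscape import SimConfig, make_countries, simulate_stack
from regrowage.age_mapping import compute_age

from conftest import N, R, U, stack_from_sequences

GEOREF = GeoRef((30.0, 0.0, 0.0, 0.0, -30.0, 0.0), "synthetic")


def age_map(ages, pixel_area=1.0):
    return AgeMap(2023, np.asarray(ages, dtype=np.int16), GEOREF, pixel_area)


class TestTabulate:
    def test_single_country_tally(self):
        ages = np.zeros((4, 4), int)
        ages[0, :3] = 3
        ages[1, 0] = 3
        amap = age_map(ages, pixel_area=0.09)
        table = tabulate_by_country(amap, np.zeros((4, 4), int))
        assert len(table) == 1
        assert table.area_ha.iloc[0] == pytest.approx((ages == 3).sum() * 0.09)

    def test_two_country_split_conserves_total(self, rng):
        ages = rng.integers(0, 35, (10, 10))
        ages[(ages > 0) & (ages < 3)] = 0
        countries = (np.arange(100).reshape(10, 10) % 2)
        table = tabulate_by_country(age_map(ages), countries)
        assert table.area_ha.sum() == pytest.approx(float((ages > 0).sum()))

    def test_matches_brute_force_on_voronoi_countries(self):
        cfg = SimConfig(shape=(32, 32), n_countries=3, seed=13)
        stack, _ = simulate_stack(cfg)
        amap = compute_age(stack)
        _, craster, names = make_countries(cfg)
        table = tabulate_by_country(amap, craster, country_names=names)
        # brute force
        expect = {}
        for i in range(32):
            for j in range(32):
                a = int(amap.ages[i, j])
                if a > 0:
                    key = (names[int(craster[i, j])], a)
                    expect[key] = expect.get(key, 0.0) + cfg.pixel_area
        got = {(r.country, r.age): r.area_ha for r in table.itertuples()}
        assert set(got) == set(expect)
        for k in expect:
            assert got[k] == pytest.approx(expect[k])

    def test_unassigned_pixels_are_tallied(self):
        ages = np.full((2, 2), 5)
        countries = np.array([[0, 0], [-1, -1]])
        table = tabulate_by_country(age_map(ages), countries)
        assert set(table.country) == {"C000", "unassigned"}
        assert table.area_ha.sum() == pytest.approx(4.0)


class TestShareRatio:
    def test_equal_shares_give_unit_ratio(self):
        s = pd.DataFrame({"country": ["A", "B"], "total_area": [10.0, 30.0],
                          "old_area": [1.0, 3.0]})
        out = share_ratio(s)
        assert np.allclose(out.ratio, 1.0)

    def test_two_country_toy(self):
        # A: old 2 of 2 total; B: old 0 of 2 -> ratio_A = (2/2)/(2/4) = 2
        s = pd.DataFrame({"country": ["A", "B"], "total_area": [2.0, 2.0],
                          "old_area": [2.0, 0.0]})
        out = share_ratio(s).set_index("country")
        assert out.loc["A", "ratio"] == pytest.approx(2.0)
        assert (out.all_share * out.ratio).sum() == pytest.approx(1.0)

    def test_ratio_identity_and_scale_invariance(self, rng):
        for _ in range(10):
            n = rng.integers(2, 30)
            total = rng.random(n) * 100 + 0.1
            old = total * rng.random(n)
            s = pd.DataFrame({"country": [f"C{i}" for i in range(n)],
                              "total_area": total, "old_area": old})
            out = share_ratio(s)
            assert (out.all_share * out.ratio).sum() == pytest.approx(1.0, abs=1e-12)
            out2 = share_ratio(s.assign(total_area=total * 7.3, old_area=old * 7.3))
            assert np.allclose(out.ratio, out2.ratio)

    def test_zero_old_area_rejected(self):
        s = pd.DataFrame({"country": ["A"], "total_area": [1.0], "old_area": [0.0]})
        with pytest.raises(ValueError, match="old"):
            share_ratio(s)


class TestRegionalSummary:
    def test_one_region_share_is_100(self):
        table = pd.DataFrame({"country": ["A"], "region": ["Americas"],
                              "age": [4], "area_ha": [10.0]})
        out = regional_summary(table)
        assert out.all_share_pct.iloc[0] == 100

    def test_published_regional_areas_reproduce_shares(self):
        reg = pd.DataFrame({
            "region": ["Americas", "Asia-Pacific", "Africa"],
            "total_area": [21.5, 19.4, 9.8],   # Mha
            "old_area": [1.9, 0.9, 0.2],
        })
        out = regional_summary(reg).set_index("region")
        assert out.loc["Americas", "all_share_pct"] == 42
        assert out.loc["Asia-Pacific", "all_share_pct"] == 38
        assert out.loc["Africa", "all_share_pct"] == 19
        assert out.loc["Americas", "old_share_pct"] == 63
        assert out.loc["Africa", "old_share_pct"] == 7

    def test_moments_from_long_table(self):
        # two age-years, equal areas: mean 5, sd 2, lower median 3
        table = pd.DataFrame({"country": ["A", "A"], "region": ["r", "r"],
                              "age": [3, 7], "area_ha": [1.0, 1.0]})
        out = regional_summary(table)
        assert out.mean_age.iloc[0] == pytest.approx(5.0)
        assert out.sd_age.iloc[0] == pytest.approx(2.0)
        assert out.median_age.iloc[0] == 3.0


class TestCountrySummary:
    def test_old_young_partition(self):
        table = pd.DataFrame({
            "country": ["A"] * 3, "region": ["r"] * 3,
            "age": [4, 19, 25], "area_ha": [2.0, 1.0, 1.0]})
        out = country_summary(table)
        assert out.total_area.iloc[0] == pytest.approx(4.0)
        assert out.old_area.iloc[0] == pytest.approx(1.0)
        assert out.young_area.iloc[0] == pytest.approx(2.0)
        # old + ages 3..19 = total
        assert out.old_area.iloc[0] + 3.0 == pytest.approx(out.total_area.iloc[0])


class TestAgeDistribution:
    def test_all_area_in_first_bin(self):
        table = pd.DataFrame({"country": ["A"], "region": ["r"],
                              "age": [4], "area_ha": [9.0]})
        out = age_distribution(table)
        assert out.loc[out.bin == "3-5", "area_ha"].iloc[0] == pytest.approx(9.0)
        assert out.area_ha.sum() == pytest.approx(9.0)

    def test_bin_areas_sum_to_regional_totals(self, rng):
        ages = rng.integers(3, 35, size=50)
        table = pd.DataFrame({"country": "A", "region": "r",
                              "age": ages, "area_ha": rng.random(50)})
        out = age_distribution(table)
        assert out.area_ha.sum() == pytest.approx(table.area_ha.sum())

    def test_deforestation_timing_toy_stack(self):
        # events (into NONFOREST) in 2017, 2018, 2019 -> lookbacks 6, 5, 4
        seqs = [
            [U] * 27 + [N] * 7,            # U->N at 2017: lookback 6
            [U] * 28 + [N] * 6,            # 2018: lookback 5
            [U] * 29 + [N] * 5,            # 2019: lookback 4
        ]
        stack = stack_from_sequences(seqs)
        table = pd.DataFrame({"country": ["A"], "region": ["all"],
                              "age": [4], "area_ha": [1.0]})
        out = age_distribution(table, stack=stack, target_year=2023)
        t = out.set_index("bin").defor_proportion
        assert t["3-5"] == pytest.approx(2 / 3)
        assert t["6-10"] == pytest.approx(1 / 3)
        assert out.defor_proportion.sum() == pytest.approx(1.0)

    def test_overlapping_bins_rejected(self):
        table = pd.DataFrame({"country": ["A"], "region": ["r"],
                              "age": [4], "area_ha": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            age_distribution(table, bins=((3, 5), (5, 10)))


class TestCarbon:
    def test_single_pixel_arithmetic(self):
        amap = age_map([[4]], pixel_area=1.0)
        est = project_carbon(amap, np.array([[4.0]]), horizon=25)
        assert est.total_gtc == pytest.approx(1.0e-7)  # 100 MgC

    def test_linear_in_rates(self, rng):
        ages = rng.integers(0, 10, (8, 8))
        rates = rng.random((8, 8)) * 5
        amap = age_map(ages, pixel_area=0.09)
        e1 = project_carbon(amap, rates)
        e2 = project_carbon(amap, rates * 2)
        assert e2.total_gtc == pytest.approx(2 * e1.total_gtc)

    def test_matches_pixel_loop_oracle(self, rng):
        ages = rng.integers(0, 35, (12, 12))
        rates = rng.random((12, 12)) * 6
        amap = age_map(ages, pixel_area=0.09)
        est = project_carbon(amap, rates, horizon=25, young_age_max=5)
        total = 0.0
        for i in range(12):
            for j in range(12):
                if 3 <= ages[i, j] <= 5:
                    total += rates[i, j] * 0.09 * 25
        assert est.total_gtc == pytest.approx(total / 1e9)

    def test_negative_rates_rejected(self):
        amap = age_map([[4]])
        with pytest.raises(ValueError, match="negative|non-negative"):
            project_carbon(amap, np.array([[-1.0]]))

    def test_per_country_breakdown_sums_to_total(self, rng):
        ages = rng.integers(0, 10, (10, 10))
        rates = rng.random((10, 10))
        countries = (np.arange(100).reshape(10, 10) % 3)
        est = project_carbon(age_map(ages), rates, country_raster=countries)
        assert est.by_country.carbon_gtc.sum() == pytest.approx(est.total_gtc)
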