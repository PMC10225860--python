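"""Sampling-day metrics, Welch comparison, taxonomic coverage, SII, boosts."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from siicov.metrics import (
    NEWLY_COVERED,
    MetricError,
    active_deployment_days,
    compare_day_distributions,
    coverage_boost_percent,
    national_sii,
    sii_series,
    species_sii_mean,
    species_sii_year,
    taxonomic_coverage_cell,
    taxonomic_coverage_delta,
    unique_sampling_days_occurrences,
)
from tests.conftest import make_presence


def occ_frame(rows):
    """rows of (cell_id, date_str) -> minimal occurrence record frame."""
    df = pd.DataFrame(rows, columns=["cell_id", "date"])
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["day_resolution"] = True
    return df


def dep_frame(rows):
    """rows of (cell_id, start, end) -> minimal deployment frame."""
    df = pd.DataFrame(rows, columns=["cell_id", "start_date", "end_date"])
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


class TestOccurrenceSamplingDays:
    def test_five_records_one_date_count_one(self, grid10):
        out = unique_sampling_days_occurrences(
            occ_frame([(3, "2020-05-05")] * 5), grid10
        )
        assert out.to_dict("records") == [
            {"cell_id": 3, "year": 2020, "n_unique_days": 1}
        ]

    def test_three_distinct_dates(self, grid10):
        rows = [(3, "2020-05-05"), (3, "2020-05-06"), (3, "2020-07-01")]
        out = unique_sampling_days_occurrences(occ_frame(rows), grid10)
        assert out.loc[0, "n_unique_days"] == 3

    def test_random_fixture_matches_distinct_date_tally(self, grid10, rng):
        rows = [
            (int(rng.integers(5)), f"2020-0{rng.integers(1, 10)}-0{rng.integers(1, 10)}")
            for _ in range(200)
        ]
        out = unique_sampling_days_occurrences(occ_frame(rows), grid10)
        want = {}
        for cell, date in rows:
            want.setdefault((cell, 2020), set()).add(date)
        got = {(r.cell_id, r.year): r.n_unique_days for r in out.itertuples()}
        assert got == {k: len(v) for k, v in want.items()}


class TestActiveDeploymentDays:
    def test_single_deployment_inclusive_endpoints(self, grid10):
        out = active_deployment_days(
            dep_frame([(2, "2020-01-01", "2020-01-10")]), grid10
        )
        assert out.loc[0, "n_unique_days"] == 10

    def test_overlapping_deployments_union(self, grid10):
        rows = [(2, "2020-01-01", "2020-01-10"), (2, "2020-01-05", "2020-01-15")]
        out = active_deployment_days(dep_frame(rows), grid10)
        assert out.loc[0, "n_unique_days"] == 15

    def test_year_straddling_deployment_splits_by_calendar_year(self, grid10):
        out = active_deployment_days(
            dep_frame([(2, "2019-12-28", "2020-01-03")]), grid10
        )
        got = {(r.year): r.n_unique_days for r in out.itertuples()}
        assert got == {2019: 4, 2020: 3}

    def test_random_deployments_match_date_enumeration_oracle(self, grid10, rng):
        rows = []
        for _ in range(40):
            start = dt.date(2019, 1, 1) + dt.timedelta(days=int(rng.integers(0, 500)))
            end = start + dt.timedelta(days=int(rng.integers(0, 90)))
            rows.append((int(rng.integers(4)), start.isoformat(), end.isoformat()))
        out = active_deployment_days(dep_frame(rows), grid10)
        want: dict = {}
        for cell, start, end in rows:
            d = dt.date.fromisoformat(start)
            while d <= dt.date.fromisoformat(end):
                want.setdefault((cell, d.year), set()).add(d)
                d += dt.timedelta(days=1)
        got = {(r.cell_id, r.year): r.n_unique_days for r in out.itertuples()}
        assert got == {k: len(v) for k, v in want.items()}


class TestWelchComparison:
    def test_identical_samples_give_zero_statistic(self):
        r = compare_day_distributions([3, 9, 12, 30], [3, 9, 12, 30])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_equal_n_equal_variance_df_reduces_to_pooled(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [11.0, 12.0, 13.0, 14.0]  # same sample variance
        r = compare_day_distributions(a, b)
        assert r.df == pytest.approx(len(a) + len(b) - 2)

    def test_random_samples_match_direct_formula_and_scipy(self, rng):
        for _ in range(30):
            a = rng.gamma(2.0, 10.0, size=int(rng.integers(5, 60)))
            b = rng.gamma(4.0, 25.0, size=int(rng.integers(5, 60)))
            r = compare_day_distributions(a, b)
            sea, seb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            t_direct = (a.mean() - b.mean()) / math.sqrt(sea + seb)
            df_direct = (sea + seb) ** 2 / (
                sea**2 / (a.size - 1) + seb**2 / (b.size - 1)
            )
            assert r.t == pytest.approx(t_direct, abs=1e-9)
            assert r.df == pytest.approx(df_direct, abs=1e-9)
            t_sp, p_sp = stats.ttest_ind(a, b, equal_var=False)
            assert r.t == pytest.approx(t_sp, abs=1e-9)
            assert r.p == pytest.approx(p_sp, abs=1e-9)

    def test_antisymmetric_under_sample_swap(self, rng):
        a = rng.poisson(12, 40).astype(float)
        b = rng.poisson(92, 40).astype(float)
        r1 = compare_day_distributions(a, b)
        r2 = compare_day_distributions(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.df == pytest.approx(r2.df)
        assert r1.p == pytest.approx(r2.p)

    def test_threshold_shares(self):
        a = [10, 30, 31, 200]
        b = [101, 99, 5, 5]
        r = compare_day_distributions(a, b)
        assert r.share_a_low == 0.5 and r.share_a_high == 0.25
        assert r.share_b_low == 0.5 and r.share_b_high == 0.25

    def test_degenerate_samples_rejected(self):
        with pytest.raises(MetricError):
            compare_day_distributions([5, 5, 5], [9, 9, 9])
        with pytest.raises(MetricError):
            compare_day_distributions([5], [1, 2, 3])


class TestTaxonomicCoverage:
    def test_full_coverage(self):
        pct, _ = taxonomic_coverage_cell({"a", "b"}, {"a", "b", "c"})
        assert pct == 100.0

    def test_half_coverage(self):
        expected = {f"s{i}" for i in range(10)}
        observed = {f"s{i}" for i in range(5)}
        pct, unexpected = taxonomic_coverage_cell(expected, observed)
        assert pct == 50.0 and unexpected == set()

    def test_unexpected_species_reported_not_counted(self):
        pct, unexpected = taxonomic_coverage_cell({"a"}, {"b"})
        assert pct == 0.0 and unexpected == {"b"}

    def test_random_sets_match_intersection_oracle(self, rng):
        for _ in range(50):
            expected = {f"s{i}" for i in rng.integers(0, 30, rng.integers(1, 20))}
            observed = {f"s{i}" for i in rng.integers(0, 30, rng.integers(0, 20))}
            pct, _ = taxonomic_coverage_cell(expected, observed)
            assert pct == pytest.approx(
                100.0 * len(observed & expected) / len(expected)
            )

    def test_delta_examples_and_superset_guard(self):
        expected = {f"s{i}" for i in range(10)}
        base = {f"s{i}" for i in range(5)}
        assert taxonomic_coverage_delta(expected, base, base) == 0.0
        assert taxonomic_coverage_delta(expected, base, base | {"s5"}) == (
            pytest.approx(10.0)
        )
        with pytest.raises(MetricError):
            taxonomic_coverage_delta(expected, base, {"s0"})

    def test_empty_expected_set_rejected(self):
        with pytest.raises(MetricError):
            taxonomic_coverage_cell(set(), {"a"})


class TestSpeciesSII:
    def test_definitional_half_coverage(self, grid10):
        presence = make_presence(
            grid10, {("Nesomys rufus", c, 2021) for c in range(5)}
        )
        sii, e, o, outside = species_sii_year(range(10), presence, "Nesomys rufus", 2021)
        assert (sii, e, o, outside) == (0.5, 10, 5, 0)

    def test_year_without_observations_scores_zero(self, grid10):
        presence = make_presence(grid10, set())
        sii, _, o, _ = species_sii_year(range(10), presence, "Nesomys rufus", 2021)
        assert sii == 0.0 and o == 0

    def test_single_cell_of_nineteen(self, grid10):
        presence = make_presence(grid10, {("Nesomys rufus", 7, 2021)})
        sii, e, o, _ = species_sii_year(range(19), presence, "Nesomys rufus", 2021)
        assert e == 19 and o == 1
        assert sii == pytest.approx(1 / 19)

    def test_presence_outside_range_excluded_and_flagged(self, grid10):
        presence = make_presence(
            grid10, {("Nesomys rufus", 3, 2021), ("Nesomys rufus", 50, 2021)}
        )
        sii, _, o, outside = species_sii_year(
            range(10), presence, "Nesomys rufus", 2021
        )
        assert o == 1 and outside == 1
        assert sii == pytest.approx(0.1)

    def test_empty_expected_range_is_an_error_not_zero(self, grid10):
        presence = make_presence(grid10, set())
        with pytest.raises(MetricError, match="empty expected cell set"):
            species_sii_year([], presence, "Nesomys rufus", 2021)


class TestWindowMean:
    def test_constant_series(self):
        assert species_sii_mean({y: 0.3 for y in range(2010, 2023)}) == (
            pytest.approx(0.3)
        )

    def test_zero_years_included_not_skipped(self):
        assert species_sii_mean({2020: 1.0}, window=(2020, 2021)) == 0.5

    def test_random_series_matches_mean_oracle(self, rng):
        vals = {y: float(rng.random()) for y in range(2010, 2023) if rng.random() < 0.6}
        got = species_sii_mean(vals, (2010, 2022))
        want = np.mean([vals.get(y, 0.0) for y in range(2010, 2023)])
        assert got == pytest.approx(want)


class TestNationalSII:
    def test_single_species_country_equals_species_mean(self, grid10):
        presence = make_presence(
            grid10, {("Nesomys rufus", c, y) for c in range(5) for y in (2020, 2021)}
        )
        nat = national_sii(
            "MDG", {"Nesomys rufus": range(10)}, presence, window=(2020, 2021)
        )
        series = sii_series(range(10), presence, "Nesomys rufus", (2020, 2021))
        assert nat.mean_sii == pytest.approx(series.mean) == pytest.approx(0.5)
        assert nat.n_species == 1

    def test_two_species_average(self, grid10):
        presence = make_presence(
            grid10,
            {("A a", c, 2020) for c in range(2)} | {("B b", c, 2020) for c in range(4)},
        )
        nat = national_sii(
            "XYZ", {"A a": range(10), "B b": range(10)}, presence, window=(2020, 2020)
        )
        assert nat.mean_sii == pytest.approx((0.2 + 0.4) / 2)

    def test_removing_a_source_never_raises_national_value(self, grid10, rng):
        species = [f"S {i}" for i in range(4)]
        ranges = {sp: set(range(12)) for sp in species}
        occ = {
            (sp, int(rng.integers(12)), 2020 + int(rng.integers(2)))
            for sp in species
            for _ in range(3)
        }
        ct = {
            (sp, int(rng.integers(12)), 2020 + int(rng.integers(2)))
            for sp in species
            for _ in range(2)
        }
        base = make_presence(grid10, occ, "occ")
        both = make_presence(grid10, occ | ct, "occ+ct")
        n_base = national_sii("XYZ", ranges, base, (2020, 2021))
        n_both = national_sii("XYZ", ranges, both, (2020, 2021))
        assert n_both.mean_sii >= n_base.mean_sii

    def test_no_expected_species_rejected(self, grid10):
        presence = make_presence(grid10, set())
        with pytest.raises(MetricError, match="non-empty clipped range"):
            national_sii("XYZ", {"A a": set()}, presence)


class TestCoverageBoost:
    def test_no_change_is_zero_percent(self):
        assert coverage_boost_percent(0.3, 0.3) == 0.0

    def test_ten_percent_gain(self):
        assert coverage_boost_percent(0.05, 0.055) == pytest.approx(10.0)

    def test_zero_baseline_yields_sentinel_not_infinity(self):
        assert coverage_boost_percent(0.0, 0.01) is NEWLY_COVERED
        assert coverage_boost_percent(0.0, 0.0) == 0.0

    def test_combined_below_base_is_an_upstream_bug(self):
        with pytest.raises(MetricError):
            coverage_boost_percent(0.5, 0.4)


class TestAggregationProperties:
    def test_order_of_aggregation_coincides(self, grid10, rng):
        """Species-then-window mean equals year-then-species mean because
        zero-observation years are included, never skipped."""
        species = [f"S {i}" for i in range(5)]
        window = (2018, 2022)
        ranges = {sp: set(range(10)) for sp in species}
        triples = {
            (sp, int(rng.integers(10)), int(rng.integers(2018, 2023)))
            for sp in species
            for _ in range(rng.integers(0, 8))
        }
        presence = make_presence(grid10, triples)
        route_a = np.mean(
            [sii_series(ranges[sp], presence, sp, window).mean for sp in species]
        )
        per_year = [
            np.mean(
                [
                    species_sii_year(ranges[sp], presence, sp, y)[0]
                    for sp in species
                ]
            )
            for y in range(window[0], window[1] + 1)
        ]
        assert route_a == pytest.approx(np.mean(per_year))

    def test_merged_sii_bounded_by_sum_of_parts(self, grid10, rng):
        for _ in range(30):
            a = {("S", int(rng.integers(10)), 2020) for _ in range(rng.integers(0, 6))}
            b = {("S", int(rng.integers(10)), 2020) for _ in range(rng.integers(0, 6))}
            pa = make_presence(grid10, a, "a")
            pb = make_presence(grid10, b, "b")
            pu = make_presence(grid10, a | b, "u")
            su = species_sii_year(range(10), pu, "S", 2020)[0]
            sa = species_sii_year(range(10), pa, "S", 2020)[0]
            sb = species_sii_year(range(10), pb, "S", 2020)[0]
            assert max(sa, sb) <= su <= sa + sb
            assert 0.0 <= su <= 1.0
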