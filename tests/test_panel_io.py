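import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from washtrends import (
    Dialect,
    LoadReport,
    PanelFormatError,
    aggregate_basic_or_higher,
    carry_democracy_2006_to_2000,
    read_access_panel,
    read_covariates,
    read_result_table,
    write_result_table,
)

from conftest import write_csv

PERCENT = Dialect(rate_unit="percent")


class TestReadAccessPanel:
    def test_percent_rates_rescaled_to_proportions_once(self, access_csv):
        panel, report = read_access_panel(access_csv, PERCENT)
        alb = panel[
            (panel.country_code == "ALB") & (panel.year == 2000) & (panel.ladder == "at_least_basic")
        ]
        assert alb.rate.iloc[0] == pytest.approx(0.882)
        assert report.n_read == 7
        assert ((panel.rate >= 0) & (panel.rate <= 1)).all()

    @pytest.mark.parametrize(
        "row,match",
        [
            ("ALB,2000,drinking_water,total,basic,101.0", "outside"),
            ("ALB,2000,drinking_water,total,basic,-1.0", "outside"),
            ("ALB,2000,sanitation,total,surface_water,10.0", "incompatible"),
            ("ALB,2000,drinking_water,total,open_defecation,10.0", "incompatible"),
            ("ALB,2000,drinking_water,total,basic,abc", "cannot parse"),
            ("ALB,2000,drinking_water,coastal,basic,10.0", "invalid area"),
        ],
    )
    def test_invalid_rows_rejected_with_line_number(self, tmp_path, row, match):
        path = write_csv(tmp_path / "bad.csv", f"country_code,year,service,area,ladder,rate\n{row}")
        with pytest.raises(PanelFormatError, match=match) as err:
            read_access_panel(path, PERCENT)
        assert "line 2" in str(err.value) or "duplicate" in str(err.value)

    def test_duplicate_key_rejected(self, tmp_path):
        path = write_csv(
            tmp_path / "dup.csv",
            "country_code,year,service,area,ladder,rate\n"
            "ALB,2000,drinking_water,total,basic,10.0\n"
            "ALB,2000,drinking_water,total,basic,11.0",
        )
        with pytest.raises(PanelFormatError, match="duplicate"):
            read_access_panel(path, PERCENT)

    def test_header_only_file_yields_empty_panel(self, tmp_path):
        path = write_csv(tmp_path / "empty.csv", "country_code,year,service,area,ladder,rate")
        panel, report = read_access_panel(path, PERCENT)
        assert len(panel) == 0 and report.n_read == 0

    def test_missing_rates_dropped_and_counted(self, tmp_path):
        path = write_csv(
            tmp_path / "miss.csv",
            "country_code,year,service,area,ladder,rate\n"
            "ALB,2000,drinking_water,total,basic,10.0\n"
            "BEN,2000,drinking_water,total,basic,",
        )
        panel, report = read_access_panel(path, PERCENT)
        assert len(panel) == 1 and report.n_dropped_missing == 1

    def test_relaxed_bounds_dialect_accepts_rates_just_outside_unit(self, tmp_path):
        path = write_csv(
            tmp_path / "noisy.csv",
            "country_code,year,service,area,ladder,rate\n"
            "ALB,2000,drinking_water,total,at_least_basic,1.02",
        )
        panel, _ = read_access_panel(path, Dialect(strict_bounds=False))
        assert panel.rate.iloc[0] == pytest.approx(1.02)


class TestReadCovariates:
    def test_raw_scale_values_kept(self, tmp_path):
        path = write_csv(
            tmp_path / "cov.csv",
            "country_code,year,factor,value\n"
            "JPN,2020,gdp_pc,39918.0\n"
            "JPN,2020,urban_pop_rate,91.8",
        )
        cov, report = read_covariates(path)
        assert cov.set_index("factor").loc["gdp_pc", "value"] == 39918.0
        assert cov.set_index("factor").loc["urban_pop_rate", "value"] == 91.8
        assert report.n_read == 2

    def test_nonpositive_log_factor_excluded_with_warning(self, tmp_path):
        path = write_csv(
            tmp_path / "cov.csv",
            "country_code,year,factor,value\nXXX,2020,gdp_pc,-5\nJPN,2020,gdp_pc,100",
        )
        with pytest.warns(UserWarning, match="non-positive"):
            cov, report = read_covariates(path)
        assert list(cov.country_code) == ["JPN"]
        assert report.n_excluded_nonpositive == 1

    def test_urban_rate_outside_percent_range_rejected(self, tmp_path):
        path = write_csv(
            tmp_path / "cov.csv", "country_code,year,factor,value\nJPN,2020,urban_pop_rate,120"
        )
        with pytest.raises(PanelFormatError, match="urban_pop_rate"):
            read_covariates(path)


class TestCarryDemocracy:
    def cov(self, rows):
        return pd.DataFrame(rows, columns=["country_code", "year", "factor", "value"])

    def test_2006_value_copied_to_2000(self):
        cov = self.cov([("ALB", 2006, "democracy_index", 5.91)])
        out, n = carry_democracy_2006_to_2000(cov)
        assert n == 1
        carried = out[(out.year == 2000) & (out.factor == "democracy_index")]
        assert carried.value.iloc[0] == 5.91

    def test_existing_2000_value_untouched_and_no_2006_means_no_carry(self):
        cov = self.cov(
            [
                ("ALB", 2000, "democracy_index", 4.0),
                ("ALB", 2006, "democracy_index", 5.91),
                ("BEN", 2010, "democracy_index", 3.0),
            ]
        )
        out, n = carry_democracy_2006_to_2000(cov)
        assert n == 0
        assert out[(out.country_code == "ALB") & (out.year == 2000)].value.iloc[0] == 4.0
        assert not ((out.country_code == "BEN") & (out.year == 2000)).any()

    @settings(deadline=None, max_examples=25)
    @given(
        years=st.lists(st.sampled_from([2000, 2006, 2010]), min_size=0, max_size=6),
        n_other=st.integers(0, 5),
    )
    def test_non_democracy_records_never_change(self, years, n_other):
        rows = [(f"C{i}", y, "democracy_index", 5.0) for i, y in enumerate(years)]
        rows += [(f"G{i}", 2000, "gdp_pc", 100.0) for i in range(n_other)]
        out, _ = carry_democracy_2006_to_2000(self.cov(rows))
        assert (out.factor != "democracy_index").sum() == n_other


class TestAggregateBasicOrHigher:
    def panel(self, rows):
        return pd.DataFrame(
            [
                {"country_code": c, "year": y, "service": "drinking_water", "area": "total",
                 "ladder": lad, "rate": r}
                for c, y, lad, r in rows
            ]
        )

    def test_sum_of_disjoint_levels_when_no_cumulative_row(self):
        out = aggregate_basic_or_higher(
            self.panel([("A", 2000, "safely_managed", 0.60), ("A", 2000, "basic", 0.25)])
        )
        assert len(out) == 1 and out.rate.iloc[0] == pytest.approx(0.85)

    def test_cumulative_row_preferred_when_present(self):
        out = aggregate_basic_or_higher(
            self.panel(
                [
                    ("A", 2000, "at_least_basic", 0.85),
                    ("A", 2000, "safely_managed", 0.60),
                    ("A", 2000, "basic", 0.25),
                ]
            )
        )
        assert out.rate.iloc[0] == pytest.approx(0.85)

    def test_sum_components_policy_always_sums(self):
        out = aggregate_basic_or_higher(
            self.panel(
                [
                    ("A", 2000, "at_least_basic", 0.99),
                    ("A", 2000, "safely_managed", 0.60),
                    ("A", 2000, "basic", 0.25),
                ]
            ),
            policy="sum_components",
        )
        assert out.rate.iloc[0] == pytest.approx(0.85)

    def test_sum_exceeding_one_signals_double_counting(self):
        with pytest.raises(PanelFormatError, match="exceeds 1"):
            aggregate_basic_or_higher(
                self.panel([("A", 2000, "safely_managed", 0.7), ("A", 2000, "basic", 0.4)])
            )

    def test_one_output_row_per_complete_key(self):
        panel = self.panel(
            [
                ("A", 2000, "safely_managed", 0.6),
                ("A", 2000, "basic", 0.2),
                ("A", 2020, "at_least_basic", 0.9),
                ("B", 2000, "safely_managed", 0.5),  # no basic, no cumulative: skipped
            ]
        )
        out = aggregate_basic_or_higher(panel)
        assert len(out) == 2
        assert set(zip(out.country_code, out.year)) == {("A", 2000), ("A", 2020)}

    def test_existing_basic_or_higher_rows_not_duplicated(self):
        panel = self.panel(
            [("A", 2000, "at_least_basic", 0.85), ("A", 2000, "basic_or_higher", 0.85)]
        )
        assert len(aggregate_basic_or_higher(panel)) == 0


class TestResultTableRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        table = pd.DataFrame(
            {
                "parameter": ["year_dummy", "gdp_pc"],
                "mean": [-0.54, 1.0699999999],
                "cri_low": [-0.86, 0.85],
                "cri_high": [-0.22, 1.30],
                "rhat": [1.001, 1.002],
                "significant": [True, True],
                "n_countries": [147, 147],
            }
        )
        path = tmp_path / "table.csv"
        write_result_table(table, path)
        back = read_result_table(path)
        pd.testing.assert_frame_equal(table, back)

    def test_empty_table_round_trips_header_only(self, tmp_path):
        table = pd.DataFrame(columns=["parameter", "mean"])
        path = tmp_path / "empty.csv"
        write_result_table(table, path)
        assert path.read_text().strip() == "parameter,mean"
        assert list(read_result_table(path).columns) == ["parameter", "mean"]
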