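"""Window selection and the proportionate redistribution cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from roadmort.io import KEY_COLUMNS
from roadmort.redistribution import (
    RedistributedTable,
    WindowRule,
    redistribute_all,
    redistribute_category,
    select_window,
)
from roadmort.taxonomy import NonspecificCategory as NC, categorize

from conftest import ALL_FRACTIONS, toy_table


class TestSelectWindow:
    @pytest.mark.parametrize(
        "p,width",
        [(0.0, 1), (0.299, 1), (0.30, 3), (0.45, 3), (0.49, 3),
         (0.50, 5), (0.69, 5), (0.70, 7), (1.0, 7)],
    )
    def test_nominal_widths_and_threshold_ties(self, p, width):
        years = range(2000, 2031)
        assert len(select_window(p, 2015, years)) == width

    def test_same_year_window(self):
        assert select_window(0.25, 2017, range(2015, 2021)) == (2017,)

    def test_three_year_window(self):
        assert select_window(0.45, 2017, range(2015, 2021)) == (2016, 2017, 2018)

    def test_missing_nominal_year_falls_back_to_all_available(self):
        assert select_window(0.72, 2016, {2015, 2016, 2018}) == (2015, 2016, 2018)

    def test_partially_missing_window_also_falls_back(self):
        # 3-year window needs 2014, which is missing -> all available years
        assert select_window(0.35, 2015, {2015, 2016, 2017, 2018}) == (
            2015, 2016, 2017, 2018,
        )

    def test_empty_available_years_errors(self):
        with pytest.raises(ValueError, match="empty"):
            select_window(0.2, 2015, [])

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError, match="proportion"):
            select_window(1.2, 2015, [2015])

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_rule(self, a, b):
        lo, hi = sorted((a, b))
        years = range(1990, 2041)
        assert len(select_window(lo, 2015, years)) <= len(
            select_window(hi, 2015, years)
        )

    def test_non_monotone_rule_rejected(self):
        with pytest.raises(ValueError, match="monotone|non-decreasing"):
            WindowRule(half_widths=(2, 1, 0, 3))


class TestRedistributeCategory:
    def test_proportional_split_same_year(self, registry):
        # stratum garbage G=10, targets A:60 B:40 -> +6 and +4
        t = toy_table(
            [("A", 2015, "male", "0-4", "I21", 60.0),
             ("A", 2015, "male", "0-4", "C34", 40.0),
             ("A", 2015, "male", "0-4", "R99", 10.0)]
        )
        delta, un = redistribute_category(t, NC.ILL_DEFINED, registry)
        got = delta.set_index("cause")["deaths"]
        assert got["I21"] == pytest.approx(6.0)
        assert got["C34"] == pytest.approx(4.0)
        assert un.empty

    def test_zero_garbage_zero_delta(self, registry):
        t = toy_table([("A", 2015, "male", "0-4", "I21", 60.0)])
        delta, un = redistribute_category(t, NC.ILL_DEFINED, registry)
        assert delta.empty and un.empty

    def test_pooled_window_weights(self, registry):
        """G=10 at 31% garbage share uses a 3-year pool {A:30,B:10,C:0}."""
        rows = [
            # study year: garbage share 31/100 -> 3-year window
            ("X", 2016, "male", "0-4", "I21", 14.0),
            ("X", 2016, "male", "0-4", "C34", 5.0),
            ("X", 2016, "male", "0-4", "W13", 50.0),
            ("X", 2016, "male", "0-4", "R99", 31.0),
            ("X", 2015, "male", "0-4", "I21", 10.0),
            ("X", 2015, "male", "0-4", "C34", 5.0),
            ("X", 2017, "male", "0-4", "I21", 6.0),
        ]
        t = toy_table(rows)
        delta, _ = redistribute_category(t, NC.ILL_DEFINED, registry)
        got = delta.groupby("cause")["deaths"].sum()
        # pooled weights: I21 30, C34 10, W13 50 -> shares 1/3, 1/9, 5/9 of 31
        assert got["I21"] == pytest.approx(31 * 30 / 90)
        assert got["C34"] == pytest.approx(31 * 10 / 90)
        assert delta["year"].unique().tolist() == [2016]

    def test_fallback_ladder_pools_sexes_then_everything(self, registry):
        # male 0-4 stratum has no targets; females in 0-4 do
        t = toy_table(
            [("A", 2015, "male", "0-4", "R99", 10.0),
             ("A", 2015, "female", "0-4", "I21", 5.0)]
        )
        delta, un = redistribute_category(t, NC.ILL_DEFINED, registry)
        assert un.empty
        assert delta["deaths"].sum() == pytest.approx(10.0)
        # mass stays in the male 0-4 stratum, cause taken from the pooled sexes
        assert (delta["sex"] == "male").all()

    def test_unallocated_when_no_targets_anywhere(self, registry):
        t = toy_table([("A", 2015, "male", "0-4", "R99", 10.0)])
        delta, un = redistribute_category(t, NC.ILL_DEFINED, registry)
        assert delta.empty
        assert un["deaths"].sum() == pytest.approx(10.0)


def _cell_diff(a, b):
    s1 = a.set_index(KEY_COLUMNS)["deaths"]
    s2 = b.set_index(KEY_COLUMNS)["deaths"]
    both = pd.concat([s1.rename("a"), s2.rename("b")], axis=1).fillna(0.0)
    return (both["a"] - both["b"]).abs().max()


class TestCascade:
    def test_garbage_free_table_is_fixpoint(self, registry):
        t = toy_table(
            [("A", 2015, "male", "0-4", "I21", 60.0),
             ("A", 2015, "male", "0-4", "V43", 40.0)]
        )
        red = redistribute_all(t, registry)
        pd.testing.assert_frame_equal(red.table, t)
        assert red.provenance.empty and red.unallocated.empty

    def test_inverse_oracle_small(self, det_panel, registry):
        red = redistribute_all(
            det_panel.observed, registry, WindowRule.same_year(), include_level5=True
        )
        assert _cell_diff(red.table, det_panel.truth) < 1e-9

    def test_output_contains_no_processed_garbage(self, det_panel, registry):
        red = redistribute_all(det_panel.observed, registry, include_level5=True)
        cats = categorize(red.table["cause"], registry)
        assert (cats == NC.NONE).all()

    def test_level5_moves_mass_only_within_road_traffic(self, det_panel, registry):
        from roadmort.trends import road_traffic_series

        l4 = redistribute_all(det_panel.observed, registry, include_level5=False)
        l5 = redistribute_all(det_panel.observed, registry, include_level5=True)
        # V87-type rows survive in the level-4 output
        cats4 = categorize(l4.table["cause"], registry)
        assert (cats4 == NC.UNSPEC_RT).any()
        rt4 = road_traffic_series(l4.table, registry)
        rt5 = road_traffic_series(l5.table, registry)
        assert np.allclose(rt4.values, rt5.reindex(rt4.index).values)

    def test_conservation_and_ledger(self, det_panel, registry):
        obs = det_panel.observed
        red = redistribute_all(obs, registry, include_level5=True)
        before = obs.groupby(["country", "year"])["deaths"].sum()
        after = red.table.groupby(["country", "year"])["deaths"].sum()
        un = (
            red.unallocated.groupby(["country", "year"])["deaths"].sum()
            if len(red.unallocated) else 0.0
        )
        total_after = after.add(un, fill_value=0.0) if np.ndim(un) else after
        assert (before - total_after.reindex(before.index)).abs().max() < 1e-9
        # provenance + unallocated account for every garbage death per category
        cats = categorize(obs["cause"], registry)
        for cat in ALL_FRACTIONS:
            g = obs[cats == cat]["deaths"].sum()
            prov = red.provenance[red.provenance["category"] == cat.name]["deaths"].sum()
            unc = (
                red.unallocated[red.unallocated["category"] == cat.name]["deaths"].sum()
                if len(red.unallocated) else 0.0
            )
            assert prov + unc == pytest.approx(g, rel=1e-9)

    def test_corrected_rt_never_below_uncorrected(self, det_panel, registry):
        from roadmort.trends import road_traffic_series

        red = redistribute_all(det_panel.observed, registry, include_level5=True)
        before = road_traffic_series(det_panel.observed, registry)
        after = road_traffic_series(red.table, registry)
        assert (after.reindex(before.index) - before).min() > -1e-9

    def test_strata_none_allocates_at_country_year_level(self, registry):
        t = toy_table(
            [("A", 2015, "male", "0-4", "I21", 30.0),
             ("A", 2015, "female", "5-9", "I21", 70.0),
             ("A", 2015, "male", "0-4", "R99", 10.0)]
        )
        red = redistribute_all(t, registry, strata="none")
        added = red.provenance.groupby(["sex", "age_group"], observed=True)["deaths"].sum()
        assert added[("male", "0-4")] == pytest.approx(3.0)
        assert added[("female", "5-9")] == pytest.approx(7.0)
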