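import math

import numpy as np
import pytest

from plastexpo.deterministic import (
    category_exposure_range,
    format_sig2,
    migration_sensitivity,
    moe,
    table3_report,
)
from plastexpo.survey import summarize


class TestMoe:
    @pytest.mark.parametrize(
        "rfd, dose, expected",
        [
            (3.0, 7.3e-3, 4.1e2),    # toilet DEHP
            (15.0, 4.9e-7, 3.1e7),   # shoes DINP
            (2.0, 2.0, 1.0),
        ],
    )
    def test_reference_dose_over_dose(self, rfd, dose, expected):
        assert moe(rfd, dose) == pytest.approx(expected, rel=0.05)

    def test_zero_dose_is_undefined_not_infinite(self):
        assert moe(3.0, 0.0) is None

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            moe(0.0, 1.0)
        with pytest.raises(ValueError):
            moe(3.0, -1.0)


class TestCategoryExposureRange:
    def test_absent_chemical_yields_empty_result(self, filtered_survey, factors):
        assert category_exposure_range(filtered_survey, "DEP", "mat", factors) == []

    def test_non_mouthing_category_has_no_ingestion_route(
        self, filtered_survey, factors
    ):
        res = category_exposure_range(filtered_survey, "DEHP", "toilet", factors)
        routes = {r.route for r in res}
        assert routes == {"dermal", "total"}
        by = {(r.route, r.scenario): r.dose for r in res}
        assert by[("total", "max")] == by[("dermal", "max")]

    def test_total_is_route_sum_and_linearity_anchor(
        self, filtered_survey, factors
    ):
        res = category_exposure_range(filtered_survey, "DEHP", "accessories", factors)
        by = {(r.route, r.scenario): r.dose for r in res}
        assert by[("total", "max")] == pytest.approx(
            by[("ingestion", "max")] + by[("dermal", "max")], rel=1e-12
        )
        # 22.90% w/w maximum scales the 8.6e-6 @ 0.01% anchor by 2290
        assert by[("dermal", "max")] == pytest.approx(8.6e-6 * 2290, rel=1e-6)

    def test_all_below_one_percent_collapses_ingestion_range(
        self, filtered_survey, factors
    ):
        # accessories DBP maximum is 0.35% w/w: both scenarios use MR 0.1
        res = category_exposure_range(filtered_survey, "DBP", "accessories", factors)
        by = {(r.route, r.scenario): r.dose for r in res}
        assert by[("ingestion", "max")] == by[("ingestion", "min")]


class TestTable3Report:
    def test_covers_the_21_reportable_pairs(self, filtered_survey, factors):
        report = table3_report(filtered_survey, factors)
        pairs = set(zip(report["category"], report["chemical"]))
        assert len(pairs) == 21
        # cells whose maximum sits exactly at the inclusion threshold
        # fall out of the deterministic assessment
        assert ("mat", "DBP") not in pairs
        assert ("stationery", "DIBP") not in pairs
        assert ("toilet", "DEHP") in pairs

    def test_totals_equal_route_sums_unrounded(self, filtered_survey, factors):
        report = table3_report(filtered_survey, factors)
        for _, row in report.iterrows():
            for scen in ("max", "min"):
                ing = 0.0 if math.isnan(row[f"ingestion_{scen}"]) \
                    else row[f"ingestion_{scen}"]
                assert row[f"total_{scen}"] == pytest.approx(
                    ing + row[f"dermal_{scen}"], rel=1e-12
                )

    def test_moe_at_max_never_exceeds_moe_at_min(self, filtered_survey, factors):
        report = table3_report(filtered_survey, factors)
        assert (report["moe_max"] <= report["moe_min"] + 1e-12).all()

    def test_dermal_range_ratio_equals_concentration_ratio(
        self, filtered_survey, factors
    ):
        report = table3_report(filtered_survey, factors).set_index(
            ["category", "chemical"]
        )
        conc = {(s.category, s.chemical): s.conc_max
                for s in summarize(filtered_survey)}
        for key in [("shoes", "DBP"), ("mat", "DEHP"), ("accessories", "DINP"),
                    ("toy", "DEHA")]:
            row = report.loc[key]
            assert row["dermal_max"] / row["dermal_min"] == pytest.approx(
                conc[key] / 100.0, rel=1e-9
            )

    def test_empty_survey_empty_report(self, factors):
        assert table3_report([], factors).empty

    def test_low_moe_rows_are_flagged(self, filtered_survey, factors):
        report = table3_report(filtered_survey, factors)
        expected = report["moe_max"] < 100.0
        assert (report["flagged"] == expected).all()


class TestMigrationSensitivity:
    def test_span_across_cem_levels_is_exactly_1e5(self, filtered_survey, factors):
        rep = migration_sensitivity(filtered_survey, factors)
        for _, grp in rep[rep.mr_kind == "assigned"].groupby(
            ["category", "chemical"]
        ):
            doses = grp.set_index("mr")["ingestion_dose"]
            assert doses[10.0] / doses[1e-4] == pytest.approx(1e5, rel=1e-12)

    def test_experimental_mr_lowers_dinp_dose_by_expected_ratio(
        self, filtered_survey, factors
    ):
        rep = migration_sensitivity(
            filtered_survey, factors, experimental_mr=8.3e-2
        )
        cell = rep[(rep.category == "toy") & (rep.chemical == "DINP")]
        assigned = cell[(cell.mr_kind == "assigned") & (cell.mr == 10.0)]
        experimental = cell[cell.mr_kind == "experimental"]
        ratio = float(assigned.ingestion_dose.iloc[0]
                      / experimental.ingestion_dose.iloc[0])
        assert ratio == pytest.approx(10 / 0.083, rel=1e-9)

    def test_single_level_degenerates_to_one_ingestion_column(
        self, filtered_survey, factors
    ):
        rep = migration_sensitivity(filtered_survey, factors, levels=[0.1])
        assert set(rep["mr"]) == {0.1}
        assert np.allclose(rep["ingestion_dose"], rep["ingestion_dose"].iloc[0])

    def test_only_mouthing_categories_present(self, filtered_survey, factors):
        rep = migration_sensitivity(filtered_survey, factors)
        assert set(rep["category"]) == {"accessories", "stationery", "toy"}


def test_two_significant_figure_formatting():
    assert format_sig2(0.0173118) == "1.7e-02"
    assert format_sig2(None) == ""
    assert format_sig2(float("nan")) == ""
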