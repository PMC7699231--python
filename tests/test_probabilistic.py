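import math
import warnings

import numpy as np
import pytest

from plastexpo.dermal import content_to_cart, dermal_daily_dose, dermal_intermediates
from plastexpo.chemistry import get_chemical
from plastexpo.ingestion import assign_migration_rate, ingestion_daily_dose
from plastexpo.probabilistic import (
    AgeGroupProfile,
    DistributionSpec,
    default_profiles,
    fit_concentration_distribution,
    run_mc,
    summarize_mc,
)
from plastexpo.survey import CATEGORIES, Measurement, ProductRecord


def _point(v):
    return DistributionSpec("point", {"value": v})


def _toy(product_id, chem_conc):
    meas = {c: Measurement(v, True) for c, v in chem_conc.items()}
    return ProductRecord(product_id, "toy", "", meas)


class TestDistributionSpec:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("weibull", {"k": 1})

    def test_truncated_normal_respects_bounds(self):
        spec = DistributionSpec(
            "truncated_normal", {"mean": 1.0, "sd": 5.0}
        )
        x = spec.sample(np.random.default_rng(0), 5000)
        assert (x >= 0).all() and (x <= 16.0).all()

    def test_point_mass(self):
        x = _point(4.2).sample(np.random.default_rng(0), 7)
        assert (x == 4.2).all()


class TestConcentrationFit:
    def test_all_nondetect_sample_collapses_to_half_loq_point(self):
        recs = [
            ProductRecord(f"p{i}", "mat", "", {"DEHP": Measurement(None, False)})
            for i in range(5)
        ]
        spec = fit_concentration_distribution(recs, "DEHP", "mat")
        assert spec.kind == "point"
        assert spec.params["value"] == pytest.approx(16.25)

    def test_log_moment_match_recovers_log_mean(self):
        recs = [_toy(f"p{i}", {"DEHP": c}) for i, c in enumerate([100, 1000, 10000])]
        spec = fit_concentration_distribution(recs, "DEHP", "toy")
        assert spec.kind == "lognormal"
        assert spec.params["mu"] == pytest.approx(math.log(1000.0))
        logs = np.log([100.0, 1000.0, 10000.0])
        assert spec.params["sigma"] == pytest.approx(logs.std(ddof=1))

    def test_unmeasured_products_count_as_nondetects(self):
        recs = [_toy("p0", {"DEHP": 1000.0}),
                ProductRecord("p1", "toy", "", {})]
        spec = fit_concentration_distribution(recs, "DEHP", "toy")
        expected = np.log([1000.0, 16.25])
        assert spec.params["mu"] == pytest.approx(expected.mean())

    def test_insufficient_data_marker(self):
        recs = [_toy("p0", {"DEHP": 1000.0})]
        assert fit_concentration_distribution(recs, "DEHP", "toy") is None

    def test_fitted_median_below_observed_maximum(self, survey):
        spec = fit_concentration_distribution(survey, "DEHP", "toy")
        median = math.exp(spec.params["mu"])
        assert median <= 28.11 * 10_000.0


def _point_profiles(ed_hours=1.0):
    spec = {
        "bw": _point(15.0), "sa": _point(375.0), "ca": _point(10.0),
        "d_mouthing": _point(4.5),
        "ed": {cat: _point(ed_hours) for cat in CATEGORIES},
    }
    return {"0-2": AgeGroupProfile(label="0-2", **spec)}


class TestRunMc:
    def test_degenerate_distributions_match_deterministic_engine(
        self, survey, factors
    ):
        conc = 250_000.0  # 25% w/w everywhere
        overrides = {
            (cat, chem): _point(conc)
            for cat in CATEGORIES
            for chem in ("DBP", "DEHA", "DEHP", "DEP", "DIBP", "DINP")
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_mc(
                survey, _point_profiles(), n_iter=50, seed=9,
                concentration_overrides=overrides, base_factors=factors,
            )
        by = {(r.chemical, r.route): r for r in results}
        for chem in ("DEHP", "DBP"):
            mr = assign_migration_rate(conc / 1e6)
            det_ing = ingestion_daily_dose(mr, factors)
            inter = dermal_intermediates(get_chemical(chem), factors)
            det_derm = dermal_daily_dose(
                content_to_cart(conc / 1e6, factors.rho_article), factors, inter
            )
            r_ing = by[(chem, "ingestion")]
            r_derm = by[(chem, "dermal")]
            # three mouthing categories and six dermal categories sum up
            assert r_ing.median == pytest.approx(3 * det_ing, rel=1e-9)
            assert r_ing.p95 == pytest.approx(r_ing.median, rel=1e-12)
            assert r_derm.median == pytest.approx(6 * det_derm, rel=1e-9)

    def test_same_seed_bitwise_reproducible(self, survey):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_mc(survey, n_iter=200, seed=11)
            b = run_mc(survey, n_iter=200, seed=11)
        assert a == b

    def test_different_seed_changes_draws(self, survey):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_mc(survey, n_iter=200, seed=11)
            c = run_mc(survey, n_iter=200, seed=12)
        assert a != c

    def test_median_no_greater_than_p95_and_moe_antimonotone(self, survey):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_mc(survey, n_iter=500, seed=2)
        for r in results:
            assert r.median <= r.p95
            assert r.moe_p95 <= r.moe_median

    def test_missing_category_distribution_is_a_configuration_error(self):
        # a survey with a single product cannot support distribution fits
        recs = [_toy("p0", {"DEHP": 1000.0})]
        with pytest.raises(ValueError, match="fewer than 2 products"):
            run_mc(recs, _point_profiles(), n_iter=10, seed=0)


class TestSummarize:
    def test_table_shape_and_total_ordering(self, survey):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = summarize_mc(run_mc(survey, n_iter=500, seed=5))
        assert len(report) == 12  # 6 chemicals x 2 age groups
        assert set(report["age_group"]) == {"0-2", "3-12"}
        assert (report["total_median"] <= report["total_p95"] + 1e-15).all()
        assert (report["moe_p95"] <= report["moe_median"] + 1e-15).all()

    def test_empty_results_empty_report(self):
        assert summarize_mc([]).empty


def test_default_profiles_cover_both_age_groups_and_all_categories():
    profiles = default_profiles()
    assert set(profiles) == {"0-2", "3-12"}
    for p in profiles.values():
        assert set(p.ed) == set(CATEGORIES)
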