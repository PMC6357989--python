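"""Odds ratios, pooled t tests, published-table reproduction, and OLS models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from needscape.group_stats import (
    ContingencyTable2x2,
    DomainError,
    MODEL_PREDICTORS,
    fit_linear_models,
    odds_ratio,
    pooled_t_binary,
    reconstruct_count,
    summarize_demographics,
    univariate_table,
)
from needscape.published import (
    ETHNICITY_ROWS,
    N_NON_ROMA,
    N_ROMA,
    reconstruct_table,
    reproduce_published,
)
from needscape.simulate import DEFAULT_INDICATORS, GeneratorConfig, IndicatorSpec, generate_survey

from conftest import make_record

counts = st.integers(min_value=1, max_value=500)


class TestReconstructCount:
    @pytest.mark.parametrize(
        "pct,n,expected", [(27.6, 98, 27), (0.0, 37, 0), (59.5, 37, 22), (50.0, 2, 1)]
    )
    def test_examples(self, pct, n, expected):
        assert reconstruct_count(pct, n) == expected

    def test_domain(self):
        with pytest.raises(DomainError):
            reconstruct_count(101.0, 10)


class TestOddsRatio:
    def test_insecure_housing_row(self):
        or_, lo, hi, corrected = odds_ratio(ContingencyTable2x2(27, 71, 2, 35))
        assert round(or_, 2) == 6.65
        assert (round(lo, 1), round(hi, 1)) == (1.5, 29.6)
        assert not corrected

    def test_symmetric_table_is_unity(self):
        or_, lo, hi, _ = odds_ratio(ContingencyTable2x2(10, 10, 10, 10))
        assert or_ == 1.0 and lo < 1.0 < hi

    def test_diarrhea_row(self):
        or_, *_ = odds_ratio(ContingencyTable2x2(57, 41, 15, 22))
        assert round(or_, 2) == 2.04

    def test_zero_cell_triggers_haldane_correction(self):
        or_, lo, hi, corrected = odds_ratio(ContingencyTable2x2(0, 20, 5, 15))
        assert corrected and 0 < lo <= or_ <= hi

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            ContingencyTable2x2(0, 0, 5, 5)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(derandomize=True, max_examples=80)
    def test_reciprocal_under_group_swap(self, a, b, c, d):
        or1, lo1, hi1, _ = odds_ratio(ContingencyTable2x2(a, b, c, d))
        or2, lo2, hi2, _ = odds_ratio(ContingencyTable2x2(c, d, a, b))
        assert or1 * or2 == pytest.approx(1.0)
        assert lo1 <= or1 <= hi1

    def test_ci_widens_as_a_cell_shrinks(self):
        widths = []
        for a in (40, 10, 2):
            or_, lo, hi, _ = odds_ratio(ContingencyTable2x2(a, 60, 20, 30))
            widths.append(np.log(hi) - np.log(lo))
        assert widths[0] < widths[1] < widths[2]


class TestPooledT:
    def test_insecure_housing_row(self):
        t, df, p = pooled_t_binary(27, 98, 2, 37)
        assert round(abs(t), 3) == 2.858 and df == 133
        assert p == pytest.approx(0.005, abs=5e-4)

    def test_equal_proportions_give_zero(self):
        t, _, p = pooled_t_binary(5, 10, 10, 20)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_rural_poverty_row(self):
        t, df, _ = pooled_t_binary(55, 89, 15, 46)
        assert round(abs(t), 3) == 3.323 and df == 133

    @given(a=st.integers(0, 30), c=st.integers(0, 40))
    @settings(derandomize=True, max_examples=60)
    def test_antisymmetric_under_group_swap(self, a, c):
        t1, _, p1 = pooled_t_binary(a, 30, c, 40)
        t2, _, p2 = pooled_t_binary(c, 40, a, 30)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_tiny_group_rejected(self):
        with pytest.raises(DomainError):
            pooled_t_binary(1, 1, 2, 5)


class TestPublishedReproduction:
    def test_every_row_reproduces_or_and_t_at_printed_precision(self):
        df = reproduce_published()
        for row in df.itertuples(index=False):
            assert round(row.odds_ratio, 2) == row.published_or, row.variable
            assert round(row.abs_t, row.t_decimals) == round(
                row.published_t, row.t_decimals
            ), row.variable


def _table2_fixture_records():
    """135 records whose per-variable adverse counts match the printed tables."""
    recs = [make_record(ethnicity="roma", community_id=f"c{i % 5}") for i in range(N_ROMA)]
    recs += [
        make_record(ethnicity="non_roma", community_id=f"c{i % 5}")
        for i in range(N_NON_ROMA)
    ]
    setters = {
        "indoor_toilet_lacking": {"indoor_toilet": False},
        "indoor_bathroom_lacking": {"indoor_bathroom": False},
        "improved_water_lacking": {"piped_tap": False, "protected_well": True},
        "insecure_housing": {"housing_deficient_roof": True},
        "diarrhea": {"diarrhea_mod_severe": True},
        "uninsured": {"insured": False},
        "no_pcp_access": {"pcp_access": False},
        "electricity_lacking": {"electricity": False},
        "severe_poverty": {"spends_over_2usd": False},
    }
    for row in ETHNICITY_ROWS:
        if row.variable not in setters:
            continue
        table = reconstruct_table(row, N_ROMA, N_NON_ROMA)
        for i in range(table.a):
            for field, value in setters[row.variable].items():
                object.__setattr__(recs[i], field, value)
        for i in range(table.c):
            for field, value in setters[row.variable].items():
                object.__setattr__(recs[N_ROMA + i], field, value)
    return recs


class TestUnivariateTable:
    def test_reconstructed_fixture_reproduces_published_ors(self):
        results = {r.variable: r for r in univariate_table(_table2_fixture_records())}
        assert round(results["electricity_lacking"].odds_ratio, 2) == 5.51
        assert round(results["improved_water_lacking"].odds_ratio, 2) == 0.34
        assert round(results["insecure_housing"].odds_ratio, 2) == 6.65
        assert round(abs(results["insecure_housing"].t_stat), 3) == 2.858

    def test_identical_groups_give_unit_or_and_zero_t(self):
        recs = [make_record(ethnicity="roma", diarrhea_mod_severe=i < 3) for i in range(10)]
        recs += [make_record(ethnicity="non_roma", diarrhea_mod_severe=i < 3) for i in range(10)]
        for r in univariate_table(recs):
            if not r.zero_cell_corrected:
                assert r.odds_ratio == pytest.approx(1.0)
            assert r.t_stat == pytest.approx(0.0)

    def test_constant_variable_flagged_non_estimable(self):
        recs = [make_record(ethnicity=e) for e in ["roma"] * 5 + ["non_roma"] * 5]
        results = {r.variable: r for r in univariate_table(recs)}
        assert results["diarrhea_mod_severe"].non_estimable

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            univariate_table([make_record(ethnicity="roma")] * 5)

    def test_geography_pools_suburban_and_urban(self, survey_records):
        results = univariate_table(survey_records, grouping="geography")
        pov = next(r for r in results if r.variable == "severe_poverty")
        assert pov.n1 == 89 and pov.n2 == 46


def _planted_survey(target_ors: dict, n_scale: int = 6, seed: int = 7):
    """Large survey with chosen indicator odds ratios, all else null."""
    indicators = {
        name: IndicatorSpec(spec.p0, target_ors.get(name, 1.0))
        for name, spec in DEFAULT_INDICATORS.items()
    }
    cfg = GeneratorConfig(seed=seed, indicators=indicators)
    big = tuple(
        type(c)(c.community_id, c.n_households * n_scale, c.n_roma * n_scale, c.geography_class)
        for c in cfg.communities
    )
    cfg.communities = big
    return generate_survey(cfg)


class TestLinearModels:
    def test_planted_insecure_housing_effect_dominates_mod2(self):
        recs = _planted_survey({"insecure_housing": 6.65})
        mod2 = next(r for r in fit_linear_models(recs, ["MOD2"]))
        coefs = mod2.params.drop("const")
        assert coefs["insecure_housing"] > 0
        assert coefs.abs().idxmax() == "insecure_housing"
        assert mod2.p_values["insecure_housing"] < 0.05

    def test_wells_closing_water_gap_attenuates_wash_safe(self):
        # Roma lack taps but safe water (incl. wells) is at parity
        recs = _planted_survey(
            {"improved_water_lacking": 8.0, "safe_water_lacking": 1.0}
        )
        mod3, mod4 = fit_linear_models(recs, ["MOD3", "MOD4"])
        assert abs(mod4.params["wash_safe_score"]) < abs(mod3.params["wash_score"])

    def test_single_ethnicity_rejected(self):
        recs = [
            make_record(ethnicity="roma", household_size=3 + (i % 4)) for i in range(20)
        ]
        with pytest.raises(DomainError):
            fit_linear_models(recs)

    def test_collinear_design_names_columns(self):
        recs = [
            make_record(ethnicity="roma" if i < 10 else "non_roma", household_size=4)
            for i in range(20)
        ]
        # household_size constant -> collinear with the intercept
        with pytest.raises(DomainError, match="household_size"):
            fit_linear_models(recs, ["MOD1"])

    def test_every_model_ci_brackets_coefficient(self, survey_records):
        for res in fit_linear_models(survey_records):
            assert set(res.params.index) == set(["const"] + MODEL_PREDICTORS[res.model_id])
            assert (res.ci_low <= res.params).all() and (res.params <= res.ci_high).all()


class TestDemographics:
    def test_generated_survey_household_sizes_near_calibration(self, survey_records):
        table = summarize_demographics(survey_records)
        roma = table.loc[("overall", "roma")]
        non = table.loc[("overall", "non_roma")]
        assert roma["n"] == 98 and non["n"] == 37
        assert roma["mean_household_size"] == pytest.approx(5.3, abs=0.6)
        assert non["mean_household_size"] == pytest.approx(4.2, abs=0.7)

    def test_single_record(self):
        table = summarize_demographics([make_record()])
        assert table.loc[("overall", "all"), "n"] == 1

    def test_order_invariance(self, survey_records):
        import pandas.testing as pdt

        t1 = summarize_demographics(survey_records)
        t2 = summarize_demographics(list(reversed(survey_records)))
        pdt.assert_frame_equal(t1, t2)  # float sums may reorder, values match
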