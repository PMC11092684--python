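"""Unit and property tests for the schedule-derivation pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import savm
from savm.io_model import (
    GENDERS, Adjusters, EndsProportionTable, GroupedPrevalenceTable, ScenarioParams,
    ValidationError,
)
from savm.preprocess import (
    apply_adjuster_arrays,
    derive_never_smoker_life_expectancy,
    derive_status_mortality,
    expand_ends_groups_to_ages,
    fill_ends_proportion_gaps,
    interpolate_group_prevalence,
)

BANDS = GroupedPrevalenceTable.BANDS


def make_grouped(current, former=None):
    """Grouped prevalence table with per-band current values (both genders)."""
    former = former or {b: 0.0 for b in BANDS}
    rows = []
    for gender in GENDERS:
        for b in BANDS:
            c, f = current[b], former[b]
            rows.append((b, gender, 1.0 - c - f, c, f))
    return GroupedPrevalenceTable(pd.DataFrame(
        rows, columns=["age_group", "gender", "never", "current", "former"]))


class TestPrevalenceInterpolation:
    def test_even_rise_between_midages(self):
        """Band values sit at mid-ages 17 and 22 and rise evenly between."""
        current = {b: 0.20 for b in BANDS}
        current["15-19"] = 0.10
        prev = interpolate_group_prevalence(make_grouped(current))
        got = prev[1, 0, 17:23]
        np.testing.assert_allclose(got, [0.10, 0.12, 0.14, 0.16, 0.18, 0.20], atol=1e-12)

    def test_constant_bands_give_constant_curve(self):
        prev = interpolate_group_prevalence(make_grouped({b: 0.25 for b in BANDS}))
        np.testing.assert_allclose(prev[1, :, 17:86], 0.25, atol=1e-12)

    def test_oldest_ages_hold_the_age62_value(self):
        current = {b: 0.20 for b in BANDS}
        current["60-65"] = 0.30
        prev = interpolate_group_prevalence(make_grouped(current))
        np.testing.assert_allclose(prev[1, :, 63:86], 0.30, atol=1e-12)
        assert prev[1, 0, 62] == pytest.approx(0.30)

    def test_zero_floors_and_ramps(self):
        """Current ramps from 0 at age 9, former from 0 at age 15."""
        current = {b: 0.16 for b in BANDS}
        former = {b: 0.10 for b in BANDS}
        prev = interpolate_group_prevalence(make_grouped(current, former))
        assert prev[1, 0, :9].max() == 0.0
        assert prev[1, 0, 13] == pytest.approx(0.16 * (13 - 9) / (17 - 9))
        assert prev[2, 0, :15].max() == 0.0
        assert prev[2, 0, 16] == pytest.approx(0.10 * 0.5)
        np.testing.assert_allclose(prev.sum(axis=0), 1.0, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 0.4), min_size=10, max_size=10))
    def test_piecewise_linear_between_midages(self, values):
        """Second differences vanish strictly inside each mid-age segment."""
        prev = interpolate_group_prevalence(make_grouped(dict(zip(BANDS, values))))
        curve = prev[1, 0]
        for lo in range(17, 57, 5):  # segments between consecutive mid-ages
            seg = curve[lo : lo + 6]
            np.testing.assert_allclose(np.diff(seg, 2), 0.0, atol=1e-12)
        mids = [17, 22, 27, 32, 37, 42, 47, 52, 57, 62]
        np.testing.assert_allclose(curve[mids], values, atol=1e-12)


def make_le_anchors(value_by_year, bands=("0-39", "40-85")):
    rows = []
    for y, vals in value_by_year.items():
        for gender in GENDERS:
            for band, v in zip(bands, vals):
                rows.append((band, gender, y, v))
    return pd.DataFrame(rows, columns=["age_group", "gender", "year", "value"])


def make_ratio(value=1.0):
    rows = [(a, g, value) for g in GENDERS for a in range(86)]
    return pd.DataFrame(rows, columns=["age", "gender", "value"])


class TestNeverSmokerLifeExpectancy:
    def test_anchor_substitution(self):
        """An anchor value of 38.0 with ratio 1.05 yields 39.9 over its years."""
        anchors = make_le_anchors({2010: (40.0, 38.5), 2015: (38.0, 36.0),
                                   2019: (36.0, 34.0)})
        params = ScenarioParams()
        le = derive_never_smoker_life_expectancy(anchors, make_ratio(1.05), params)
        # 2015 anchor covers 2015-2018; band 0-39 has mid-age 19, flat below
        for year in (2015, 2016, 2017, 2018):
            assert le[0, 10, params.year_index(year)] == pytest.approx(38.0 * 1.05)

    def test_identity_ratio_reproduces_overall_le(self):
        anchors = make_le_anchors({2010: (40.0, 20.0), 2015: (41.0, 21.0),
                                   2019: (42.0, 22.0)})
        params = ScenarioParams()
        le = derive_never_smoker_life_expectancy(anchors, make_ratio(1.0), params)
        assert le[1, 5, params.year_index(2009)] == pytest.approx(40.0)   # 2010 anchor
        assert le[1, 5, params.year_index(2014)] == pytest.approx(40.0)
        assert le[1, 5, params.year_index(2049)] == pytest.approx(42.0)   # 2019 anchor

    def test_missing_anchor_gender_is_an_error(self):
        anchors = make_le_anchors({2010: (40.0, 20.0)})
        anchors = anchors[anchors.gender != "female"]
        with pytest.raises(ValidationError, match="female"):
            derive_never_smoker_life_expectancy(anchors, make_ratio(), ScenarioParams())


class TestStatusMortality:
    def test_direct_substitution(self):
        shape = (2, 86, 1)
        out = derive_status_mortality(
            np.full(shape, 0.004), np.full(shape, 0.002),
            {"never": np.full(shape, 0.0015), "current": np.full(shape, 0.004),
             "former": np.full(shape, 0.002)})
        assert out["never"][0, 30, 0] == pytest.approx(0.003)

    def test_degenerate_reference_collapses_to_country_rate(self):
        shape = (2, 86, 2)
        ref = np.full(shape, 0.002)
        country = np.random.default_rng(0).uniform(0.001, 0.01, shape)
        out = derive_status_mortality(country, ref, {s: ref for s in
                                                     ("never", "current", "former")})
        for s in ("never", "current", "former"):
            np.testing.assert_allclose(out[s], country, rtol=1e-12)

    def test_ratio_recovered_by_brute_force_division(self, fixture_bundle, derived, params):
        """R recomputed cell-by-cell from the raw tables reproduces the derived rates."""
        mc = fixture_bundle.overall_mortality_country.to_array(params.years)
        mr = fixture_bundle.overall_mortality_reference.to_array(params.years)
        ref_never = fixture_bundle.reference_status_mortality["never"].to_array(params.years)
        rng = np.random.default_rng(1)
        for _ in range(200):
            g = rng.integers(0, 2)
            a = rng.integers(0, 86)
            t = rng.integers(0, params.n_years)
            r = mc[g, a, t] / mr[g, a, t]
            assert derived.mort["never"][g, a, t] == pytest.approx(r * ref_never[g, a, t],
                                                                   rel=1e-12)

    def test_scaling_commutes(self):
        """Scaling the country's overall rates by k scales every status rate by k."""
        rng = np.random.default_rng(2)
        shape = (2, 86, 3)
        country = rng.uniform(1e-4, 5e-3, shape)
        ref = rng.uniform(1e-4, 5e-3, shape)
        by_status = {s: rng.uniform(1e-4, 5e-3, shape) for s in
                     ("never", "current", "former")}
        base = derive_status_mortality(country, ref, by_status)
        scaled = derive_status_mortality(3.0 * country, ref, by_status)
        for s in base:
            np.testing.assert_allclose(scaled[s], 3.0 * base[s], rtol=1e-12)

    def test_zero_reference_rate_is_an_error(self):
        shape = (2, 86, 1)
        ref = np.full(shape, 0.002)
        ref[1, 40, 0] = 0.0
        with pytest.raises(ValidationError, match="female.*40"):
            derive_status_mortality(np.full(shape, 0.004), ref,
                                    {s: ref for s in ("never", "current", "former")})


def make_ends_table(values):
    """values: {(gender, band, year): (pn, pf)}; unset cells default to 0."""
    years = sorted({y for (_, _, y) in values})
    rows = []
    for gender in GENDERS:
        for band in EndsProportionTable.BANDS:
            for y in years:
                pn, pf = values.get((gender, band, y), (0.0, 0.0))
                rows.append((band, gender, y, pn, pf))
    return EndsProportionTable(pd.DataFrame(
        rows, columns=["age_group", "gender", "survey_year", "pn", "pf"]))


class TestEndsProportions:
    def test_interior_gap_is_neighbour_average(self):
        table = make_ends_table({("male", "15-24", 2016): (0.004, 0.0),
                                 ("male", "15-24", 2018): (0.006, 0.0)})
        filled = fill_ends_proportion_gaps(table, ScenarioParams())
        cell = filled[(filled.gender == "male") & (filled.age_group == "15-24")]
        assert float(cell[cell.year == 2017].pn.iloc[0]) == pytest.approx(0.005)

    def test_constant_after_last_survey_year(self):
        table = make_ends_table({("female", "25-39", 2015): (0.0, 0.004),
                                 ("female", "25-39", 2022): (0.0, 0.01)})
        filled = fill_ends_proportion_gaps(table, ScenarioParams())
        cell = filled[(filled.gender == "female") & (filled.age_group == "25-39")]
        for year in (2035, 2049):
            assert float(cell[cell.year == year].pf.iloc[0]) == pytest.approx(0.01)

    def test_single_survey_year_extends_constant(self):
        table = make_ends_table({("male", "40-65", 2015): (0.002, 0.0)})
        filled = fill_ends_proportion_gaps(
            table, ScenarioParams(end_year=2020, ban_lift_year=2020))
        cell = filled[(filled.gender == "male") & (filled.age_group == "40-65")]
        np.testing.assert_allclose(cell.sort_values("year").pn, 0.002)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 0.02), min_size=6, max_size=6))
    def test_survey_years_reproduced_exactly(self, levels):
        years = (2015, 2016, 2018, 2020, 2021, 2022)
        table = make_ends_table({("male", "15-24", y): (v, 0.0)
                                 for y, v in zip(years, levels)})
        filled = fill_ends_proportion_gaps(table, ScenarioParams())
        cell = filled[(filled.gender == "male") & (filled.age_group == "15-24")]
        cell = cell.set_index("year")
        for y, v in zip(years, levels):
            assert float(cell.loc[y].pn) == pytest.approx(v, abs=1e-15)
        after = cell[cell.index > 2022].pn
        np.testing.assert_allclose(after, levels[-1], atol=1e-15)

    def test_group_expansion_piecewise_constant(self):
        table = make_ends_table({("male", "15-24", 2015): (0.01, 0.0)})
        filled = fill_ends_proportion_gaps(table, ScenarioParams())
        pn, pf = expand_ends_groups_to_ages(filled, ScenarioParams())
        t = ScenarioParams().year_index(2015)
        assert pn[0, 19, t] == pytest.approx(0.01)
        assert pn[0, 24, t] == pytest.approx(0.01)
        assert pn[0, 14, t] == 0.0          # outside the modelled ENDS ages
        assert pn[0, 40:66, t].max() == 0.0  # zero band propagates zeros
        assert pn[:, :, : t].max() == 0.0    # nothing before the first survey


class TestAdjusters:
    def test_published_scaler_examples(self):
        init = np.zeros((2, 86, 1))
        cess = np.zeros((2, 86, 1))
        init[0, 20, 0] = 0.02   # male age 20
        cess[1, 50, 0] = 0.03   # female age 50
        out_i, out_c = apply_adjuster_arrays(init, cess, Adjusters.default())
        assert out_i[0, 20, 0] == pytest.approx(0.02 * 1.52)
        assert out_c[1, 50, 0] == 0.0   # female 40+ cessation adjuster is 0.00

    def test_unit_adjusters_are_identity(self, fixture_bundle, params):
        init, cess = fixture_bundle.rates.to_arrays(params.years)
        out_i, out_c = apply_adjuster_arrays(init, cess, Adjusters.unit())
        np.testing.assert_array_equal(out_i, init)
        np.testing.assert_array_equal(out_c, cess)

    def test_rates_above_one_are_clipped(self):
        init = np.full((2, 86, 1), 0.5)
        adj = Adjusters(
            initiation={g: {(15, 24): 100.0, (25, 40): 1.0} for g in GENDERS},
            cessation={g: {(25, 39): 1.0, (40, 85): 1.0} for g in GENDERS})
        out_i, _ = apply_adjuster_arrays(init, np.zeros_like(init), adj)
        assert out_i.max() == 1.0

    def test_negative_scaler_is_rejected(self):
        with pytest.raises(ValidationError):
            Adjusters(initiation={g: {(15, 24): -0.5, (25, 40): 1.0} for g in GENDERS},
                      cessation={g: {(25, 39): 1.0, (40, 85): 1.0} for g in GENDERS})

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 1.5), min_size=8, max_size=8))
    def test_composition_multiplies_scalers(self, scalers):
        """Applying adjusters A then B equals applying the product A*B
        (away from the clipping boundary)."""
        rng = np.random.default_rng(3)
        init = rng.uniform(0.0, 0.1, (2, 86, 2))
        cess = rng.uniform(0.0, 0.1, (2, 86, 2))

        def adj(vals):
            i1, i2, c1, c2 = vals[:4]
            return Adjusters(
                initiation={g: {(15, 24): i1, (25, 40): i2} for g in GENDERS},
                cessation={g: {(25, 39): c1, (40, 85): c2} for g in GENDERS})

        a, b = adj(scalers[:4]), adj(scalers[4:])
        ab = adj([x * y for x, y in zip(scalers[:4], scalers[4:])])
        step1 = apply_adjuster_arrays(init, cess, a)
        step2 = apply_adjuster_arrays(step1[0], step1[1], b)
        direct = apply_adjuster_arrays(init, cess, ab)
        np.testing.assert_allclose(step2[0], direct[0], rtol=1e-12)
        np.testing.assert_allclose(step2[1], direct[1], rtol=1e-12)


def test_derived_schedules_with_adjusters_matches_full_derivation(
        fixture_bundle, params, derived_raw):
    d2 = derived_raw.with_adjusters(savm.Adjusters.default())
    full = savm.derive_schedules(fixture_bundle, params, savm.Adjusters.default())
    np.testing.assert_array_equal(d2.initiation, full.initiation)
    np.testing.assert_array_equal(d2.cessation, full.cessation)
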