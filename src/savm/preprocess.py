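"""Derivation of the complete single-age, single-year schedules the engine consumes.

Raw inputs arrive grouped (5-year prevalence bands, coarse ENDS bands, a few
life-expectancy anchor years).  This module expands them to dense
``[gender, age, year]`` arrays:

* baseline smoking prevalence via mid-age linear interpolation,
* never-smoker life expectancy via anchor-year assignment times the
  never/overall reference ratio,
* country mortality by smoking status via the mortality ratio
  R = overall country rate / overall reference rate applied to the
  reference status-specific rates,
* ENDS-PN/PF via neighbour-year gap filling and piecewise-constant age
  expansion,
* calibrated initiation/cessation schedules via band adjusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import (
    AGE_MAX,
    AGE_MIN,
    GENDERS,
    N_AGE,
    STATUSES,
    Adjusters,
    EndsProportionTable,
    GroupedPrevalenceTable,
    InputBundle,
    ScenarioParams,
    ValidationError,
    mid_age,
    parse_age_band,
)

log = logging.getLogger("savm.preprocess")


@dataclass
class DerivedSchedules:
    """Dense schedules on the modelling grid (ages 0-85, model years).

    All arrays are indexed ``[gender, age, year]`` except ``baseline_prev``
    which is ``[status, gender, age]`` with status order never/current/former
    at the baseline year.
    """

    years: np.ndarray
    pop: np.ndarray                      # persons
    mort: Mapping[str, np.ndarray]       # status -> deaths/person-year
    never_le: np.ndarray                 # remaining years, never smokers
    baseline_prev: np.ndarray            # [3, gender, age]
    pn: np.ndarray                       # ENDS-PN, zero before ends_start_year
    pf: np.ndarray                       # ENDS-PF
    raw_initiation: np.ndarray           # pre-adjustment schedules
    raw_cessation: np.ndarray
    initiation: np.ndarray               # adjusted schedules
    cessation: np.ndarray

    def with_adjusters(self, adjusters: Adjusters) -> "DerivedSchedules":
        """Cheap re-derivation with different calibration adjusters."""
        init, cess = apply_adjuster_arrays(self.raw_initiation, self.raw_cessation, adjusters)
        return replace(self, initiation=init, cessation=cess)


def grouped_to_midage_curve(bands, values, lower_anchor=None) -> np.ndarray:
    """Expand banded values to single ages 0-85 through their mid-ages.

    Exact at each mid-age, linear between consecutive mid-ages, constant above
    the last mid-age.  With ``lower_anchor=(age0, v0)`` the curve ramps
    linearly from ``v0`` at ``age0`` up to the first mid-age and equals ``v0``
    below; without it the first band's value extends downward unchanged.
    """
    mids = [mid_age(*parse_age_band(b)) for b in bands]
    if any(b <= a for a, b in zip(mids, mids[1:])):
        raise ValidationError("age bands must be increasing and non-overlapping")
    xp = list(mids)
    fp = [float(v) for v in values]
    if lower_anchor is not None:
        a0, v0 = lower_anchor
        if a0 >= xp[0]:
            raise ValidationError("lower anchor must precede the first mid-age")
        xp = [a0] + xp
        fp = [float(v0)] + fp
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    return np.interp(ages, xp, fp)


def interpolate_group_prevalence(grouped: GroupedPrevalenceTable) -> np.ndarray:
    """Single-age baseline prevalence ``[status, gender, age]``.

    Band values sit at their mid-ages (17, 22, ..., 62) and are linearly
    interpolated between; ages above 62 keep the age-62 value.  Current
    smoking ramps from 0 at age 9, former from 0 at age 15, up to the first
    mid-age.  Never prevalence is the complement.
    """
    grouped.validate()
    out = np.zeros((3, 2, N_AGE))
    for g, gender in enumerate(GENDERS):
        cur = grouped_to_midage_curve(
            grouped.BANDS, grouped.values(gender, "current"), lower_anchor=(9, 0.0)
        )
        fmr = grouped_to_midage_curve(
            grouped.BANDS, grouped.values(gender, "former"), lower_anchor=(15, 0.0)
        )
        nev = 1.0 - cur - fmr
        if (nev < -1e-12).any():
            a = int(np.argmax(nev < -1e-12))
            raise ValidationError(
                f"interpolated current+former exceeds 1 at age {a} ({gender})"
            )
        out[0, g] = np.clip(nev, 0.0, 1.0)
        out[1, g] = cur
        out[2, g] = fmr
    return out


def _anchor_for_year(anchors: np.ndarray, year: int) -> int:
    """Largest anchor <= year; years before the first anchor use the first."""
    le = anchors[anchors <= year]
    return int(le.max()) if len(le) else int(anchors.min())


def derive_never_smoker_life_expectancy(
    le_anchors: pd.DataFrame, ratio: pd.DataFrame, params: ScenarioParams
) -> np.ndarray:
    """Never-smoker life expectancy ``[gender, age, year]``.

    Anchor-year schedules (e.g. 2010/2015/2019) are assigned piecewise-
    constant over the model years (2010 covers 2009-2014, 2015 covers
    2015-2018, 2019 extends to the final year), expanded from 5-year bands to
    single ages through mid-age interpolation, and multiplied by the reference
    never-smoker/overall ratio, held constant over the modelling period.
    """
    anchors = np.sort(le_anchors.year.unique())
    if len(anchors) == 0:
        raise ValidationError("life_expectancy: no anchor years present")
    ratio_arr = np.zeros((2, N_AGE))
    for g, gender in enumerate(GENDERS):
        sub = ratio[ratio.gender == gender].set_index("age")["value"]
        sub = sub.reindex(range(AGE_MIN, AGE_MAX + 1))
        if sub.isna().any():
            raise ValidationError(f"le_ratio: incomplete ages for {gender}")
        ratio_arr[g] = sub.to_numpy(dtype=float)

    curves: dict[tuple[int, str], np.ndarray] = {}
    for y in anchors:
        for gender in GENDERS:
            sub = le_anchors[(le_anchors.year == y) & (le_anchors.gender == gender)]
            if len(sub) == 0:
                raise ValidationError(f"life_expectancy: missing anchor year {y} for {gender}")
            sub = sub.sort_values("age_group", key=lambda s: s.map(lambda b: parse_age_band(b)[0]))
            curves[(int(y), gender)] = grouped_to_midage_curve(
                sub.age_group.tolist(), sub["value"].tolist()
            )

    out = np.zeros((2, N_AGE, params.n_years))
    for t, year in enumerate(params.years):
        a = _anchor_for_year(anchors, int(year))
        for g, gender in enumerate(GENDERS):
            out[g, :, t] = curves[(a, gender)] * ratio_arr[g]
    if (out <= 0).any():
        raise ValidationError("derived never-smoker life expectancy must be positive")
    diffs = np.diff(out, axis=1)
    if (diffs > 1e-9).any():
        g, a, t = np.unravel_index(np.argmax(diffs), diffs.shape)
        raise ValidationError(
            f"never-smoker life expectancy increases with age at "
            f"gender={GENDERS[g]} age={a}->{a + 1} year={params.years[t]}"
        )
    return out


def derive_status_mortality(
    overall_country: np.ndarray,
    overall_reference: np.ndarray,
    reference_by_status: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Country mortality by smoking status from the ratio method.

    ``m_s_country = R * m_s_reference`` with ``R = overall country rate /
    overall reference rate`` cell-by-cell.  Rates above 1 are clipped with a
    warning.
    """
    if (overall_reference <= 0).any():
        g, a, t = np.unravel_index(np.argmax(overall_reference <= 0), overall_reference.shape)
        raise ValidationError(
            f"reference overall mortality is zero at gender={GENDERS[g]} age={a} "
            f"year-index={t}; the mortality ratio is undefined there"
        )
    R = overall_country / overall_reference
    out = {}
    for s in STATUSES:
        m = R * reference_by_status[s]
        if (m > 1).any():
            log.warning("status mortality for '%s' exceeded 1 in %d cell(s); clipped",
                        s, int((m > 1).sum()))
            m = np.clip(m, 0.0, 1.0)
        out[s] = m
    return out


def fill_ends_proportion_gaps(
    table: EndsProportionTable, params: ScenarioParams
) -> pd.DataFrame:
    """ENDS-PN/PF for every year ``ends_start_year..end_year`` per band/gender.

    Interior years without a survey take the arithmetic mean of the nearest
    preceding and following survey values (2017 from 2016 and 2018, 2019 from
    2018 and 2020); years after the last survey hold the last survey's value.
    """
    table.validate()
    survey_years = np.array(table.survey_years)
    if len(survey_years) == 0:
        raise ValidationError("ends_proportions: no survey years to fill from")
    years = np.arange(params.ends_start_year, params.end_year + 1)
    rows = []
    for gender in GENDERS:
        for band in table.BANDS:
            sub = table.df[(table.df.gender == gender) & (table.df.age_group == band)]
            sub = sub.set_index("survey_year").sort_index()
            for col in ("pn", "pf"):
                series = sub[col]
                vals = {}
                for y in years:
                    if y in series.index:
                        vals[y] = float(series.loc[y])
                    elif y > survey_years.max():
                        vals[y] = float(series.loc[survey_years.max()])
                    elif y < survey_years.min():
                        vals[y] = float(series.loc[survey_years.min()])
                    else:
                        prev = survey_years[survey_years < y].max()
                        nxt = survey_years[survey_years > y].min()
                        vals[y] = 0.5 * (float(series.loc[prev]) + float(series.loc[nxt]))
                for y, v in vals.items():
                    rows.append((gender, band, int(y), col, v))
    df = pd.DataFrame(rows, columns=["gender", "age_group", "year", "quantity", "value"])
    return df.pivot_table(
        index=["gender", "age_group", "year"], columns="quantity", values="value"
    ).reset_index()


def expand_ends_groups_to_ages(
    filled: pd.DataFrame, params: ScenarioParams
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant single-age ENDS-PN/PF arrays ``[gender, age, year]``.

    Each band's value applies to every age inside it; ages outside 15-65 and
    years before ``ends_start_year`` are zero.
    """
    pn = np.zeros((2, N_AGE, params.n_years))
    pf = np.zeros_like(pn)
    spans = [parse_age_band(b) for b in sorted(set(filled.age_group), key=str)]
    spans.sort()
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ValidationError(f"ends groups overlap: {lo1}-{hi1} and {lo2}-{hi2}")
    for g, gender in enumerate(GENDERS):
        sub = filled[filled.gender == gender]
        for _, row in sub.iterrows():
            lo, hi = parse_age_band(row.age_group)
            t = params.year_index(row.year)
            if 0 <= t < params.n_years:
                pn[g, lo : hi + 1, t] = row.pn
                pf[g, lo : hi + 1, t] = row.pf
    return pn, pf


def apply_adjuster_arrays(
    initiation: np.ndarray, cessation: np.ndarray, adjusters: Adjusters
) -> tuple[np.ndarray, np.ndarray]:
    """Scale dense rate arrays by the band adjusters; clip into [0, 1].

    Ages outside every adjuster band keep their unscaled rates.
    """
    init = initiation.copy()
    cess = cessation.copy()
    for g, gender in enumerate(GENDERS):
        for (lo, hi), v in adjusters.initiation[gender].items():
            init[g, lo : hi + 1, :] *= v
        for (lo, hi), v in adjusters.cessation[gender].items():
            cess[g, lo : hi + 1, :] *= v
    for name, arr in (("initiation", init), ("cessation", cess)):
        over = arr > 1.0
        if over.any():
            log.warning("adjusted %s rates exceeded 1 in %d cell(s); clipped",
                        name, int(over.sum()))
            np.clip(arr, 0.0, 1.0, out=arr)
    return init, cess


def apply_adjusters(rates, adjusters: Adjusters, params: ScenarioParams | None = None):
    """Adjust a tidy :class:`~savm.io_model.RateSchedule` (DataFrame form)."""
    from .io_model import RateSchedule

    params = params or ScenarioParams()
    init, cess = rates.to_arrays(params.years)
    init2, cess2 = apply_adjuster_arrays(init, cess, adjusters)

    def back(df, arr):
        df = df.copy()
        gi = np.where(df.gender.to_numpy() == "male", 0, 1)
        df["value"] = arr[gi, df.age.to_numpy(int), df.year.to_numpy(int) - params.start_year]
        return df

    return RateSchedule(back(rates.initiation, init2), back(rates.cessation, cess2))


def derive_schedules(
    bundle: InputBundle,
    params: ScenarioParams | None = None,
    adjusters: Adjusters | None = None,
) -> DerivedSchedules:
    """Run the full preprocessing pipeline on a validated bundle."""
    params = params or ScenarioParams()
    adjusters = adjusters or Adjusters.default()
    years = params.years

    pop = bundle.population.to_array(years)
    mc = bundle.overall_mortality_country.to_array(years)
    mr = bundle.overall_mortality_reference.to_array(years)
    status_ref = {s: bundle.reference_status_mortality[s].to_array(years) for s in STATUSES}
    mort = derive_status_mortality(mc, mr, status_ref)

    never_le = derive_never_smoker_life_expectancy(
        bundle.life_expectancy_country,
        bundle.reference_never_over_overall_le_ratio,
        params,
    )
    baseline = interpolate_group_prevalence(bundle.baseline_prevalence)
    filled = fill_ends_proportion_gaps(bundle.ends_proportions, params)
    pn, pf = expand_ends_groups_to_ages(filled, params)

    raw_init, raw_cess = bundle.rates.to_arrays(years)
    init, cess = apply_adjuster_arrays(raw_init, raw_cess, adjusters)

    return DerivedSchedules(
        years=np.asarray(years),
        pop=pop,
        mort=mort,
        never_le=never_le,
        baseline_prev=baseline,
        pn=pn,
        pf=pf,
        raw_initiation=raw_init,
        raw_cessation=raw_cess,
        initiation=init,
        cessation=cess,
    )
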