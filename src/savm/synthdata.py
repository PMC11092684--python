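"""Synthetic input bundles: a fully self-contained, license-free stand-in for
the demographic and survey schedules the simulator consumes.

Age profiles are parametric (exponential age-slope for mortality, Gaussian
initiation peak in the late teens, logistic rise of former smoking and of
cessation with age) rather than resampled real data, so every bundle is
reproducible bit-for-bit from its spec and seed.  The default fixture is
anchored to a handful of published magnitudes: reference overall mortality of
0.12% (0.04%) for 20-year-old males (females) in the first model year with a
46-52% relative decline to 2049, never-smoker life expectancy rising 7% (5%)
at age 20 over the modelling period, 15-65 current-smoking prevalence of
25.01% (8.02%) in 2009, and exclusive-ENDS proportions below 2% rising to the
last survey year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    AGE_MAX,
    AGE_MIN,
    CESSATION_AGES,
    GENDERS,
    INITIATION_AGES,
    N_AGE,
    AgeGenderYearTable,
    EndsProportionTable,
    GroupedPrevalenceTable,
    InputBundle,
    RateSchedule,
    ScenarioParams,
    ValidationError,
    parse_age_band,
)
from .preprocess import interpolate_group_prevalence

AGES = np.arange(AGE_MIN, AGE_MAX + 1)

SURVEY_YEARS = (2015, 2016, 2018, 2020, 2021, 2022)

LE_BANDS = tuple(f"{a}-{a + 4}" for a in range(0, 80, 5)) + ("80-85",)


def _interp_anchors(anchors: dict[int, float]) -> np.ndarray:
    """Piecewise-linear age curve through anchor (age, value) pairs, flat tails."""
    xs = sorted(anchors)
    return np.interp(AGES, xs, [anchors[x] for x in xs])


@dataclass
class SyntheticSpec:
    """Distributional knobs for bundle generation.

    The same spec and seed always produce the identical bundle.  Proportional
    levels must lie in [0, 1]; the generator validates the composed
    prevalence profile rather than each knob in isolation.
    """

    seed: int = 20090

    # population: persons at age 0 in 2009, exponential age decay, birth decline/yr
    pop_age0: float = 2.2e6
    pop_age_decay: float = 0.012
    birth_decline: float = 0.004

    # reference-country overall mortality: level anchors (age -> rate, first year)
    # and total relative decline over the modelling period, per gender
    mort_anchors: dict = field(default_factory=lambda: {
        "male": {20: 0.0012, 40: 0.0021, 60: 0.0113},
        "female": {20: 0.0004, 40: 0.0014, 60: 0.0068},
    })
    mort_decline: dict = field(default_factory=lambda: {
        "male": {20: 0.46, 40: 0.52, 60: 0.48},
        "female": {20: 0.43, 40: 0.49, 60: 0.47},
    })
    # status-specific relative risks vs the overall reference rate
    rr_never: float = 0.75
    rr_former: float = 1.25
    rr_current: float = 2.0
    # country/reference overall mortality ratio (the "R" the model recovers)
    country_ratio: dict = field(default_factory=lambda: {"male": 1.25, "female": 1.20})

    # overall life expectancy anchors (age -> remaining years, first anchor year)
    # and relative increase to the last anchor year, per gender
    le_base: dict = field(default_factory=lambda: {
        "male": {0: 75.0, 20: 57.0, 40: 39.0, 60: 22.0, 80: 9.0},
        "female": {0: 78.0, 20: 60.0, 40: 41.0, 60: 23.5, 80: 10.0},
    })
    le_trend: dict = field(default_factory=lambda: {
        "male": {20: 0.07, 40: 0.14, 60: 0.22},
        "female": {20: 0.05, 40: 0.10, 60: 0.18},
    })
    le_anchor_years: tuple = (2010, 2015, 2019)
    # never-smoker / overall life-expectancy ratio: 1 + slope * years-over-15 (capped)
    le_ratio_slope: float = 0.0015

    # baseline smoking prevalence profile: peak level/age/width for current,
    # logistic ceiling for former; female levels scale by the sex gap
    current_peak_level: float = 0.30
    current_peak_age: float = 32.0
    current_width: float = 25.0
    former_max: float = 0.22
    sex_gap: float = 0.32

    # initiation: Gaussian peak in the late teens with a mild secular decline;
    # cessation: linear rise with age
    initiation_peak: dict = field(default_factory=lambda: {"male": 0.020, "female": 0.008})
    initiation_peak_age: float = 16.0
    initiation_width_young: float = 3.0
    initiation_width_old: float = 7.0
    initiation_secular: float = 0.003   # relative decline per year
    cessation_base: float = 0.008
    cessation_slope: float = 0.0007

    # ENDS-PN/PF levels by band: first-survey-year -> last-survey-year, male;
    # female levels scale by ends_sex_gap; multiplicative survey jitter
    pn_levels: dict = field(default_factory=lambda: {
        "15-24": (0.004, 0.018), "25-39": (0.0015, 0.007), "40-65": (0.0004, 0.0015)})
    pf_levels: dict = field(default_factory=lambda: {
        "15-24": (0.005, 0.018), "25-39": (0.002, 0.009), "40-65": (0.0008, 0.003)})
    ends_sex_gap: float = 0.5
    ends_jitter: float = 0.03

    # additive noise scale for survey emulation
    survey_noise_scale: float = 0.005


def _reference_mortality(spec: SyntheticSpec, years: np.ndarray) -> np.ndarray:
    """Overall reference mortality ``[gender, age, year]``: log-linear age
    interpolation through the level anchors, geometric secular decline."""
    n_year = len(years)
    out = np.zeros((2, N_AGE, n_year))
    horizon = max(n_year - 1, 1)
    for g, gender in enumerate(GENDERS):
        anchors = spec.mort_anchors[gender]
        xs = sorted(anchors)
        logm = np.interp(AGES, xs, [np.log(anchors[x]) for x in xs])
        # extend the boundary log-slopes beyond the anchor range
        lo_slope = (np.log(anchors[xs[1]]) - np.log(anchors[xs[0]])) / (xs[1] - xs[0])
        hi_slope = (np.log(anchors[xs[-1]]) - np.log(anchors[xs[-2]])) / (xs[-1] - xs[-2])
        logm = np.where(AGES < xs[0], np.log(anchors[xs[0]]) + lo_slope * (AGES - xs[0]), logm)
        logm = np.where(AGES > xs[-1], np.log(anchors[xs[-1]]) + hi_slope * (AGES - xs[-1]), logm)
        base = np.exp(logm)
        decline = _interp_anchors(spec.mort_decline[gender])
        frac = (years - years[0]) / horizon
        out[g] = base[:, None] * (1.0 - decline[:, None]) ** frac[None, :]
    return np.clip(out, 1e-8, 1.0)


def _population(spec: SyntheticSpec, country_mort: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Cohort-consistent projection: the 2009 pyramid survives forward under
    country mortality while annual birth cohorts enter at age 0."""
    n_year = len(years)
    pop = np.zeros((2, N_AGE, n_year))
    for g in range(2):
        share = 0.5
        pop[g, :, 0] = share * spec.pop_age0 * np.exp(-spec.pop_age_decay * AGES)
        for t in range(n_year - 1):
            pop[g, 0, t + 1] = share * spec.pop_age0 * (1.0 - spec.birth_decline) ** (t + 1)
            pop[g, 1:, t + 1] = pop[g, :-1, t] * (1.0 - country_mort[g, :-1, t])
    return pop


def _baseline_prevalence(spec: SyntheticSpec) -> pd.DataFrame:
    rows = []
    for gender in GENDERS:
        scale = 1.0 if gender == "male" else spec.sex_gap
        for band in GroupedPrevalenceTable.BANDS:
            lo, hi = parse_age_band(band)
            a = (lo + hi) // 2
            cur = scale * spec.current_peak_level * np.exp(
                -0.5 * ((a - spec.current_peak_age) / spec.current_width) ** 2)
            fmr = scale * spec.former_max / (1.0 + np.exp(-(a - 45.0) / 8.0))
            if cur + fmr >= 1.0:
                raise ValidationError("infeasible spec: current+former prevalence >= 1")
            rows.append((band, gender, 1.0 - cur - fmr, cur, fmr))
    return pd.DataFrame(rows, columns=["age_group", "gender", "never", "current", "former"])


def _rate_schedules(spec: SyntheticSpec, years: np.ndarray) -> RateSchedule:
    rows_i, rows_c = [], []
    secular = (1.0 - spec.initiation_secular) ** (years - years[0])
    for gender in GENDERS:
        peak = spec.initiation_peak[gender]
        for a in range(INITIATION_AGES[0], INITIATION_AGES[1] + 1):
            width = (spec.initiation_width_young if a < spec.initiation_peak_age
                     else spec.initiation_width_old)
            base = peak * np.exp(-0.5 * ((a - spec.initiation_peak_age) / width) ** 2)
            for t, y in enumerate(years):
                rows_i.append((a, gender, int(y), base * secular[t]))
        for a in range(CESSATION_AGES[0], CESSATION_AGES[1] + 1):
            base = spec.cessation_base + spec.cessation_slope * (a - CESSATION_AGES[0])
            for y in years:
                rows_c.append((a, gender, int(y), base))
    cols = ["age", "gender", "year", "value"]
    return RateSchedule(pd.DataFrame(rows_i, columns=cols),
                        pd.DataFrame(rows_c, columns=cols))


def _ends_proportions(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    y0, y1 = SURVEY_YEARS[0], SURVEY_YEARS[-1]
    for gender in GENDERS:
        scale = 1.0 if gender == "male" else spec.ends_sex_gap
        for band in EndsProportionTable.BANDS:
            pn0, pn1 = spec.pn_levels[band]
            pf0, pf1 = spec.pf_levels[band]
            for y in SURVEY_YEARS:
                f = (y - y0) / (y1 - y0)
                pn = scale * (pn0 + f * (pn1 - pn0))
                pf = scale * (pf0 + f * (pf1 - pf0))
                jn = 1.0 + spec.ends_jitter * rng.standard_normal()
                jf = 1.0 + spec.ends_jitter * rng.standard_normal()
                rows.append((band, gender, int(y),
                             float(np.clip(pn * jn, 0.0, 1.0)),
                             float(np.clip(pf * jf, 0.0, 1.0))))
    return pd.DataFrame(rows, columns=["age_group", "gender", "survey_year", "pn", "pf"])


def _life_expectancy(spec: SyntheticSpec) -> pd.DataFrame:
    rows = []
    y0, y1 = spec.le_anchor_years[0], spec.le_anchor_years[-1]
    for gender in GENDERS:
        base = _interp_anchors(spec.le_base[gender])
        trend = _interp_anchors(spec.le_trend[gender])
        for y in spec.le_anchor_years:
            f = (y - y0) / (y1 - y0)
            curve = base * (1.0 + f * trend)
            for band in LE_BANDS:
                lo, hi = parse_age_band(band)
                rows.append((band, gender, int(y), float(curve[(lo + hi) // 2])))
    return pd.DataFrame(rows, columns=["age_group", "gender", "year", "value"])


def _le_ratio(spec: SyntheticSpec) -> pd.DataFrame:
    rows = []
    ratio = 1.0 + spec.le_ratio_slope * np.clip(AGES - 15, 0, 50)
    for gender in GENDERS:
        for a in AGES:
            rows.append((int(a), gender, float(ratio[a])))
    return pd.DataFrame(rows, columns=["age", "gender", "value"])


def generate_bundle(spec: SyntheticSpec | None = None,
                    params: ScenarioParams | None = None) -> InputBundle:
    """Build a complete, validated input bundle from a synthetic spec."""
    spec = spec or SyntheticSpec()
    params = params or ScenarioParams()
    years = params.years
    rng = np.random.default_rng(spec.seed)

    mort_ref = _reference_mortality(spec, years)
    ratio = np.array([[spec.country_ratio[g]] for g in GENDERS])[:, :, None]
    mort_country = np.clip(mort_ref * ratio, 0.0, 1.0)
    pop = _population(spec, mort_country, years)

    status = {
        "never": np.clip(mort_ref * spec.rr_never, 0.0, 1.0),
        "current": np.clip(mort_ref * spec.rr_current, 0.0, 1.0),
        "former": np.clip(mort_ref * spec.rr_former, 0.0, 1.0),
    }

    bundle = InputBundle(
        population=AgeGenderYearTable.from_array(pop, years, "population", "persons"),
        overall_mortality_country=AgeGenderYearTable.from_array(
            mort_country, years, "mortality_country", "rate"),
        overall_mortality_reference=AgeGenderYearTable.from_array(
            mort_ref, years, "mortality_reference", "rate"),
        reference_status_mortality={
            s: AgeGenderYearTable.from_array(a, years, f"reference_mortality_{s}", "rate")
            for s, a in status.items()
        },
        life_expectancy_country=_life_expectancy(spec),
        reference_never_over_overall_le_ratio=_le_ratio(spec),
        baseline_prevalence=GroupedPrevalenceTable(_baseline_prevalence(spec)),
        rates=_rate_schedules(spec, years),
        ends_proportions=EndsProportionTable(_ends_proportions(spec, rng)),
    )
    return bundle.validate(params)


#: 15-65 current-smoking prevalence targets for the default fixture's baseline year
FIXTURE_PREVALENCE_2009 = {"male": 0.2501, "female": 0.0802}


def default_fixture(params: ScenarioParams | None = None) -> InputBundle:
    """The deterministic packaged bundle.

    Starts from the default :class:`SyntheticSpec` and rescales the grouped
    current-smoking prevalence so that the population-weighted 15-65
    aggregate in the baseline year lands exactly on the fixture targets
    (25.01% male, 8.02% female).  Rescaling bands rescales the interpolated
    single-age curve linearly, so the match is exact by construction.
    """
    params = params or ScenarioParams()
    bundle = generate_bundle(SyntheticSpec(), params)
    pop = bundle.population.to_array(params.years)
    prev = interpolate_group_prevalence(bundle.baseline_prevalence)
    lo, hi = params.reported_age_range
    df = bundle.baseline_prevalence.df.copy()
    for g, gender in enumerate(GENDERS):
        w = pop[g, lo : hi + 1, 0]
        achieved = float((prev[1, g, lo : hi + 1] * w).sum() / w.sum())
        factor = FIXTURE_PREVALENCE_2009[gender] / achieved
        sel = df.gender == gender
        df.loc[sel, "current"] *= factor
        df.loc[sel, "never"] = 1.0 - df.loc[sel, "current"] - df.loc[sel, "former"]
    bundle.baseline_prevalence = GroupedPrevalenceTable(df).validate()
    return bundle


def band_prevalence(traj, band: str, year: int) -> dict[str, float]:
    """Population-weighted current-smoking prevalence of an age band at one year."""
    lo, hi = parse_age_band(band)
    t = int(year) - int(traj.years[0])
    occ = traj.state_occupancy("current_smoker")[t]       # [gender, age]
    out = {}
    for g, gender in enumerate(GENDERS):
        w = traj.pop[g, lo : hi + 1, t]
        out[gender] = float((occ[g, lo : hi + 1] * w).sum() / w.sum())
    return out


def emulate_survey(traj, years, bands=("15-24", "25-39", "40-65", "15-65"),
                   noise_scale: float | None = None, seed: int = 0) -> pd.DataFrame:
    """Survey-style current-smoking prevalence tables from a model trajectory.

    Additive Gaussian noise of the declared scale emulates sampling error;
    scale zero reproduces the model prevalences exactly (used for noise-free
    calibration round trips).
    """
    if noise_scale is None:
        noise_scale = SyntheticSpec().survey_noise_scale
    rng = np.random.default_rng(seed)
    rows = []
    for year in years:
        for band in bands:
            p = band_prevalence(traj, band, year)
            for gender in GENDERS:
                v = p[gender] + (noise_scale * rng.standard_normal() if noise_scale else 0.0)
                rows.append((gender, band, int(year), float(np.clip(v, 0.0, 1.0))))
    return pd.DataFrame(rows, columns=["gender", "age_band", "year", "prevalence"])
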