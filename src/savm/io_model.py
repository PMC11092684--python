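"""Domain types, CSV readers/writers and run configuration.

All tables are stored long/tidy (``age, gender, year, value``), UTF-8,
comma-separated, with a header row.  Gender is coded ``"male"``/``"female"``.
Ages are integer years attained at the start of the model year; years are
calendar years.  Proportions are fractions in [0, 1] everywhere inside the
package; percent formatting happens only at the reporting layer.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("savm")

GENDERS = ("male", "female")
AGE_MIN = 0
AGE_MAX = 85
N_AGE = AGE_MAX - AGE_MIN + 1

#: reported use/risk states, in reporting order
STATES = (
    "never_nonuser",
    "current_smoker",
    "former_lt35",
    "former_ge35",
    "n_ends",
    "fs_ends",
    "former_ends_user",
)

STATUSES = ("never", "current", "former")

INITIATION_AGES = (6, 39)
CESSATION_AGES = (11, 65)


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the requested level."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


class ValidationError(ValueError):
    """An input table or parameter set violates one of its invariants."""


class InputError(IOError):
    """A referenced input file is missing or unreadable."""


def parse_age_band(label: str) -> tuple[int, int]:
    """Parse an age-band label like ``"15-19"``, ``"40+"`` or ``"65"``.

    Open-ended bands map their upper bound to the maximum modelled age.
    """
    label = str(label).strip()
    if label.endswith("+"):
        return int(label[:-1]), AGE_MAX
    if "-" in label:
        lo, hi = label.split("-")
        return int(lo), int(hi)
    a = int(label)
    return a, a


def band_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}" if hi < AGE_MAX else f"{lo}+"


def mid_age(lo: int, hi: int) -> int:
    """Integer mid-age of a band: 15-19 -> 17, 60-65 -> 62."""
    return (lo + hi) // 2


def _check_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")


def _check_complete(df: pd.DataFrame, name: str, ages, years=None) -> None:
    """Require a complete rectangular (age, gender[, year]) index."""
    keys = ["age", "gender"] + (["year"] if years is not None else [])
    levels = [list(ages), list(GENDERS)] + ([list(years)] if years is not None else [])
    want = pd.MultiIndex.from_product(levels, names=keys)
    have = pd.MultiIndex.from_frame(df[keys])
    if have.has_duplicates:
        dup = df[have.duplicated()].iloc[0]
        raise ValidationError(f"{name}: duplicate cell {tuple(dup[k] for k in keys)}")
    gap = want.difference(have)
    if len(gap):
        raise ValidationError(
            f"{name}: {len(gap)} missing cell(s), first {tuple(gap[0])} "
            f"(index must cover ages {min(ages)}-{max(ages)}"
            + (f", years {min(years)}-{max(years)})" if years is not None else ")")
        )


@dataclass
class AgeGenderYearTable:
    """A non-negative quantity indexed by single age, gender and year.

    ``kind`` selects range checks: ``"rate"`` and ``"proportion"`` must lie in
    [0, 1]; ``"persons"`` and ``"years"`` only need to be non-negative.
    """

    df: pd.DataFrame
    name: str = "table"
    kind: str = "persons"

    def validate(self, ages=range(AGE_MIN, AGE_MAX + 1), years=None) -> "AgeGenderYearTable":
        _check_columns(self.df, ("age", "gender", "year", "value"), self.name)
        v = self.df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{self.name}: non-finite value")
        if (v < 0).any():
            bad = self.df[v < 0].iloc[0]
            raise ValidationError(
                f"{self.name}: negative value at age={bad.age} gender={bad.gender} year={bad.year}"
            )
        if self.kind in ("rate", "proportion") and (v > 1).any():
            bad = self.df[v > 1].iloc[0]
            raise ValidationError(
                f"{self.name}: value > 1 at age={bad.age} gender={bad.gender} year={bad.year} "
                f"(rule: {self.kind} in [0,1])"
            )
        _check_complete(self.df, self.name, ages, years)
        return self

    def to_array(self, years) -> np.ndarray:
        """Dense ``[gender, age, year]`` array over ages 0..85 and the given years."""
        years = list(years)
        out = np.zeros((2, N_AGE, len(years)))
        piv = self.df.pivot_table(index=["gender", "age"], columns="year", values="value")
        piv = piv.reindex(columns=years)
        for g, gender in enumerate(GENDERS):
            sub = piv.loc[gender].reindex(range(AGE_MIN, AGE_MAX + 1))
            out[g] = sub.to_numpy(dtype=float)
        if not np.all(np.isfinite(out)):
            raise ValidationError(f"{self.name}: incomplete coverage of ages/years")
        return out

    @staticmethod
    def from_array(arr: np.ndarray, years, name: str, kind: str = "persons") -> "AgeGenderYearTable":
        years = np.asarray(list(years))
        g_ix, a_ix, y_ix = np.meshgrid(
            np.arange(2), np.arange(N_AGE), np.arange(len(years)), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "age": a_ix.ravel(),
                "gender": np.array(GENDERS)[g_ix.ravel()],
                "year": years[y_ix.ravel()],
                "value": arr.ravel(),
            }
        )
        return AgeGenderYearTable(df, name=name, kind=kind)


@dataclass
class GroupedPrevalenceTable:
    """Baseline never/current/former smoking prevalence by 5-year band and gender."""

    df: pd.DataFrame  # columns: age_group, gender, never, current, former

    BANDS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44",
             "45-49", "50-54", "55-59", "60-65")

    def validate(self) -> "GroupedPrevalenceTable":
        _check_columns(self.df, ("age_group", "gender", "never", "current", "former"),
                       "baseline_prevalence")
        for gender in GENDERS:
            sub = self.df[self.df.gender == gender]
            have = set(sub.age_group)
            missing = [b for b in self.BANDS if b not in have]
            if missing:
                raise ValidationError(
                    f"baseline_prevalence: gender={gender} missing band(s) {missing}"
                )
        vals = self.df[["never", "current", "former"]].to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("baseline_prevalence: proportions must lie in [0,1]")
        s = vals.sum(axis=1)
        bad = np.abs(s - 1.0) > 1e-9
        if bad.any():
            row = self.df[bad].iloc[0]
            raise ValidationError(
                f"baseline_prevalence: never+current+former={s[bad][0]:.6g} != 1 at "
                f"age_group={row.age_group} gender={row.gender} (rule: sums to 1 +/- 1e-9)"
            )
        return self

    def values(self, gender: str, column: str) -> np.ndarray:
        sub = self.df[self.df.gender == gender].set_index("age_group")
        return sub.loc[list(self.BANDS), column].to_numpy(dtype=float)


@dataclass
class RateSchedule:
    """Smoking initiation (ages 6-39) and cessation (ages 11-65) rate schedules."""

    initiation: pd.DataFrame  # age, gender, year, value
    cessation: pd.DataFrame

    def validate(self, years) -> "RateSchedule":
        for name, df, (lo, hi) in (
            ("initiation", self.initiation, INITIATION_AGES),
            ("cessation", self.cessation, CESSATION_AGES),
        ):
            t = AgeGenderYearTable(df, name=name, kind="rate")
            t.validate(ages=range(lo, hi + 1), years=years)
            out = df[(df.age < lo) | (df.age > hi)]
            if len(out) and (out["value"] != 0).any():
                raise ValidationError(f"{name}: non-zero rate outside ages {lo}-{hi}")
        return self

    def to_arrays(self, years) -> tuple[np.ndarray, np.ndarray]:
        """Dense ``[gender, age, year]`` arrays, zero outside the age windows."""
        init = _window_array(self.initiation, years, INITIATION_AGES)
        cess = _window_array(self.cessation, years, CESSATION_AGES)
        return init, cess


def _window_array(df: pd.DataFrame, years, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    years = list(years)
    out = np.zeros((2, N_AGE, len(years)))
    sub = df[(df.age >= lo) & (df.age <= hi)]
    piv = sub.pivot_table(index=["gender", "age"], columns="year", values="value")
    piv = piv.reindex(columns=years)
    for g, gender in enumerate(GENDERS):
        block = piv.loc[gender].reindex(range(lo, hi + 1)).to_numpy(dtype=float)
        if not np.all(np.isfinite(block)):
            raise ValidationError(f"rate schedule: incomplete ages {lo}-{hi} for {gender}")
        out[g, lo : hi + 1, :] = block
    return out


@dataclass
class EndsProportionTable:
    """ENDS-PN / ENDS-PF by coarse age band, gender and survey year.

    ENDS-PN is the proportion of never smokers who currently use ENDS;
    ENDS-PF the proportion of former smokers who currently use ENDS.
    """

    df: pd.DataFrame  # columns: age_group, gender, survey_year, pn, pf

    BANDS = ("15-24", "25-39", "40-65")

    def validate(self) -> "EndsProportionTable":
        _check_columns(self.df, ("age_group", "gender", "survey_year", "pn", "pf"),
                       "ends_proportions")
        vals = self.df[["pn", "pf"]].to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("ends_proportions: pn/pf must lie in [0,1]")
        years = sorted(self.df.survey_year.unique())
        if not years:
            raise ValidationError("ends_proportions: no survey years")
        spans = [parse_age_band(b) for b in sorted(set(self.df.age_group), key=str)]
        spans.sort()
        for (lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValidationError(
                    f"ends_proportions: overlapping bands {band_label(lo1, hi1)} / "
                    f"{band_label(lo2, _hi2)}"
                )
        for gender in GENDERS:
            for y in years:
                sub = self.df[(self.df.gender == gender) & (self.df.survey_year == y)]
                have = set(sub.age_group)
                missing = [b for b in self.BANDS if b not in have]
                if missing:
                    raise ValidationError(
                        f"ends_proportions: gender={gender} survey_year={y} missing {missing}"
                    )
        return self

    @property
    def survey_years(self) -> list[int]:
        return sorted(self.df.survey_year.unique())


# band keys used throughout: (lo, hi) inclusive integer ages
InitBands = ((15, 24), (25, 40))
CessBands = ((25, 39), (40, AGE_MAX))
SwitchBands = ((0, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, AGE_MAX))


@dataclass(frozen=True)
class Adjusters:
    """Calibration scalers applied to the initiation/cessation schedules.

    ``initiation[gender][(15, 24)]`` etc.; ages outside every band are left
    unscaled.  Age 40 belongs to the 25-40 initiation band and to the 40+
    cessation band.
    """

    initiation: Mapping[str, Mapping[tuple[int, int], float]]
    cessation: Mapping[str, Mapping[tuple[int, int], float]]

    def __post_init__(self):
        for part in (self.initiation, self.cessation):
            for gender, bands in part.items():
                for band, v in bands.items():
                    if v < 0:
                        raise ValidationError(
                            f"adjuster for {gender} band {band} is negative ({v})"
                        )

    @classmethod
    def unit(cls) -> "Adjusters":
        one_i = {b: 1.0 for b in InitBands}
        one_c = {b: 1.0 for b in CessBands}
        return cls({g: dict(one_i) for g in GENDERS}, {g: dict(one_c) for g in GENDERS})

    @classmethod
    def default(cls) -> "Adjusters":
        """The packaged calibration: male (female) initiation 1.52 (1.53) at
        15-24 and 1.78 (1.56) at 25-40; cessation 0.50 (0.50) at 25-39 and
        0.48 (0.00) at 40+."""
        return cls(
            initiation={
                "male": {(15, 24): 1.52, (25, 40): 1.78},
                "female": {(15, 24): 1.53, (25, 40): 1.56},
            },
            cessation={
                "male": {(25, 39): 0.50, (40, AGE_MAX): 0.48},
                "female": {(25, 39): 0.50, (40, AGE_MAX): 0.00},
            },
        )

    def as_flat(self) -> dict[str, float]:
        out = {}
        for g in GENDERS:
            for (lo, hi), v in self.initiation[g].items():
                out[f"initiation_{g}_{lo}_{hi}"] = v
            for (lo, hi), v in self.cessation[g].items():
                out[f"cessation_{g}_{lo}_{hi}"] = v
        return out


def _default_switching() -> dict[str, dict[tuple[int, int], float]]:
    # Reference (100% PATH 2013-2017) smoker->exclusive-ENDS switching rates;
    # the applied rate is switching_scale x reference (0.50 by default, i.e.
    # male 2.0%/yr under 25, female 1.3%/yr, ...).
    male = (0.040, 0.026, 0.026, 0.014, 0.012, 0.006)
    female = (0.026, 0.020, 0.016, 0.014, 0.014, 0.010)
    return {
        "male": dict(zip(SwitchBands, male)),
        "female": dict(zip(SwitchBands, female)),
    }


@dataclass
class ScenarioParams:
    """Scenario timing, multipliers and switching rates.

    The Unrestricted scenario applies ``smoking_initiation_multiplier`` (0.75)
    and ``ends_initiation_multiplier`` (0.50) to the adjusted Restricted
    smoking-initiation schedule, cessation multipliers of 1.00, and
    smoker-to-ENDS switching at ``switching_scale`` (0.50) of the reference
    rates.  ``ends_risk_multiplier`` expresses ENDS excess mortality as a
    fraction of smoking's excess mortality (0.15; sensitivity 0.05/0.25).
    """

    smoking_initiation_multiplier: float = 0.75
    ends_initiation_multiplier: float = 0.50
    smoking_cessation_multiplier: float = 1.00
    ends_cessation_multiplier: float = 1.00
    switching_rate: Mapping[str, Mapping[tuple[int, int], float]] = field(
        default_factory=_default_switching
    )
    switching_scale: float = 0.50
    ends_risk_multiplier: float = 0.15
    ban_lift_year: int = 2024
    ends_start_year: int = 2015
    quit_age_threshold: int = 35
    start_year: int = 2009
    end_year: int = 2049
    reported_age_range: tuple[int, int] = (15, 65)

    def __post_init__(self):
        for name in ("smoking_initiation_multiplier", "ends_initiation_multiplier",
                     "smoking_cessation_multiplier", "ends_cessation_multiplier",
                     "switching_scale", "ends_risk_multiplier"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (self.start_year <= self.ban_lift_year <= self.end_year):
            raise ValidationError("ban_lift_year must lie within [start_year, end_year]")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def year_index(self, year: int) -> int:
        return int(year) - self.start_year

    def switching_array(self) -> np.ndarray:
        """Applied switching rates by ``[gender, age]`` (scale x reference)."""
        out = np.zeros((2, N_AGE))
        for g, gender in enumerate(GENDERS):
            for (lo, hi), v in self.switching_rate[gender].items():
                out[g, lo : hi + 1] = self.switching_scale * v
        return out

    def replace(self, **kw) -> "ScenarioParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["switching_rate"] = {
            g: {band_label(*b): v for b, v in bands.items()}
            for g, bands in self.switching_rate.items()
        }
        d["reported_age_range"] = list(self.reported_age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioParams":
        d = dict(d)
        if "switching_rate" in d:
            d["switching_rate"] = {
                g: {parse_age_band(b): float(v) for b, v in bands.items()}
                for g, bands in d["switching_rate"].items()
            }
        if "reported_age_range" in d:
            d["reported_age_range"] = tuple(d["reported_age_range"])
        return cls(**d)


@dataclass
class InputBundle:
    """The full set of demographic and epidemiologic schedules the engine consumes."""

    population: AgeGenderYearTable
    overall_mortality_country: AgeGenderYearTable
    overall_mortality_reference: AgeGenderYearTable
    reference_status_mortality: Mapping[str, AgeGenderYearTable]
    life_expectancy_country: pd.DataFrame  # age_group, gender, year, value (anchor years)
    reference_never_over_overall_le_ratio: pd.DataFrame  # age, gender, value
    baseline_prevalence: GroupedPrevalenceTable
    rates: RateSchedule
    ends_proportions: EndsProportionTable

    def validate(self, params: ScenarioParams | None = None) -> "InputBundle":
        params = params or ScenarioParams()
        years = range(params.start_year, params.end_year + 1)
        self.population.validate(years=years)
        self.overall_mortality_country.validate(years=years)
        self.overall_mortality_reference.validate(years=years)
        for s in STATUSES:
            if s not in self.reference_status_mortality:
                raise ValidationError(f"reference_status_mortality: missing status '{s}'")
            self.reference_status_mortality[s].validate(years=years)
        _check_columns(self.life_expectancy_country, ("age_group", "gender", "year", "value"),
                       "life_expectancy")
        if len(self.life_expectancy_country.year.unique()) < 1:
            raise ValidationError("life_expectancy: needs at least one anchor year")
        if (self.life_expectancy_country["value"] <= 0).any():
            raise ValidationError("life_expectancy: values must be positive")
        _check_columns(self.reference_never_over_overall_le_ratio, ("age", "gender", "value"),
                       "le_ratio")
        if (self.reference_never_over_overall_le_ratio["value"] <= 0).any():
            raise ValidationError("le_ratio: values must be positive")
        self.baseline_prevalence.validate()
        self.rates.validate(years=years)
        self.ends_proportions.validate()
        return self


BUNDLE_FILES = {
    "population": "population.csv",
    "mortality_country": "mortality_country.csv",
    "mortality_reference": "mortality_reference.csv",
    "mortality_reference_status": "mortality_reference_status.csv",
    "life_expectancy": "life_expectancy.csv",
    "le_ratio": "le_ratio.csv",
    "baseline_prevalence": "baseline_prevalence.csv",
    "initiation": "initiation.csv",
    "cessation": "cessation.csv",
    "ends_proportions": "ends_proportions.csv",
}


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    return pd.read_csv(path)


def read_input_bundle(paths: Mapping[str, Path] | Path | str,
                      params: ScenarioParams | None = None) -> InputBundle:
    """Read and validate a full input bundle.

    ``paths`` is either a directory containing the canonical file names
    (:data:`BUNDLE_FILES`) or an explicit key -> path mapping.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = {k: root / v for k, v in BUNDLE_FILES.items()}
    status_df = _read_csv(paths["mortality_reference_status"])
    _check_columns(status_df, ("status", "age", "gender", "year", "value"),
                   "mortality_reference_status")
    status = {
        s: AgeGenderYearTable(
            status_df[status_df.status == s].drop(columns="status").reset_index(drop=True),
            name=f"reference_mortality_{s}", kind="rate")
        for s in STATUSES
    }
    bundle = InputBundle(
        population=AgeGenderYearTable(_read_csv(paths["population"]), "population", "persons"),
        overall_mortality_country=AgeGenderYearTable(
            _read_csv(paths["mortality_country"]), "mortality_country", "rate"),
        overall_mortality_reference=AgeGenderYearTable(
            _read_csv(paths["mortality_reference"]), "mortality_reference", "rate"),
        reference_status_mortality=status,
        life_expectancy_country=_read_csv(paths["life_expectancy"]),
        reference_never_over_overall_le_ratio=_read_csv(paths["le_ratio"]),
        baseline_prevalence=GroupedPrevalenceTable(_read_csv(paths["baseline_prevalence"])),
        rates=RateSchedule(_read_csv(paths["initiation"]), _read_csv(paths["cessation"])),
        ends_proportions=EndsProportionTable(_read_csv(paths["ends_proportions"])),
    )
    return bundle.validate(params)


FLOAT_FMT = "%.12g"  # read-back equals written to >= 10 significant digits


def write_input_bundle(bundle: InputBundle, directory: Path | str) -> dict[str, Path]:
    """Write a bundle to ``directory`` in the canonical CSV layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    def put(key, df):
        p = directory / BUNDLE_FILES[key]
        df.to_csv(p, index=False, float_format=FLOAT_FMT)
        out[key] = p

    put("population", bundle.population.df)
    put("mortality_country", bundle.overall_mortality_country.df)
    put("mortality_reference", bundle.overall_mortality_reference.df)
    status = pd.concat(
        [t.df.assign(status=s) for s, t in bundle.reference_status_mortality.items()],
        ignore_index=True,
    )[["status", "age", "gender", "year", "value"]]
    put("mortality_reference_status", status)
    put("life_expectancy", bundle.life_expectancy_country)
    put("le_ratio", bundle.reference_never_over_overall_le_ratio)
    put("baseline_prevalence", bundle.baseline_prevalence.df)
    put("initiation", bundle.rates.initiation)
    put("cessation", bundle.rates.cessation)
    put("ends_proportions", bundle.ends_proportions.df)
    return out


def write_outputs(trajectories: Mapping[str, "object"], impact, directory: Path | str,
                  params: ScenarioParams | None = None) -> dict[str, Path]:
    """Write trajectory and impact CSVs plus a resolved-config snapshot.

    ``trajectories`` maps scenario name -> Trajectory.  ``impact`` may be None
    (single-scenario runs).  Returns the file-path map.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # pragma: no cover - environment dependent
        raise InputError(f"cannot create output directory {directory}: {e}")
    out: dict[str, Path] = {}
    frames = []
    for which, traj in trajectories.items():
        frames.append(traj.to_frame().assign(scenario=which))
    if not frames or all(len(f) == 0 for f in frames):
        raise ValidationError("no rows to write")
    prev = pd.concat(frames, ignore_index=True)
    p = directory / "prevalence.csv"
    prev.to_csv(p, index=False, float_format=FLOAT_FMT)
    out["prevalence"] = p
    if impact is not None:
        p = directory / "impact_yearly.csv"
        impact.yearly_frame().to_csv(p, index=False, float_format=FLOAT_FMT)
        out["impact_yearly"] = p
        p = directory / "impact_totals.csv"
        impact.totals_frame().to_csv(p, index=False, float_format=FLOAT_FMT)
        out["impact_totals"] = p
    if params is not None:
        p = directory / "config_resolved.yaml"
        p.write_text(yaml.safe_dump({"scenario_params": params.to_dict()}, sort_keys=False))
        out["config"] = p
    log.info("wrote %d output file(s) to %s", len(out), directory)
    return out


@dataclass
class RunConfig:
    """Resolved run configuration: input locations, parameters, outputs."""

    input_dir: Path
    params: ScenarioParams = field(default_factory=ScenarioParams)
    adjusters: Adjusters = field(default_factory=Adjusters.default)
    output_dir: Path = Path("savm_out")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")


def _adjusters_to_dict(adj: Adjusters) -> dict:
    return {
        "initiation": {g: {band_label(*b): v for b, v in adj.initiation[g].items()}
                       for g in GENDERS},
        "cessation": {g: {band_label(*b): v for b, v in adj.cessation[g].items()}
                      for g in GENDERS},
    }


def _adjusters_from_dict(d: Mapping) -> Adjusters:
    return Adjusters(
        initiation={g: {parse_age_band(b): float(v) for b, v in d["initiation"][g].items()}
                    for g in GENDERS},
        cessation={g: {parse_age_band(b): float(v) for b, v in d["cessation"][g].items()}
                   for g in GENDERS},
    )


def load_config(path: Path | str) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    params = ScenarioParams.from_dict(raw.get("scenario_params", {}))
    adj = (_adjusters_from_dict(raw["adjusters"]) if "adjusters" in raw
           else Adjusters.default())
    return RunConfig(
        input_dir=Path(raw.get("input_dir", ".")),
        params=params,
        adjusters=adj,
        output_dir=Path(raw.get("output_dir", "savm_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def save_config(cfg: RunConfig, path: Path | str) -> None:
    d = {
        "input_dir": str(cfg.input_dir),
        "scenario_params": cfg.params.to_dict(),
        "adjusters": _adjusters_to_dict(cfg.adjusters),
        "output_dir": str(cfg.output_dir),
        "seed": cfg.seed,
        "log_level": cfg.log_level,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
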