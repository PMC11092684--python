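"""Calibration of rate adjusters, ENDS-proportion recalibration, and validation.

Calibration matches the model's relative changes in current-smoking
prevalence between a base and a comparison year (by gender and age band)
to survey-observed relative changes, by scaling the initiation and cessation
schedules with fixed band adjusters.  The fit minimises the sum of squared
differences with a bounded coordinate grid search: the objective is cheap to
evaluate, non-smooth where rate clipping engages, and deterministic for a
given search spec.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory, run_scenario
from .impact import relative_change
from .io_model import (
    GENDERS,
    Adjusters,
    CessBands,
    EndsProportionTable,
    InitBands,
    ScenarioParams,
    ValidationError,
    parse_age_band,
)
from .preprocess import DerivedSchedules

log = logging.getLogger("savm.calibrate")


@dataclass(frozen=True)
class CalibrationTarget:
    """An observed relative prevalence change the model should reproduce."""

    quantity: str               # current_smoking_prevalence | exclusive_ends_prevalence
    gender: str
    age_band: str               # e.g. "15-24" or "15-65"
    year_pair: tuple[int, int]  # (base, comparison)
    observed_relative_change: float

    def __post_init__(self):
        if self.year_pair[0] >= self.year_pair[1]:
            raise ValidationError("target base year must precede the comparison year")


@dataclass
class SearchSpec:
    """Coordinate grid-search settings: shared bounds, step and sweep limit."""

    lower: float = 0.0
    upper: float = 3.0
    step: float = 0.01
    max_sweeps: int = 10

    def grid(self) -> np.ndarray:
        n = int(round((self.upper - self.lower) / self.step))
        return self.lower + self.step * np.arange(n + 1)


def _band_ages(band: str) -> tuple[int, int]:
    return parse_age_band(band)


def _band_prevalence(traj: Trajectory, quantity: str, gender: str, band: str,
                     year: int) -> float:
    lo, hi = _band_ages(band)
    g = GENDERS.index(gender)
    t = int(year) - int(traj.years[0])
    if quantity == "current_smoking_prevalence":
        occ = traj.state_occupancy("current_smoker")[t, g]
    elif quantity == "exclusive_ends_prevalence":
        occ = (traj.state_occupancy("n_ends")[t, g]
               + traj.state_occupancy("fs_ends")[t, g])
    else:
        raise ValidationError(f"unknown target quantity '{quantity}'")
    w = traj.pop[g, lo : hi + 1, t]
    return float((occ[lo : hi + 1] * w).sum() / w.sum())


def model_relative_changes(derived: DerivedSchedules, params: ScenarioParams,
                           adjusters: Adjusters,
                           targets: list[CalibrationTarget]) -> np.ndarray:
    """Modelled relative changes for each target under candidate adjusters."""
    stop = max(t.year_pair[1] for t in targets)
    traj = run_scenario(derived.with_adjusters(adjusters), params, "restricted",
                        stop_year=stop)
    out = np.empty(len(targets))
    for i, tg in enumerate(targets):
        base = _band_prevalence(traj, tg.quantity, tg.gender, tg.age_band, tg.year_pair[0])
        comp = _band_prevalence(traj, tg.quantity, tg.gender, tg.age_band, tg.year_pair[1])
        out[i] = relative_change(base, comp)
    return out


# the adjuster coordinates searched per gender, in sweep order
_COORDS = [("initiation", InitBands[0]), ("initiation", InitBands[1]),
           ("cessation", CessBands[0]), ("cessation", CessBands[1])]


def fit_adjusters(derived: DerivedSchedules, targets: list[CalibrationTarget],
                  params: ScenarioParams | None = None,
                  search: SearchSpec | None = None) -> tuple[Adjusters, dict]:
    """Fit band adjusters to relative-change targets by coordinate grid search.

    Genders are independent in the model, so each gender's four adjusters are
    fitted against that gender's targets only.  Returns the best adjusters
    plus diagnostics (objective value, per-target residuals, sweep count).
    Deterministic for a given search spec.
    """
    params = params or ScenarioParams()
    search = search or SearchSpec()
    grid = search.grid()
    diagnostics: dict = {"per_gender": {}}
    values = {g: {"initiation": {b: 1.0 for b in InitBands},
                  "cessation": {b: 1.0 for b in CessBands}} for g in GENDERS}

    for gender in GENDERS:
        g_targets = [t for t in targets if t.gender == gender]
        if not g_targets:
            continue
        if len(g_targets) < len(_COORDS):
            log.warning("calibration for %s: %d target(s) for %d adjusters; "
                        "the fit may be unidentifiable", gender, len(g_targets),
                        len(_COORDS))
            diagnostics.setdefault("warnings", []).append(
                f"{gender}: fewer targets ({len(g_targets)}) than adjusted bands")
        obs = np.array([t.observed_relative_change for t in g_targets])

        def objective() -> float:
            adj = _assemble(values)
            model = model_relative_changes(derived, params, adj, g_targets)
            return float(((model - obs) ** 2).sum())

        best = objective()
        sweeps = 0
        for sweep in range(search.max_sweeps):
            improved = False
            for part, band in _COORDS:
                current = values[gender][part][band]
                best_v, best_obj = current, best
                for v in grid:
                    values[gender][part][band] = float(v)
                    obj = objective()
                    if obj < best_obj - 1e-15:
                        best_v, best_obj = float(v), obj
                values[gender][part][band] = best_v
                if abs(best_v - current) > 1e-12:
                    improved = True
                best = best_obj
            sweeps = sweep + 1
            if not improved:
                break
        adj = _assemble(values)
        model = model_relative_changes(derived, params, adj, g_targets)
        diagnostics["per_gender"][gender] = {
            "objective": best,
            "sweeps": sweeps,
            "residuals": (model - obs).tolist(),
        }
    return _assemble(values), diagnostics


def _assemble(values: dict) -> Adjusters:
    return Adjusters(
        initiation={g: dict(values[g]["initiation"]) for g in GENDERS},
        cessation={g: dict(values[g]["cessation"]) for g in GENDERS},
    )


def recalibrate_ends_proportions(
    table: EndsProportionTable,
    traj_uncalibrated: Trajectory,
    observed: pd.DataFrame,
) -> EndsProportionTable:
    """Rescale ENDS-PN/PF where the uncalibrated model misses observed ENDS use.

    For each observed (gender, age band, year): the replacement value is
    ``(observed exclusive-ENDS prevalence / modelled exclusive-ENDS
    prevalence) x`` the original ENDS-PN (and likewise ENDS-PF).  Cells
    without an observation pass through unchanged; cells where the model
    predicts zero are skipped with a warning.

    ``observed`` columns: gender, age_band, year, prevalence.
    """
    df = table.df.copy()
    for _, row in observed.iterrows():
        modelled = _band_prevalence(traj_uncalibrated, "exclusive_ends_prevalence",
                                    row.gender, row.age_band, int(row.year))
        if modelled <= 0:
            if row.prevalence > 0:
                log.warning("recalibration skipped for %s %s %d: modelled ENDS "
                            "prevalence is zero", row.gender, row.age_band, int(row.year))
            continue
        ratio = float(row.prevalence) / modelled
        sel = ((df.gender == row.gender) & (df.age_group == row.age_band)
               & (df.survey_year == int(row.year)))
        df.loc[sel, "pn"] = np.clip(df.loc[sel, "pn"] * ratio, 0.0, 1.0)
        df.loc[sel, "pf"] = np.clip(df.loc[sel, "pf"] * ratio, 0.0, 1.0)
    return EndsProportionTable(df).validate()


def validate_relative_changes(traj: Trajectory, survey: pd.DataFrame,
                              year_pairs: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Model-vs-survey relative changes in current smoking prevalence.

    ``survey`` columns: gender, age_band, year, prevalence.  Year pairs
    default to every (first survey year, later survey year) combination
    present.  Returns one row per gender, band and year pair with the model
    change, the survey change and their difference.
    """
    years = sorted(survey.year.unique())
    if year_pairs is None:
        year_pairs = [(years[0], y) for y in years[1:]]
    rows = []
    for gender in GENDERS:
        for band in sorted(survey.age_band.unique()):
            sub = survey[(survey.gender == gender) & (survey.age_band == band)]
            series = sub.set_index("year")["prevalence"]
            for base, comp in year_pairs:
                if base not in series.index or comp not in series.index:
                    raise ValidationError(
                        f"survey series missing year {base} or {comp} for "
                        f"{gender} {band}")
                model_rc = relative_change(
                    _band_prevalence(traj, "current_smoking_prevalence", gender, band, base),
                    _band_prevalence(traj, "current_smoking_prevalence", gender, band, comp))
                survey_rc = relative_change(float(series.loc[base]), float(series.loc[comp]))
                rows.append((gender, band, base, comp, model_rc, survey_rc,
                             model_rc - survey_rc))
    return pd.DataFrame(rows, columns=[
        "gender", "age_band", "base_year", "comparison_year",
        "model_relative_change", "survey_relative_change", "difference"])
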