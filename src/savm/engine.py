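"""Discrete-time cohort state-transition simulator for both ENDS scenarios.

The model steps every cohort (birth years 1924-2049, ages 0-85) annually from
2009 to 2049.  Seven use/risk states are reported; internally nine slots are
tracked so that exclusive-ENDS users and former ENDS users remember whether
they carry never-smoker or former-smoker mortality risk:

====  =================  =============== =========================================
slot  reported state     risk class      meaning
====  =================  =============== =========================================
NV    never_nonuser      never           never used cigarettes or ENDS
CS    current_smoker     current         current (daily or nondaily) smoker
FLT   former_lt35        never           quit smoking before age 35
FGE   former_ge35        former          quit smoking at age 35 or later
NEN   n_ends             never           exclusive ENDS, never smoked
NEF   n_ends             never           exclusive ENDS, quit smoking before 35
FSE   fs_ends            former          exclusive ENDS, quit smoking at 35+
FUN   former_ends_user   never           quit ENDS, never-smoker risk class
FUF   former_ends_user   former          quit ENDS, former-smoker risk class
====  =================  =============== =========================================

Within a year the update order is: status-specific survival, renormalisation
of the cohort to the external population projection, smoking initiation,
(Unrestricted only) ENDS initiation and smoker-to-ENDS switching, smoking
cessation, (Unrestricted only) ENDS cessation; then cohorts age one year and
(Restricted stepping only) the cross-sectional ENDS-PN/PF overlay is applied
at the arrival year.  Competing outflows are sequential: each rate applies to
the mass remaining after the previous flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import GENDERS, N_AGE, STATES, ScenarioParams, ValidationError
from .preprocess import DerivedSchedules

# internal slot indices
NV, CS, FLT, FGE, NEN, NEF, FSE, FUN, FUF = range(9)
N_SLOT = 9

SLOT_NAMES = ("NV", "CS", "FLT", "FGE", "NEN", "NEF", "FSE", "FUN", "FUF")

#: mortality risk class used for within-cohort composition, per slot
SLOT_RISK = ("never", "current", "never", "former", "never", "never",
             "former", "never", "former")

#: reported state -> internal slots
STATE_SLOTS = {
    "never_nonuser": (NV,),
    "current_smoker": (CS,),
    "former_lt35": (FLT,),
    "former_ge35": (FGE,),
    "n_ends": (NEN, NEF),
    "fs_ends": (FSE,),
    "former_ends_user": (FUN, FUF),
}


def initialize_cohorts(derived: DerivedSchedules, params: ScenarioParams) -> np.ndarray:
    """State occupancies ``[gender, slot, age]`` at the start year.

    Each age is filled from the interpolated baseline prevalence; former
    smokers split by attained age against the quit-age threshold (below the
    threshold they carry never-smoker risk).  ENDS states start empty.
    """
    sums = derived.baseline_prev.sum(axis=0)
    if np.abs(sums - 1.0).max() > 1e-9:
        raise ValidationError("baseline prevalence does not sum to 1 at every age")
    occ = np.zeros((2, N_SLOT, N_AGE))
    ages = np.arange(N_AGE)
    young = ages < params.quit_age_threshold
    occ[:, NV, :] = derived.baseline_prev[0]
    occ[:, CS, :] = derived.baseline_prev[1]
    occ[:, FLT, :] = np.where(young, derived.baseline_prev[2], 0.0)
    occ[:, FGE, :] = np.where(~young, derived.baseline_prev[2], 0.0)
    return occ


def _survive_and_renormalize(occ: np.ndarray, derived: DerivedSchedules, t: int) -> np.ndarray:
    """Differential survival followed by renormalisation to proportions.

    Status-specific mortality shifts the cohort composition; cohort counts are
    pinned to the external population projection, so occupancies renormalise
    to sum to one.
    """
    m = np.empty((2, N_SLOT, N_AGE))
    for s, risk in enumerate(SLOT_RISK):
        m[:, s, :] = derived.mort[risk][:, :, t]
    out = occ * (1.0 - m)
    tot = out.sum(axis=1, keepdims=True)
    return np.divide(out, tot, out=np.zeros_like(out), where=tot > 0)


def _move(occ: np.ndarray, src: int, dst: int, rate: np.ndarray) -> None:
    """Sequential flow: ``rate`` of the current ``src`` mass moves to ``dst``."""
    flow = rate * occ[:, src, :]
    occ[:, src, :] -= flow
    occ[:, dst, :] += flow


def _move_split(occ: np.ndarray, src: int, dst_young: int, dst_old: int,
                rate: np.ndarray, threshold: int) -> None:
    ages = np.arange(N_AGE)
    young = (ages < threshold)[None, :]
    flow = rate * occ[:, src, :]
    occ[:, src, :] -= flow
    occ[:, dst_young, :] += np.where(young, flow, 0.0)
    occ[:, dst_old, :] += np.where(~young, flow, 0.0)


def _age_shift(occ: np.ndarray) -> np.ndarray:
    """Advance every cohort one year of age; a fresh all-never birth cohort enters."""
    out = np.zeros_like(occ)
    out[:, :, 1:] = occ[:, :, :-1]
    out[:, NV, 0] = 1.0
    return out


def _apply_overlay(occ: np.ndarray, derived: DerivedSchedules, t: int) -> None:
    """Cross-sectional ENDS occupancy in the Restricted scenario.

    ENDS-PN reassigns the never pool (never users plus returning exclusive-
    ENDS-never mass); ENDS-PF reassigns the two former pools, with the
    under-threshold-quitters' ENDS mass kept in the never-risk class.
    Holding these proportions fixed each year encodes the assumption that
    ENDS initiation and cessation offset each other under the ban.
    """
    pn = derived.pn[:, :, t]
    pf = derived.pf[:, :, t]
    pool = occ[:, NV, :] + occ[:, NEN, :]
    occ[:, NEN, :] = pn * pool
    occ[:, NV, :] = (1.0 - pn) * pool
    pool = occ[:, FLT, :] + occ[:, NEF, :]
    occ[:, NEF, :] = pf * pool
    occ[:, FLT, :] = (1.0 - pf) * pool
    pool = occ[:, FGE, :] + occ[:, FSE, :]
    occ[:, FSE, :] = pf * pool
    occ[:, FGE, :] = (1.0 - pf) * pool


def step_restricted(occ: np.ndarray, derived: DerivedSchedules,
                    params: ScenarioParams, t: int) -> np.ndarray:
    """One annual step under the ENDS-ban scenario, year index ``t`` -> ``t+1``."""
    occ = _survive_and_renormalize(occ, derived, t)
    _move(occ, NV, CS, derived.initiation[:, :, t])
    _move_split(occ, CS, FLT, FGE, derived.cessation[:, :, t], params.quit_age_threshold)
    occ = _age_shift(occ)
    if params.years[t + 1] >= params.ends_start_year:
        _apply_overlay(occ, derived, t + 1)
    return occ


def step_unrestricted(occ: np.ndarray, derived: DerivedSchedules,
                      params: ScenarioParams, t: int) -> np.ndarray:
    """One annual step with ENDS access permitted (year >= ban-lift year).

    Smoking initiation runs at its multiplier (default 75%) of the Restricted
    rate, ENDS initiation at its multiplier (50%) of the same schedule,
    smokers switch to exclusive ENDS at the scaled reference rates, and both
    smoking and ENDS cessation run at 100% of the Restricted cessation rates.
    """
    occ = _survive_and_renormalize(occ, derived, t)
    init = derived.initiation[:, :, t]
    cess = derived.cessation[:, :, t]
    _move(occ, NV, CS, params.smoking_initiation_multiplier * init)
    _move(occ, NV, NEN, params.ends_initiation_multiplier * init)
    _move_split(occ, CS, NEF, FSE, params.switching_array(), params.quit_age_threshold)
    _move_split(occ, CS, FLT, FGE, params.smoking_cessation_multiplier * cess,
                params.quit_age_threshold)
    ends_cess = params.ends_cessation_multiplier * cess
    _move(occ, NEN, FUN, ends_cess)
    _move(occ, NEF, FUN, ends_cess)
    _move(occ, FSE, FUF, ends_cess)
    if (occ < -1e-12).any():
        raise ValidationError("negative occupancy after update (a rate exceeded 1 upstream)")
    return _age_shift(occ)


@dataclass
class Trajectory:
    """Full state history of a scenario run.

    ``occ[year, gender, slot, age]`` keeps per-cohort occupancies (each
    gender-age cell sums to 1); counts weight them by the external population
    projection.  Reported prevalences aggregate over the reported age range
    (15-65) with the projected population as denominator.
    """

    which: str
    params: ScenarioParams
    occ: np.ndarray            # [n_year, 2, N_SLOT, N_AGE]
    pop: np.ndarray            # [2, N_AGE, n_year]
    years: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.years is None:
            self.years = self.params.years[: self.occ.shape[0]]

    def counts(self) -> np.ndarray:
        """Persons per ``[year, gender, slot, age]``."""
        return self.occ * np.transpose(self.pop, (2, 0, 1))[:, :, None, :]

    def state_occupancy(self, state: str) -> np.ndarray:
        """Reported-state occupancy ``[year, gender, age]``."""
        return self.occ[:, :, list(STATE_SLOTS[state]), :].sum(axis=2)

    def prevalence(self, state: str, age_range: tuple[int, int] | None = None) -> np.ndarray:
        """Population-weighted prevalence ``[year, gender]`` over an age range."""
        lo, hi = age_range or self.params.reported_age_range
        w = np.transpose(self.pop[:, lo : hi + 1, :], (2, 0, 1))  # [year, gender, age]
        num = (self.state_occupancy(state)[:, :, lo : hi + 1] * w).sum(axis=2)
        den = w.sum(axis=2)
        return num / den

    def to_frame(self) -> pd.DataFrame:
        """Tidy prevalence/count table: one row per gender, year and state."""
        rows = []
        lo, hi = self.params.reported_age_range
        cnt = self.counts()
        for state in STATES:
            prev = self.prevalence(state)
            slots = list(STATE_SLOTS[state])
            c = cnt[:, :, slots, :][:, :, :, lo : hi + 1].sum(axis=(2, 3))
            for g, gender in enumerate(GENDERS):
                for t, year in enumerate(self.years):
                    rows.append((gender, int(year), state, prev[t, g], c[t, g]))
        return pd.DataFrame(rows, columns=["gender", "year", "state", "prevalence", "count"])

    def cohort_history(self, birth_year: int, gender: str) -> pd.DataFrame:
        """One cohort's full state history (debugging aid)."""
        g = GENDERS.index(gender)
        rows = []
        for t, year in enumerate(self.years):
            age = int(year) - birth_year
            if 0 <= age < N_AGE:
                rows.append((int(year), age, *self.occ[t, g, :, age]))
        return pd.DataFrame(rows, columns=["year", "age", *SLOT_NAMES])


def run_scenario(derived: DerivedSchedules, params: ScenarioParams, which: str,
                 stop_year: int | None = None) -> Trajectory:
    """Simulate one scenario over all cohorts.

    ``which`` is ``"restricted"`` or ``"unrestricted"``; the Unrestricted
    scenario delegates to Restricted stepping for years before the ban-lift
    year, so the two runs coincide until then.  ``stop_year`` truncates the
    run (used by calibration).
    """
    if which not in ("restricted", "unrestricted"):
        raise ValidationError(f"unknown scenario '{which}'")
    stop_year = params.end_year if stop_year is None else min(stop_year, params.end_year)
    n_steps = stop_year - params.start_year
    occ = np.zeros((n_steps + 1, 2, N_SLOT, N_AGE))
    occ[0] = initialize_cohorts(derived, params)
    if params.years[0] >= params.ends_start_year:
        _apply_overlay(occ[0], derived, 0)
    for t in range(n_steps):
        year = int(params.years[t])
        if which == "unrestricted" and year >= params.ban_lift_year:
            occ[t + 1] = step_unrestricted(occ[t], derived, params, t)
        else:
            occ[t + 1] = step_restricted(occ[t], derived, params, t)
    return Trajectory(which=which, params=params, occ=occ,
                      pop=derived.pop[:, :, : n_steps + 1],
                      years=params.years[: n_steps + 1])
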