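"""Mortality attribution, life-years lost, scenario comparison and sensitivity sweeps.

Smoking- and vaping-attributable deaths (SVADs) multiply state counts by the
state's excess mortality over never smokers; life-years lost (LYLs) weight
each attributable death by the remaining never-smoker life expectancy at that
age.  The public-health impact of lifting the ban is the Restricted-minus-
Unrestricted difference in these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    CS, FGE, FLT, FSE, FUF, FUN, NEF, NEN, NV, N_SLOT, Trajectory, run_scenario,
)
from .io_model import GENDERS, N_AGE, ScenarioParams, ValidationError
from .preprocess import DerivedSchedules


def relative_change(base: float, comparison: float) -> float:
    """(comparison - base) / base; the convention used for every relative
    reduction and validation comparison in the package."""
    return (comparison - base) / base


def percent_averted(averted: float, restricted_total: float) -> float:
    """Averted share of the Restricted-scenario total (the reporting denominator)."""
    return averted / restricted_total


def slot_excess_mortality(derived: DerivedSchedules, ends_risk_multiplier: float) -> np.ndarray:
    """Excess mortality over never smokers per internal slot, ``[gender, slot, age, year]``.

    Current smokers carry ``m_current - m_never`` and former (35+) quitters
    ``m_former - m_never``; quitting before 35 erases the excess.  Exclusive
    ENDS users in the never-risk class carry the ENDS multiplier times the
    smoker excess; those in the former-risk class carry the former-smoker risk
    plus the multiplier times the current-former gap.  Former ENDS users keep
    the excess of their risk class of origin.
    """
    mn = derived.mort["never"]
    mc = derived.mort["current"]
    mf = derived.mort["former"]
    rho = ends_risk_multiplier
    ex = np.zeros((2, N_SLOT, N_AGE, mn.shape[2]))
    ex[:, CS] = mc - mn
    ex[:, FGE] = mf - mn
    ex[:, NEN] = rho * (mc - mn)
    ex[:, NEF] = rho * (mc - mn)
    ex[:, FSE] = (mf + rho * (mc - mf)) - mn
    ex[:, FUF] = mf - mn
    # NV, FLT, FUN: zero excess
    return ex


_STATE_TO_SLOT = {
    "never_nonuser": NV, "current_smoker": CS, "former_lt35": FLT, "former_ge35": FGE,
    "n_ends": NEN, "fs_ends": FSE,
}


def excess_mortality_rate(state: str, age: int, gender: str, year: int,
                          derived: DerivedSchedules, ends_risk_multiplier: float,
                          provenance: str = "former") -> float:
    """Scalar excess mortality for one reported state and cell.

    ``former_ends_user`` needs a ``provenance`` ("never" or "former") because
    its risk class depends on how the person reached ENDS use.
    """
    g = GENDERS.index(gender)
    t = int(year) - int(derived.years[0])
    ex = slot_excess_mortality(derived, ends_risk_multiplier)
    if state == "former_ends_user":
        slot = FUN if provenance == "never" else FUF
    elif state in _STATE_TO_SLOT:
        slot = _STATE_TO_SLOT[state]
    else:
        raise ValidationError(f"unknown state '{state}'")
    return float(ex[g, slot, age, t])


def _attributable_deaths_by_age(traj: Trajectory, derived: DerivedSchedules,
                                params: ScenarioParams) -> np.ndarray:
    """Age-resolved SVADs ``[year, gender, age]``; only reported ages contribute."""
    n_year = traj.occ.shape[0]
    ex = slot_excess_mortality(derived, params.ends_risk_multiplier)
    ex = np.transpose(ex, (3, 0, 1, 2))[:n_year]          # [year, gender, slot, age]
    deaths = (traj.counts() * ex).sum(axis=2)             # [year, gender, age]
    lo, hi = params.reported_age_range
    mask = np.zeros(N_AGE)
    mask[lo : hi + 1] = 1.0
    return deaths * mask


def compute_svads(traj: Trajectory, derived: DerivedSchedules,
                  params: ScenarioParams) -> np.ndarray:
    """SVADs ``[year, gender]``: state counts times excess mortality, ages 15-65."""
    if traj.occ.shape[0] > derived.pop.shape[2]:
        raise ValidationError("trajectory and schedules cover different year ranges")
    return _attributable_deaths_by_age(traj, derived, params).sum(axis=2)


def compute_lyls(traj: Trajectory, derived: DerivedSchedules,
                 params: ScenarioParams) -> np.ndarray:
    """LYLs ``[year, gender]``: age-resolved SVADs times never-smoker life expectancy."""
    deaths = _attributable_deaths_by_age(traj, derived, params)
    n_year = deaths.shape[0]
    le = np.transpose(derived.never_le, (2, 0, 1))[:n_year]  # [year, gender, age]
    if not np.all(np.isfinite(le)):
        raise ValidationError("never-smoker life expectancy has missing cells")
    return (deaths * le).sum(axis=2)


@dataclass
class ImpactSummary:
    """Scenario-difference results: yearly series, cumulative totals, ratios.

    Averted quantities are Restricted minus Unrestricted, cell-wise.  Percent-
    averted ratios divide cumulative averted totals (over the averted window)
    by the Restricted scenario's cumulative totals (over the cumulative
    window).  Relative prevalence reduction is
    ``(P_unrestricted - P_restricted) / P_restricted`` per gender and year.
    """

    years: np.ndarray
    svads_restricted: np.ndarray       # [year, gender]
    svads_unrestricted: np.ndarray
    lyls_restricted: np.ndarray
    lyls_unrestricted: np.ndarray
    relative_prevalence_reduction: np.ndarray  # [year, gender]
    averted_window: tuple[int, int] = (2025, 2049)
    cumulative_window: tuple[int, int] = (2009, 2049)

    averted_svads: np.ndarray = field(init=False)
    averted_lyls: np.ndarray = field(init=False)

    def __post_init__(self):
        self.averted_svads = self.svads_restricted - self.svads_unrestricted
        self.averted_lyls = self.lyls_restricted - self.lyls_unrestricted

    def _win(self, window: tuple[int, int]) -> np.ndarray:
        return (self.years >= window[0]) & (self.years <= window[1])

    def cumulative(self, series: np.ndarray, window: tuple[int, int]) -> np.ndarray:
        """Per-gender sum of a yearly ``[year, gender]`` series over a window."""
        return series[self._win(window)].sum(axis=0)

    @property
    def cumulative_svads(self) -> np.ndarray:
        return self.cumulative(self.svads_restricted, self.cumulative_window)

    @property
    def cumulative_lyls(self) -> np.ndarray:
        return self.cumulative(self.lyls_restricted, self.cumulative_window)

    @property
    def cumulative_averted_svads(self) -> np.ndarray:
        return self.cumulative(self.averted_svads, self.averted_window)

    @property
    def cumulative_averted_lyls(self) -> np.ndarray:
        return self.cumulative(self.averted_lyls, self.averted_window)

    @property
    def percent_averted_svads(self) -> float:
        return percent_averted(self.cumulative_averted_svads.sum(),
                               self.cumulative_svads.sum())

    @property
    def percent_averted_lyls(self) -> float:
        return percent_averted(self.cumulative_averted_lyls.sum(),
                               self.cumulative_lyls.sum())

    def yearly_frame(self) -> pd.DataFrame:
        rows = []
        for g, gender in enumerate(GENDERS):
            for t, year in enumerate(self.years):
                rows.append((
                    gender, int(year),
                    self.svads_restricted[t, g], self.svads_unrestricted[t, g],
                    self.averted_svads[t, g],
                    self.lyls_restricted[t, g], self.lyls_unrestricted[t, g],
                    self.averted_lyls[t, g],
                    self.relative_prevalence_reduction[t, g],
                ))
        return pd.DataFrame(rows, columns=[
            "gender", "year", "svads_restricted", "svads_unrestricted", "averted_svads",
            "lyls_restricted", "lyls_unrestricted", "averted_lyls",
            "relative_smoking_prevalence_reduction",
        ])

    def totals_frame(self) -> pd.DataFrame:
        rows = []
        for g, gender in enumerate(GENDERS):
            rows.append((gender, self.cumulative_svads[g], self.cumulative_lyls[g],
                         self.cumulative_averted_svads[g], self.cumulative_averted_lyls[g]))
        rows.append(("both", self.cumulative_svads.sum(), self.cumulative_lyls.sum(),
                     self.cumulative_averted_svads.sum(), self.cumulative_averted_lyls.sum()))
        df = pd.DataFrame(rows, columns=[
            "gender", "cumulative_svads_restricted", "cumulative_lyls_restricted",
            "cumulative_averted_svads", "cumulative_averted_lyls"])
        df["percent_averted_svads"] = np.where(
            df.gender == "both", self.percent_averted_svads, np.nan)
        df["percent_averted_lyls"] = np.where(
            df.gender == "both", self.percent_averted_lyls, np.nan)
        return df


def compare_scenarios(traj_restricted: Trajectory, traj_unrestricted: Trajectory,
                      derived: DerivedSchedules, params: ScenarioParams,
                      averted_window: tuple[int, int] | None = None,
                      cumulative_window: tuple[int, int] | None = None) -> ImpactSummary:
    """Assemble the impact summary from a matched pair of scenario runs."""
    if traj_restricted.occ.shape[0] != traj_unrestricted.occ.shape[0]:
        raise ValidationError("scenario runs cover different year ranges")
    years = traj_restricted.years
    p_res = traj_restricted.prevalence("current_smoker")
    p_unres = traj_unrestricted.prevalence("current_smoker")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(p_res > 0, (p_unres - p_res) / p_res, 0.0)
    return ImpactSummary(
        years=np.asarray(years),
        svads_restricted=compute_svads(traj_restricted, derived, params),
        svads_unrestricted=compute_svads(traj_unrestricted, derived, params),
        lyls_restricted=compute_lyls(traj_restricted, derived, params),
        lyls_unrestricted=compute_lyls(traj_unrestricted, derived, params),
        relative_prevalence_reduction=rel,
        averted_window=averted_window or (params.ban_lift_year + 1, params.end_year),
        cumulative_window=cumulative_window or (params.start_year, params.end_year),
    )


def run_impact(derived: DerivedSchedules, params: ScenarioParams) -> tuple[Trajectory, Trajectory, ImpactSummary]:
    """Run both scenarios on shared schedules and compare them."""
    traj_r = run_scenario(derived, params, "restricted")
    traj_u = run_scenario(derived, params, "unrestricted")
    return traj_r, traj_u, compare_scenarios(traj_r, traj_u, derived, params)


def run_sensitivity(derived: DerivedSchedules, base_params: ScenarioParams,
                    grid: list[dict]) -> pd.DataFrame:
    """One full two-scenario run per grid point of parameter overrides.

    Each grid cell is a dict of :class:`ScenarioParams` overrides (typically
    ``switching_scale`` and/or ``ends_risk_multiplier``).  The output is tidy:
    one row per run with cumulative averted SVADs/LYLs (both genders, averted
    window) and the percent change relative to the base run.
    """
    rows = []
    _, _, base = run_impact(derived, base_params)
    base_svads = base.cumulative_averted_svads.sum()
    base_lyls = base.cumulative_averted_lyls.sum()
    rows.append({"run": "base", "averted_svads": base_svads, "averted_lyls": base_lyls,
                 "pct_change_svads": 0.0, "pct_change_lyls": 0.0,
                 **{k: getattr(base_params, k) for k in
                    ("switching_scale", "ends_risk_multiplier")}})
    for i, overrides in enumerate(grid):
        params = base_params.replace(**overrides)
        _, _, summ = run_impact(derived, params)
        sv = summ.cumulative_averted_svads.sum()
        ly = summ.cumulative_averted_lyls.sum()
        rows.append({"run": f"grid_{i}", "averted_svads": sv, "averted_lyls": ly,
                     "pct_change_svads": relative_change(base_svads, sv),
                     "pct_change_lyls": relative_change(base_lyls, ly),
                     **{k: getattr(params, k) for k in
                        ("switching_scale", "ends_risk_multiplier")}})
    return pd.DataFrame(rows)
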