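"""Individual-level Monte-Carlo reading of the cohort engine.

Each agent walks the identical ordered rule set as the deterministic engine,
with Bernoulli draws at the engine's rates: status-specific death, smoking
initiation, (Unrestricted) ENDS initiation and switching, smoking and ENDS
cessation, and the (Restricted) cross-sectional ENDS overlay realised as
per-year reassignment within its source pool.  Renormalisation to the
population projection is handled by weighting the estimates, not by
resurrecting agents, so the agent model stays a true probabilistic reading
of the engine's update; state prevalences conditioned on survival are then
unbiased for the engine's renormalised occupancies.

Only cohorts that ever enter the reported 15-65 age window during the run
receive agents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    CS, FGE, FLT, FSE, FUF, FUN, NEF, NEN, NV, N_SLOT, SLOT_RISK, STATE_SLOTS,
)
from .io_model import GENDERS, N_AGE, STATES, ScenarioParams, ValidationError
from .preprocess import DerivedSchedules

_RISK_INDEX = {"never": 0, "current": 1, "former": 2}
_SLOT_RISK_IX = np.array([_RISK_INDEX[r] for r in SLOT_RISK])


@dataclass
class MicrosimResult:
    """Population-weighted prevalence estimates and their Monte-Carlo SEs.

    Arrays are ``[state, gender, year]`` over the reported states and age
    range; SEs propagate the binomial variance of each age cell through the
    population weights.
    """

    which: str
    years: np.ndarray
    prevalence: np.ndarray
    se: np.ndarray
    n_agents: int
    #: alive agents per [gender, age, year] inside the reported window
    n_alive: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, state in enumerate(STATES):
            for g, gender in enumerate(GENDERS):
                for t, year in enumerate(self.years):
                    rows.append((state, gender, int(year),
                                 self.prevalence[s, g, t], self.se[s, g, t]))
        return pd.DataFrame(rows, columns=["state", "gender", "year", "prevalence", "se"])


def _allocate(weights: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder proportional allocation of ``n`` agents."""
    share = weights / weights.sum() * n
    base = np.floor(share).astype(int)
    rem = n - base.sum()
    if rem > 0:
        order = np.argsort(-(share - base))
        base[order[:rem]] += 1
    return base


def _init_states(rng: np.random.Generator, prev: np.ndarray, ages: np.ndarray,
                 threshold: int) -> np.ndarray:
    """Draw baseline states (never/current/former with the quit-age split)."""
    u = rng.random(len(ages))
    p_never = prev[0, ages]
    p_current = prev[1, ages]
    state = np.full(len(ages), NV, dtype=np.int8)
    state[u >= p_never] = CS
    former = u >= p_never + p_current
    state[former & (ages < threshold)] = FLT
    state[former & (ages >= threshold)] = FGE
    return state


def simulate_agents(derived: DerivedSchedules, params: ScenarioParams,
                    n_agents: int, seed: int, which: str) -> MicrosimResult:
    """Monte-Carlo prevalence estimates for one scenario.

    Agents are allocated to cohorts proportionally to the cohort's projected
    entry population; the simulation is reproducible for a fixed seed.
    """
    if n_agents < 1:
        raise ValidationError("n_agents must be >= 1")
    if which not in ("restricted", "unrestricted"):
        raise ValidationError(f"unknown scenario '{which}'")
    rng = np.random.default_rng(seed)
    years = params.years
    n_year = params.n_years
    lo, hi = params.reported_age_range
    thr = params.quit_age_threshold

    prev_out = np.zeros((len(STATES), 2, n_year))
    se_out = np.zeros_like(prev_out)
    n_alive = np.zeros((2, N_AGE, n_year))

    slot_state = np.zeros((N_SLOT, len(STATES)))
    for s, state in enumerate(STATES):
        for slot in STATE_SLOTS[state]:
            slot_state[slot, s] = 1.0

    n_per_gender = [n_agents // 2 + (n_agents % 2), n_agents // 2]
    for g, gender in enumerate(GENDERS):
        # cohorts that ever occupy the reported ages during the run
        births = np.arange(params.start_year - hi, params.end_year - lo + 1)
        entry_pop = np.array([
            derived.pop[g, params.start_year - b, 0] if b <= params.start_year
            else derived.pop[g, 0, b - params.start_year]
            for b in births
        ])
        counts = _allocate(entry_pop, n_per_gender[g])
        birth_year = np.repeat(births, counts)
        n = len(birth_year)

        state = np.full(n, NV, dtype=np.int8)
        alive = np.ones(n, dtype=bool)
        entered = birth_year <= params.start_year
        age0 = params.start_year - birth_year
        state[entered] = _init_states(rng, derived.baseline_prev[:, g, :],
                                      age0[entered].astype(int), thr)

        mort = np.stack([derived.mort[s][g] for s in ("never", "current", "former")])

        for t in range(n_year):
            year = int(years[t])
            ages = year - birth_year
            active = alive & (ages >= 0) & (ages <= N_AGE - 1) & (birth_year <= year)
            # --- record estimates over the reported window
            rep = active & (ages >= lo) & (ages <= hi)
            if rep.any():
                cell = np.zeros((N_AGE, N_SLOT))
                np.add.at(cell, (ages[rep], state[rep]), 1.0)
                n_a = cell.sum(axis=1)
                n_alive[g, :, t] = n_a
                w = derived.pop[g, :, t].copy()
                w[: lo] = 0.0
                w[hi + 1 :] = 0.0
                w[n_a == 0] = 0.0
                w = w / w.sum()
                with np.errstate(invalid="ignore", divide="ignore"):
                    p_a = np.divide(cell, n_a[:, None], where=n_a[:, None] > 0,
                                    out=np.zeros_like(cell))
                p_state = p_a @ slot_state                       # [age, state]
                prev_out[:, g, t] = (w[:, None] * p_state).sum(axis=0)
                var = p_state * (1.0 - p_state)
                with np.errstate(invalid="ignore", divide="ignore"):
                    var = np.divide(var, n_a[:, None], where=n_a[:, None] > 0,
                                    out=np.zeros_like(var))
                se_out[:, g, t] = np.sqrt((w[:, None] ** 2 * var).sum(axis=0))
            if t == n_year - 1:
                break
            # --- transition to year t+1 (mirrors the engine's ordered update)
            unres = which == "unrestricted" and year >= params.ban_lift_year
            act = np.flatnonzero(active)
            a_act = ages[act]
            s_act = state[act]
            # death by risk class of the current slot
            m = mort[_SLOT_RISK_IX[s_act], a_act, t]
            die = rng.random(len(act)) < m
            alive[act[die]] = False
            live = act[~die]
            a_l = ages[live]
            if unres:
                init = params.smoking_initiation_multiplier * derived.initiation[g, a_l, t]
                ends_init = params.ends_initiation_multiplier * derived.initiation[g, a_l, t]
                cess = params.smoking_cessation_multiplier * derived.cessation[g, a_l, t]
                ends_cess = params.ends_cessation_multiplier * derived.cessation[g, a_l, t]
                switch = params.switching_array()[g, a_l]
                # fresh draw per stage: sequential flows are conditionally
                # independent given the state reached so far
                u_init = rng.random(len(live))
                u_ends_init = rng.random(len(live))
                u_switch = rng.random(len(live))
                u_cess = rng.random(len(live))
                u_ends_cess = rng.random(len(live))
                is_nv = state[live] == NV
                start_smoking = is_nv & (u_init < init)
                start_ends = is_nv & ~start_smoking & (u_ends_init < ends_init)
                state[live[start_smoking]] = CS
                state[live[start_ends]] = NEN
                is_cs = state[live] == CS
                do_switch = is_cs & (u_switch < switch)
                young = a_l < thr
                state[live[do_switch & young]] = NEF
                state[live[do_switch & ~young]] = FSE
                is_cs = state[live] == CS
                do_cess = is_cs & (u_cess < cess)
                state[live[do_cess & young]] = FLT
                state[live[do_cess & ~young]] = FGE
                quit_ends = u_ends_cess < ends_cess
                on_ends = state[live]
                state[live[(on_ends == NEN) & quit_ends]] = FUN
                state[live[(on_ends == NEF) & quit_ends]] = FUN
                state[live[(on_ends == FSE) & quit_ends]] = FUF
            else:
                init = derived.initiation[g, a_l, t]
                cess = derived.cessation[g, a_l, t]
                u1 = rng.random(len(live))
                is_nv = state[live] == NV
                state[live[is_nv & (u1 < init)]] = CS
                is_cs = state[live] == CS
                u2 = rng.random(len(live))
                do_cess = is_cs & (u2 < cess)
                young = a_l < thr
                state[live[do_cess & young]] = FLT
                state[live[do_cess & ~young]] = FGE
                # ENDS overlay at the arrival year, within each source pool
                if int(years[t + 1]) >= params.ends_start_year:
                    a_next = a_l + 1
                    ok = a_next <= N_AGE - 1
                    ln, an = live[ok], a_next[ok]
                    pn = derived.pn[g, an, t + 1]
                    pf = derived.pf[g, an, t + 1]
                    u = rng.random(len(ln))
                    s_now = state[ln]
                    pool = (s_now == NV) | (s_now == NEN)
                    state[ln[pool & (u < pn)]] = NEN
                    state[ln[pool & (u >= pn)]] = NV
                    pool = (s_now == FLT) | (s_now == NEF)
                    state[ln[pool & (u < pf)]] = NEF
                    state[ln[pool & (u >= pf)]] = FLT
                    pool = (s_now == FGE) | (s_now == FSE)
                    state[ln[pool & (u < pf)]] = FSE
                    state[ln[pool & (u >= pf)]] = FGE
    return MicrosimResult(which=which, years=np.asarray(years),
                          prevalence=prev_out, se=se_out, n_agents=n_agents,
                          n_alive=n_alive)


def compare_with_engine(result: MicrosimResult, traj, params: ScenarioParams | None = None
                        ) -> pd.DataFrame:
    """Cell-wise engine-vs-microsim comparison with studentised gaps.

    The SE used for studentisation is computed under the null that the engine
    prevalence is the true Bernoulli probability in each age cell (the plug-in
    SE collapses to zero when a rare state draws no agents).  Returns one row
    per state, gender and year with ``z = (engine - estimate) / SE``; cells
    where both sides are exactly zero report z = 0.
    """
    params = params or traj.params
    lo, hi = params.reported_age_range
    rows = []
    for s, state in enumerate(STATES):
        eng = traj.prevalence(state)
        occ = traj.state_occupancy(state)                 # [year, gender, age]
        for g, gender in enumerate(GENDERS):
            for t, year in enumerate(result.years):
                e = eng[t, g]
                m = result.prevalence[s, g, t]
                n_a = result.n_alive[g, :, t]
                w = traj.pop[g, :, t].copy()
                w[:lo] = 0.0
                w[hi + 1 :] = 0.0
                w[n_a == 0] = 0.0
                w = w / w.sum()
                p = occ[t, g]
                var = np.divide(p * (1.0 - p), n_a, where=n_a > 0,
                                out=np.zeros(len(n_a)))
                se = float(np.sqrt((w ** 2 * var).sum()))
                z = (e - m) / se if se > 0 else (0.0 if abs(e - m) < 1e-12 else np.inf)
                rows.append((state, gender, int(year), e, m, se, z))
    return pd.DataFrame(rows, columns=["state", "gender", "year",
                                       "engine", "microsim", "se", "z"])
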