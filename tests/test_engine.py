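"""Engine unit tests: initialization, single-step arithmetic, run contracts."""

import dataclasses

import numpy as np
import pytest

import savm
from savm.engine import (
    CS, FGE, FLT, NEF, NEN, NV, initialize_cohorts, run_scenario, step_restricted,
    step_unrestricted,
)
from savm.io_model import N_AGE, ScenarioParams


def _toy_derived(derived, *, mort=0.0, init=0.0, init_age=None, cess=0.0,
                 pn=0.0, pf=0.0, baseline=None):
    """Fixture-shaped schedules with controlled constant rates (for hand calcs)."""
    n = derived.pop.shape[2]
    zeros = np.zeros((2, N_AGE, n))
    init_arr = np.full_like(zeros, init) if init_age is None else zeros.copy()
    if init_age is not None:
        init_arr[:, init_age, :] = init
    d = dataclasses.replace(
        derived,
        mort={s: np.full_like(zeros, mort) for s in ("never", "current", "former")},
        initiation=init_arr,
        cessation=np.full_like(zeros, cess),
        pn=np.full_like(zeros, pn),
        pf=np.full_like(zeros, pf),
    )
    if baseline is not None:
        d = dataclasses.replace(d, baseline_prev=baseline)
    return d


def _uniform_baseline(never, current, former):
    b = np.zeros((3, 2, N_AGE))
    b[0], b[1], b[2] = never, current, former
    return b


class TestInitialization:
    def test_former_split_by_quit_age_threshold(self, derived, params):
        b = derived.baseline_prev.copy()
        b[:, :, 30] = np.array([0.70, 0.22, 0.08])[:, None]
        b[:, :, 50] = np.array([0.80, 0.15, 0.05])[:, None]
        occ = initialize_cohorts(dataclasses.replace(derived, baseline_prev=b), params)
        assert occ[0, FLT, 30] == pytest.approx(0.08)   # below 35: never-risk quitters
        assert occ[0, FGE, 30] == 0.0
        assert occ[0, FGE, 50] == pytest.approx(0.05)   # 35+: former-risk quitters
        assert occ[0, FLT, 50] == 0.0
        assert occ[0, NV, 30] == pytest.approx(0.70)
        assert occ[0, CS, 50] == pytest.approx(0.15)

    def test_new_birth_cohorts_start_all_never(self, restricted_traj):
        # the age-0 cohort of every post-baseline year is 100% never users
        assert np.allclose(restricted_traj.occ[1:, :, NV, 0], 1.0)

    def test_invalid_baseline_is_rejected(self, derived, params):
        b = derived.baseline_prev.copy()
        b[0, 0, 10] += 0.05
        with pytest.raises(savm.ValidationError, match="sum"):
            initialize_cohorts(dataclasses.replace(derived, baseline_prev=b), params)


class TestSingleSteps:
    def test_initiation_moves_exactly_its_rate(self, derived, params):
        """With zero mortality/cessation, current gains initiation x never."""
        d = _toy_derived(derived, init=0.1, init_age=20,
                         baseline=_uniform_baseline(1.0, 0.0, 0.0))
        occ = initialize_cohorts(d, params)
        nxt = step_restricted(occ, d, params, 0)
        assert nxt[0, CS, 21] == pytest.approx(0.1)     # the cohort aged 20 -> 21
        assert nxt[0, NV, 21] == pytest.approx(0.9)
        assert nxt[0, CS, 30] == 0.0

    def test_switching_moves_smokers_to_ends(self, derived):
        """Current=1 with only switching 2%/yr at age 30 leaves 98% smoking."""
        params = ScenarioParams(ban_lift_year=2009,
                                smoking_initiation_multiplier=0.0,
                                ends_initiation_multiplier=0.0)
        sw = {g: {(0, 34): 0.04, (35, 85): 0.0} for g in ("male", "female")}
        params = params.replace(switching_rate=sw, switching_scale=0.5)
        d = _toy_derived(derived, baseline=_uniform_baseline(0.0, 1.0, 0.0))
        occ = initialize_cohorts(d, params)
        nxt = step_unrestricted(occ, d, params, 0)
        assert nxt[0, NEN, 31] + nxt[0, NEF, 31] == pytest.approx(0.02)
        assert nxt[0, CS, 31] == pytest.approx(0.98)

    def test_ends_overlay_is_cross_sectional(self, derived, params):
        """N-ENDS occupancy equals ENDS-PN times the never pool each year."""
        d = _toy_derived(derived, pn=0.01, baseline=_uniform_baseline(1.0, 0.0, 0.0))
        occ = initialize_cohorts(d, params)
        t = params.year_index(params.ends_start_year) - 1
        nxt = step_restricted(occ, d, params, t)
        assert nxt[0, NEN, 30] == pytest.approx(0.01)
        assert nxt[0, NV, 30] == pytest.approx(0.99)
        # applying the overlay again the next year does not compound it
        nxt2 = step_restricted(nxt, d, params, t + 1)
        assert nxt2[0, NEN, 31] == pytest.approx(0.01)

    def test_five_step_two_compartment_recursion(self, derived, params):
        """Constant rates reproduce the closed-form never/current recursion.

        With initiation i and cessation c and no mortality,
        never_t = (1-i)^t and current_t = i * sum_k (1-i)^k (1-c)^(t-k).
        """
        i, c = 0.08, 0.05
        d = _toy_derived(derived, init=i, cess=c,
                         baseline=_uniform_baseline(1.0, 0.0, 0.0))
        occ = initialize_cohorts(d, params)
        for step in range(5):
            occ = step_restricted(occ, d, params, step)
        t, age0 = 5, 40  # follow the cohort aged 40 in the baseline year
        never = (1 - i) ** t
        current = i * sum((1 - i) ** k * (1 - c) ** (t - k) for k in range(t))
        assert occ[0, NV, age0 + t] == pytest.approx(never, rel=1e-12)
        assert occ[0, CS, age0 + t] == pytest.approx(current, rel=1e-12)


class TestRunContracts:
    def test_unrestricted_delegates_before_ban_lift(self, restricted_traj,
                                                    unrestricted_traj, params):
        """The scenarios are bit-for-bit identical through the ban-lift year."""
        t_lift = params.year_index(params.ban_lift_year)
        np.testing.assert_array_equal(restricted_traj.occ[: t_lift + 1],
                                      unrestricted_traj.occ[: t_lift + 1])
        assert not np.array_equal(restricted_traj.occ[t_lift + 1],
                                  unrestricted_traj.occ[t_lift + 1])

    def test_occupancies_conserved(self, restricted_traj, unrestricted_traj):
        for traj in (restricted_traj, unrestricted_traj):
            sums = traj.occ.sum(axis=2)
            np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_counts_match_population_projection(self, restricted_traj, derived, params):
        lo, hi = params.reported_age_range
        counts = restricted_traj.counts().sum(axis=2)          # [year, gender, age]
        total = counts[:, :, lo : hi + 1].sum(axis=2)
        pop = derived.pop[:, lo : hi + 1, :].sum(axis=1).T     # [year, gender]
        np.testing.assert_allclose(total, pop, rtol=1e-12)

    def test_ends_free_reduction(self, derived, params):
        """With every ENDS channel zeroed both scenarios collapse to the same
        three-state smoking model."""
        d = _toy_derived(derived, mort=0.001, init=0.02, cess=0.03, pn=0.0, pf=0.0)
        null = params.replace(smoking_initiation_multiplier=1.0,
                              ends_initiation_multiplier=0.0, switching_scale=0.0)
        tr = run_scenario(d, null, "restricted")
        tu = run_scenario(d, null, "unrestricted")
        np.testing.assert_array_equal(tr.occ, tu.occ)
        for state in ("n_ends", "fs_ends", "former_ends_user"):
            assert tr.prevalence(state).max() == 0.0

    def test_smoking_monotone_in_initiation_multiplier(self, derived, params):
        """Cumulative Unrestricted smoking prevalence rises with the smoking
        initiation multiplier."""
        totals = []
        for m in (0.5, 0.75, 1.0):
            traj = run_scenario(derived, params.replace(
                smoking_initiation_multiplier=m), "unrestricted")
            totals.append(traj.prevalence("current_smoker").sum())
        assert totals[0] < totals[1] < totals[2]

    def test_smoking_monotone_in_switching_scale(self, derived, params):
        totals = []
        for s in (0.25, 0.50, 0.75):
            traj = run_scenario(derived, params.replace(switching_scale=s),
                                "unrestricted")
            totals.append(traj.prevalence("current_smoker").sum())
        assert totals[0] > totals[1] > totals[2]

    def test_stop_year_truncates(self, derived, params):
        traj = run_scenario(derived, params, "restricted", stop_year=2015)
        assert traj.occ.shape[0] == 7
        assert traj.years[-1] == 2015

    def test_unknown_scenario_rejected(self, derived, params):
        with pytest.raises(savm.ValidationError):
            run_scenario(derived, params, "banned")


def test_fixture_restricted_regression(restricted_traj, params):
    """Golden-file regression: the packaged fixture's male smoking prevalence
    is stable-to-declining (frozen at the first verified build)."""
    smk = restricted_traj.prevalence("current_smoker")
    got = [smk[params.year_index(y), 0] for y in (2009, 2015, 2035, 2049)]
    np.testing.assert_allclose(got, [0.2501, 0.245857, 0.213648, 0.198474], atol=5e-6)
    assert got[0] > got[-1]
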