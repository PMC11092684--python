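# savm — a smoking and vaping policy simulator

`savm` is a cohort-based, discrete-time simulator of cigarette-smoking and
e-cigarette (ENDS, electronic nicotine delivery systems) use for a national
population, built to ask a policy question: *what happens to smoking
prevalence and smoking-attributable mortality if a country that currently
bans ENDS lifts the ban?*  The package is configured for a Mexico-like
population over 2009–2049 but every schedule is an input, so any country's
data can be substituted.

It compares two scenarios:

* **Restricted** — the status quo: ENDS are banned but some use persists;
  exclusive-ENDS occupancy is pinned to survey-observed proportions among
  never smokers (ENDS-PN) and former smokers (ENDS-PF).
* **Unrestricted** — the ban is lifted in 2024: smoking initiation falls to
  75% of its Restricted schedule, ENDS initiation runs at 50% of the same
  schedule, and current smokers switch to exclusive ENDS at age- and
  gender-specific rates (0.3–2.0%/yr, 50% of US reference rates).

The public-health impact of legalisation is the scenario difference in
smoking- and vaping-attributable deaths (SVADs) and life-years lost (LYLs).

## Model

Cohorts (by birth year and gender) move annually through seven states:
never user, current smoker, former smoker who quit before/after age 35,
exclusive ENDS user with never-smoker-like risk (N-ENDS) or former-smoker
risk (FS-ENDS), and former ENDS user.  Each year a cohort undergoes
status-specific survival, renormalisation to the external population
projection, then initiation, switching and cessation flows (sequentially;
each rate applies to the remaining mass).

Mortality by smoking status is derived by the ratio method,

    m_s^country(a, g, t) = R(a, g, t) · m_s^ref(a, g, t),
    R = m^country_overall / m^ref_overall,

and attributable deaths are

    SVAD(g, t) = Σ_a Σ_s N_s(a, g, t) · [m_s(a, g, t) − m_never(a, g, t)],
    LYL(g, t)  = Σ_a SVAD(a, g, t) · LE_never(a, g, t),

with ENDS states carrying a fraction ρ (default 0.15) of smoking's excess
risk: N-ENDS excess is ρ·(m_c − m_n) and FS-ENDS excess is
m_f + ρ·(m_c − m_f) − m_n.  Never-smoker life expectancy is the country's
overall life expectancy times a reference never/overall ratio.  Initiation
(ages 6–39) and cessation (ages 11–65) schedules are calibrated with fixed
band adjusters (e.g. male initiation ×1.52 at 15–24, ×1.78 at 25–40).

All inputs — population projections, mortality, life-expectancy anchors,
baseline prevalence, rate schedules, ENDS proportions — can be read from
tidy CSVs or generated by the built-in synthetic module, so the package runs
with no downloads.

## Worked example

```python
import savm

params  = savm.ScenarioParams()                    # 2009-2049, ban lifted 2024
bundle  = savm.default_fixture(params)             # packaged synthetic inputs
derived = savm.derive_schedules(bundle, params, savm.Adjusters.default())
traj_r, traj_u, impact = savm.run_impact(derived, params)

smk = traj_r.prevalence("current_smoker")          # [year, gender], ages 15-65
print(f"2009 smoking: male {100*smk[0,0]:.2f}%, female {100*smk[0,1]:.2f}%")
print(f"averted SVADs 2025-2049: {impact.cumulative_averted_svads.sum():,.0f}")
print(f"averted LYLs  2025-2049: {impact.cumulative_averted_lyls.sum():,.0f}")
```

prints

```
2009 smoking: male 25.01%, female 8.02%
averted SVADs 2025-2049: 95,735
averted LYLs  2025-2049: 4,235,625
```

i.e. on the packaged fixture, lifting the ban averts ≈96 thousand deaths and
≈4.2 million life-years lost over 2025–2049.  Sensitivity runs
(`savm.run_sensitivity`) show averted deaths rising with the switching scale
(63k at 25% of the reference rates, 126k at 75%) and falling as the assumed
ENDS risk rises (111k at ρ=0.05, 80k at ρ=0.25).

The same pipeline is scriptable from the shell:

```sh
savm synth --seed 3 --out bundle/        # write a synthetic input bundle
savm run --input-dir bundle/ --out out/  # both scenarios + impact CSVs
savm sweep --grid grid.csv --out out/    # sensitivity sweep
savm microsim --n 100000 --which restricted --out out/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on the packaged fixture — schedule
derivation, both scenarios, the impact comparison, the sensitivity grid and
a seeded 100,000-agent Monte-Carlo cross-check of the engine — logging run
diagnostics to stderr and writing the results JSON to `--out`.

## Layout

| module | contents |
| --- | --- |
| `savm.io_model` | domain types, CSV schemas, config, validation |
| `savm.preprocess` | grouped→single-age expansion, mortality ratio, ENDS gap fill, adjusters |
| `savm.engine` | the 7-state cohort simulator for both scenarios |
| `savm.impact` | SVADs, LYLs, scenario comparison, sensitivity sweeps |
| `savm.calibrate` | adjuster fitting, ENDS recalibration, validation tables |
| `savm.synthdata` | synthetic bundles and the packaged default fixture |
| `savm.microsim` | agent-based Monte-Carlo oracle for the engine |

See `docs/methods.md` for the model's assumptions, parameter defaults and
numerical choices.
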