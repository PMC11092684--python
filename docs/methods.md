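# Methods

## Model structure

`savm` is a deterministic, discrete-time cohort model.  Each gender × birth
cohort is a probability vector over use/risk states, advanced annually from
2009 to 2049 over attained ages 0–85 (simulating from age 0 lets initiation
start at age 6 and keeps a tail above the reported range; results are
reported for ages 15–65 only).

Seven states are reported; internally nine slots are tracked because two
reported states are mixtures of risk classes:

* exclusive ENDS users split into never-provenance (never smoked, or
  reassigned from the never pool) and former-provenance (quit smoking before
  35) — both carry never-smoker mortality for cohort composition, and both
  carry the scaled ENDS excess for attribution;
* former ENDS users remember whether they came from the never-risk or
  former-risk class; only the latter carries a mortality excess.

Quitting smoking before age 35 erases the mortality excess entirely (such
quitters carry never-smoker risk); quitting at 35+ leaves former-smoker
risk.  The threshold is configurable (`quit_age_threshold`, default 35), and
a switcher exactly at the threshold age is assigned to the former-risk class.

### Within-year update order

The source material for this class of model specifies annual transition
proportions but not their within-year ordering, so the order is fixed by
design and mirrored exactly by the Monte-Carlo oracle:

1. status-specific survival (never / current / former rates by slot);
2. renormalisation of each cohort to proportions (cohort counts are pinned
   to the external population projection, so differential mortality changes
   composition, not totals);
3. smoking initiation (never → current, ages 6–39);
4. *(Unrestricted only)* ENDS initiation (never → N-ENDS) and smoker
   switching (current → N-ENDS below the quit-age threshold, else FS-ENDS);
5. smoking cessation (current → former, split by the threshold, ages 11–65);
6. *(Unrestricted only)* ENDS cessation (ENDS states → former ENDS user);
7. ageing by one year; a fresh all-never birth cohort enters at age 0;
8. *(Restricted stepping only)* the ENDS overlay at the arrival year.

Competing outflows are applied sequentially — each annual proportion acts on
the mass remaining after the previous flow — rather than as competing
hazards, which keeps the published annual proportions interpretable as such.

### The ENDS overlay (Restricted scenario)

Under the ban, exclusive ENDS use is not modelled as an absorbing flow:
ENDS-PN and ENDS-PF are treated as cross-sectional proportions, re-imposed
each year on their source pools (never users, former smokers below/above the
threshold).  The under-threshold formers' ENDS mass is kept in the
never-risk ENDS class.  Holding proportions fixed encodes the assumption
that ENDS initiation and cessation offset each other while the ban holds.
The overlay is applied after ageing, at the arrival year's proportions, so a
survey year's observed proportion is reproduced in that same calendar year.

### Scenario timing

The Unrestricted run delegates to Restricted stepping for every year before
the ban-lift year (default 2024); the first diverging state is therefore the
2025 one, and averted quantities are reported over 2025–2049 by default
while per-scenario cumulative totals span 2009–2049.  Both windows are
configurable on `compare_scenarios`.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `smoking_initiation_multiplier` | 0.75 | Unrestricted smoking initiation as a share of the Restricted schedule |
| `ends_initiation_multiplier` | 0.50 | Unrestricted ENDS initiation as a share of the same smoking-initiation schedule |
| `smoking_cessation_multiplier`, `ends_cessation_multiplier` | 1.00 | both cessation channels run at the Restricted cessation schedule |
| `switching_rate` | 0.6–4.0 %/yr by band | reference (100%) smoker→ENDS switching rates by age band and gender |
| `switching_scale` | 0.50 | applied share of the reference switching rates (sensitivity 0.25/0.75) |
| `ends_risk_multiplier` ρ | 0.15 | ENDS excess mortality as a fraction of smoking's excess (sensitivity 0.05/0.25) |
| `ban_lift_year` | 2024 | first year stepped with Unrestricted rules |
| `ends_start_year` | 2015 | first year of the Restricted ENDS overlay |
| `quit_age_threshold` | 35 | age separating never-risk from former-risk quitters |

The stored switching rates are the full reference rates; the applied rate is
`switching_scale ×` reference, so the default configuration applies male
(female) rates of 2.0% (1.3%) per year under 25 down to 0.3% (0.5%) at 65+.

Calibration adjusters (band scalers on the rate schedules) default to the
packaged values: male (female) initiation 1.52 (1.53) at ages 15–24 and 1.78
(1.56) at 25–40; cessation 0.50 (0.50) at 25–39 and 0.48 (0.00) at 40+.
Read literally from their band labels, age 40 belongs to both the 25–40
initiation band and the 40+ cessation band.  Rates pushed above 1 by
adjusters or by the mortality ratio are clipped to 1 with a logged warning.

## Preprocessing choices

* **Grouped → single age.**  Five-year-band prevalence is anchored at each
  band's integer mid-age (15–19 → 17, …, 60–65 → 62), linearly interpolated
  between mid-ages, and held constant above 62.  Current smoking ramps
  linearly from 0 at age 9 and former smoking from 0 at age 15 up to the
  first mid-age — the zero floors and the anchoring are given; the linear
  connecting shape is the minimal consistent assumption.
* **Life expectancy.**  Anchor-year schedules (2010/2015/2019) are assigned
  piecewise-constant over model years (2010 → 2009–2014, 2015 → 2015–2018,
  2019 → 2019–2049), expanded from 5-year bands with the same mid-age
  interpolation (a choice made for internal consistency; no convention is
  prescribed), and multiplied by the never-smoker/overall reference ratio,
  held constant over the modelling period.
* **ENDS proportions.**  Interior non-survey years take the mean of the
  nearest surveys on either side (2017 from 2016/2018, 2019 from 2018/2020);
  years after the last survey hold its value; band values apply uniformly to
  every age in the band and are zero outside ages 15–65.
* **Status mortality.**  `m_s = (m_overall^country / m_overall^ref) ×
  m_s^ref`, cell-by-cell; a zero reference rate is a hard error naming the
  cell.

## Synthetic data

The generator emulates the *structure* of the real inputs, not their exact
values: a smooth population pyramid projected forward consistently with the
country mortality it generates; reference mortality log-linear in age
through the published anchor magnitudes (0.12%/0.04% at age 20, male/female)
with a 43–52% secular decline; status-specific rates ordered never < former
< current; a male smoking profile several-fold the female one; ENDS
proportions below 2% rising to the last survey year with small
multiplicative jitter.  The packaged default fixture additionally rescales
the grouped current-smoking bands so the 2009 population-weighted 15–65
prevalence is exactly 25.01% (male) / 8.02% (female), and its
life-expectancy anchors give the published never-smoker trend (+7%/+5% at
age 20 over the period).

What a green test on the fixture does **not** establish: agreement with any
real country's survey microdata, realistic migration (the projection has
none), cohort effects in initiation beyond a mild secular decline, or the
absolute SVAD/LYL magnitudes of any published configuration — those depend
on proprietary input schedules that are not reproducible from printed
sources.  Fixture-based tests establish the *mechanics*: conservation,
monotone scenario response, oracle equivalence and calibration
recoverability.

## Calibration and validation

The fit minimises the sum of squared differences between modelled and
observed relative changes in current-smoking prevalence, `(P_later −
P_base)/P_base`, over the eight adjusters (four per gender; genders are
independent and fitted separately).  The optimizer is a bounded coordinate
grid search (bounds [0, 3], step 0.01, up to 10 sweeps) — the objective is
cheap, deterministic, and non-smooth where clipping engages, which rules out
gradient methods.  With only the four coarse-band targets the 25–40
initiation and 25–39 cessation adjusters trade off along a near-flat ridge;
ten 5-year-band targets (the resolution such surveys actually publish)
identify all four coordinates, and the parameter-recovery test demonstrates
exact recovery on noise-free targets.

ENDS recalibration is single-pass: each observed cell's ENDS-PN/PF is
multiplied by observed/modelled exclusive-ENDS prevalence; cells with zero
modelled prevalence are skipped with a warning.

## The Monte-Carlo oracle

`savm.microsim` re-implements the identical ordered rule set with Bernoulli
draws per agent, using a fresh uniform per sequential stage (conditional
independence given the state reached so far).  Renormalisation is handled by
weighting — agents die and stay dead; prevalence conditioned on survival is
estimated per age cell and combined with population weights, which is
unbiased for the engine's renormalised occupancies.

Equivalence is checked cell-wise with gaps studentised under the null that
the engine prevalence is the true Bernoulli probability (the plug-in SE
degenerates to zero when a rare state draws no agents).  Because ~1,150
cells are compared at once, a raw every-cell-within-3-SE criterion would
fail honest noise with high probability; the test therefore requires ≥99% of
cells within 3 SE *and* no cell beyond 5 SE, whose family false-alarm
probability is below 0.1%.  Observed agreement at n = 100,000 is max |z| ≈ 3
with ≥99.8% of cells inside 3 SE.

## Numerical notes

* Occupancies are renormalised once per year after survival; conservation
  holds to ~1e-15 over the full run.
* Zero-population or zero-occupancy cells divide to zero, not NaN.
* CSV output uses 12-significant-digit floats; write→read round-trips are
  identities at 10 significant digits.
* All randomness (synthetic jitter, survey emulation, agents) flows through
  `numpy.random.default_rng` with explicit seeds; equal seeds give
  bit-identical outputs.

## Known limitations

Dual use of cigarettes and ENDS, relapse after two years quit, heated
tobacco products, migration, QALYs/costs and attribution above age 65 are
all out of scope by design.  The Restricted overlay holds ENDS proportions
at their last survey value indefinitely; if real ENDS use keeps rising, the
scenario difference overstates the ban's effect.  Sensitivity percentages
are ratios of the package's own computed counts and are not expected to
match any externally printed sensitivity percentages exactly.
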