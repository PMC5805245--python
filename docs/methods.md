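# Methods

## The model

`nutristage` models a population aged 0–59 as a system-dynamics aging
chain stratified by nutritional stage. Twelve 5-year age-group stocks
(0–4 … 55–59) are each split into three BMI categories — *not overweight*,
*overweight*, *obese* (WHO z-score cut-offs for ages 0–17, BMI 25/30 kg/m²
for adults). Writing `N_i, W_i, O_i` for the three stocks of group `i`, the
continuous-time dynamics of one stratum are

    dN_i/dt = in_i^N + τ4_i W_i − τ1_i N_i − E_i^N
    dW_i/dt = in_i^W + τ1_i N_i + τ3_i O_i − (τ2_i + τ4_i) W_i − E_i^W
    dO_i/dt = in_i^O + τ2_i W_i − τ3_i O_i − E_i^O

where the inflow `in_0` is births and `in_i = E_{i−1} S_{i−1}` for `i ≥ 1`
(maturation of upstream survivors). The four **transference rates (TRs)**
τ1 (N→W), τ2 (W→O), τ3 (O→W), τ4 (W→N) are fractions per year, uniform
within a group. People exit the system on reaching 60.

**Exits.** The default exit flow is the first-order aging chain
`E_i = stock_i / Y` with mean residence `Y = 5` years; a fraction
`S_i = exp(−R_i Y)` of each exit matures into group `i+1` and `1 − S_i`
dies (`R_i` = per-year mortality rate, identical across BMI categories
within a group — there are no Colombian mortality-by-BMI data). An
alternative `literal_paper` formulation, in which the exit equals the
stock's *net inflow* divided by `Y`, is retained behind a flag for fidelity
experiments: it is degenerate (a stock with no inflow never drains,
regardless of size), which is why it is not the default.

**Births.** `B_c = μ · θ_c · f(t)/35 · Σ_{i∈15–49} (N_i + W_i + O_i)`,
with μ = 0.523 the female fraction of the 15–49 population, `f(t)` the
total fertility rate (children per woman, looked up piecewise-constant by
calendar year, no extrapolation), 35 = the span of the childbearing ages
15–49 (age groups 3–9), and θ the birth fractions by category (prevalence
at ages 0–2 months), `Σθ_c = 1`.

**Integration.** Fixed-step Euler, `dt = 0.25` yr by default (the
convention of the desktop system-dynamics tools this model family comes
from), with classic RK4 available; report points at integer years. Stocks
are clamped at zero after each step and clamp events counted (none occur
under realistic inputs). Halving `dt` moves yearly prevalences by < 1e−3
(verified in the suite), and Euler at `dt = 0.01` agrees with RK4 at
`dt = 0.25` to the same tolerance. The per-step population ledger — change
in total = births − deaths − final-group maturation — closes to 1e−6
relative.

## Estimating the transference rates from two survey waves

Longitudinal data do not exist, so the TRs are recovered from two
cross-sectional prevalence-by-single-age tables five years apart (emulating
the 2005 and 2010 national health surveys). The cohort aged `a` in wave 1
is treated as the cohort aged `a + 5` in wave 2. Within group `i` the
one-year category dynamics are the column-stochastic matrix

    A_i = [[1−τ1, τ4,       0  ],
           [τ1,   1−τ2−τ4,  τ3 ],
           [0,    τ2,       1−τ3]]

(columns = source category), so the prediction for wave 2 is `A_i^5` applied
to each of the five wave-1 age columns of group `i`. The estimate minimises

    CD_i = Σ_{j=1..5} ‖ P2010_{i+1,j} − A_i^5 P2005_{i,j} ‖²

subject to `0 ≤ τ ≤ 1` and `τ2 + τ4 ≤ 1` (equivalently, all retention
rates α in [0, 1]; the α's are eliminated by substitution). Group 11
(55–59) uses the wave-2 ages 60–64, which is why survey tables extend to
age 64 although the simulated chain stops at 59.

**Optimiser.** SLSQP with bounds and the single linear constraint,
multi-started from the origin, a small uniform-rate point, and seeded
Latin-hypercube draws biased toward the small-rate corner (32 starts by
default). Among candidates whose objective ties within relative 1e−9 the
smallest ‖τ‖₂ is reported, making results deterministic given the seed. A
vectorised lattice search (`grid_search`) provides an independent oracle:
on 0.001-step lattices the optimiser always attains an objective at or
below the lattice minimum.

**Identifiability.** With noiseless data generated by the model, the
minimum is exact and unique in practice and recovery is better than 1e−4
per rate. The weakly identified direction is the (τ2, τ3) pair: a fast
W↔O exchange with the right equilibrium split mimics a slow one unless the
five age columns of a group differ enough in their overweight/obese mix.
Identification therefore rests on within-group age heterogeneity of the
survey prevalences — real single-age survey tables carry several percentage
points of age-to-age variation, which is ample.

## Synthetic data generator

The generator emulates exactly the structure the estimator assumes, so the
whole pipeline is testable without any external download:

* **Truth rates** — `paper_like` draws adult τ1 ∈ [0.005, 0.04],
  τ2 ∈ [0.002, 0.017], recovery rates τ3, τ4 ≈ 0 except in childhood
  (τ4 ∈ [0.02, 0.05] at ages 0–4, τ3 ∈ [0.015, 0.045] at 10–14), matching
  the magnitudes and sign pattern of the published Colombian estimates;
  `random_feasible` draws uniformly over the feasible region.
* **Wave 1** — logistic ramps in age for overweight (midpoint 22 y) and
  obesity (midpoint 30 y) plus sinusoidal ripples of amplitude 0.04 and
  0.025. The ripples model realistic single-age heterogeneity and carry
  the identification of the recovery rates (see above); with smaller
  ripples (≈0.015) the (τ2, τ3) direction is under-identified at survey
  noise scale and estimates can run away along it while legitimately
  lowering the objective.
* **Wave 2** — wave-1 columns pushed through `A_i^5`; ages 0–4 of wave 2
  (cohorts born between the waves, unused by the estimator) reuse the
  wave-1 columns.
* **Noise** — additive Gaussian (default sd 0.005, survey sampling-error
  scale) on every prevalence entry, clipped at zero and renormalised to
  the simplex. At that noise level the median absolute recovery error over
  replicates is ≈ 0.002.

What the generator does **not** emulate: the survey's cluster sampling and
weights, age-correlated sampling error, reporting heaping, or secular
drift between waves beyond the transition process itself. Passing recovery
tests therefore show that the estimator inverts the assumed data-generating
process, not that the assumptions hold in any particular survey.

## SES stratification and summaries

Three strata (wealth-index quintiles 1–2 / 3 / 4–5) run as independent
chains on a shared calendar — no between-strata mobility. Stratum-specific
demography can be supplied; by default all strata share the national
values (the stratified appendix detail of the source analysis is not
public). Summaries:

* **Obesity prevalence ratio** `PR(t)` = adult (20–59) obesity prevalence
  of the lower stratum divided by the higher stratum's. PR > 1 places the
  obesity burden on the poorer population. Invariant to rescaling either
  stratum's population.
* **Mean TR** — the unweighted arithmetic mean of a τ column over the 12
  age groups, reported at 4 decimals. This is the only aggregation
  consistent with the published per-SES summary values (verified against
  the packaged tables; note the lower-SES τ1 mean computes to 0.02156,
  which the published summary evidently truncated to 0.0215).

## Policy scenarios

A scenario is a list of timed overrides `(groups, τ-index, value, window)`.
Overrides are *floors* — the effective rate is `max(baseline, value)`
inside the window — because the policy narrative is "raise the recovery
rates *to* 0.02"; a `replace` mode exists. Two canned scenarios target the
recovery rates τ3, τ4 at 0.02/yr from 2011 to 2030 for ages 5–14
(school-based programmes) and 15–24. Comparisons report both the
percentage-point difference and the percent relative change; the relative
change is the headline (it is the reading consistent with the published
paired prevalences, e.g. 20.5 → 18.8 ≈ −8.3%).

## The packaged Colombia configuration

The package ships the published TR tables (urban and per-SES, 2005–2010)
and a **synthetic** reconstruction of the 2005 starting conditions
(`datasets.synthetic_colombia_2005`): the publicly reported 2005 group
prevalences are used as-is, childhood and 40–59 values are field-typical
fills, and the 40–59 fills are shifted by a constant so the adult (20–59)
aggregates reproduce the observed 34.2% overweight / 15.7% obese exactly.
Demography is a DANE-scale reconstruction (population pyramid in
thousands, age-specific mortality, urban fertility declining 2.1 → 1.85
over 2005–2015, θ = (0.85, 0.11, 0.04)). This stand-in exists because the
official single-age inputs are not redistributable here; results computed
from it are labelled accordingly.

Under this configuration the *relative* published results reproduce well
(scenario-1 relative decreases for ages 5–19 by 2030: 9.4% overweight /
8.4% obese; the PR crosses 1 just before 2018), while the *absolute* 2030
levels undershoot (adult overweight 42.4% vs 47.7% published; obese 11.8%
vs 19.2%). The gap is structural: the first-order chain's exponential
residence times mix cohorts and erode the 2005 initial conditions faster
than the original solver evidently did — the `literal_paper` formulation
brackets the published values from above (50.9% / 24.3%) on the same
inputs — compounded by the reconstructed inputs. We report the default
formulation's numbers and do not tune the stand-in toward the published
outputs.

## Numerical choices and edge cases

* Survey columns are validated to the simplex within 1e−6 and renormalised
  to machine precision; empty age groups report zero prevalence rows.
* Band prevalence for stock initialisation is the unweighted mean of the
  five single-year prevalences (configurable to population-weighted when
  single-age populations are known).
* Fertility lookup is strict: a year outside the supplied series raises.
* The negative-stock guard clamps at zero and logs; with default inputs it
  never triggers.
* TR CSVs are serialised at 6 significant digits in scientific notation;
  age groups as "0-4" … "55-59".

## Known limitations

* No migration, no BMI-specific mortality, no SES mobility, no rural
  population — all absent by design of the underlying model.
* TRs are point estimates; the least-squares heuristic provides no
  uncertainty quantification.
* Ages 60+ are outside the simulated system (no reliable wave-2 target for
  estimating their rates).
* Projections inherit the aging-chain residence-time approximation; see
  the Colombia section above for its quantitative effect.
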