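# Methods

This note documents the models behind `thermoshred`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Study system

Two freshwater amphipod shredders are compared: the native *Gammarus
pulex* and the invasive Ponto–Caspian *Dikerogammarus villosus*.  Two
experiments feed the pipeline: (1) individual animals on a 4–24 °C
thermal-gradient track, observed every 3 min for 45 min after acclimation
at 5, 15 or 20 °C (30 animals per group per species); (2) 72 h
leaf-shredding trials at eight temperatures (5–22.5 °C), two animals per
pot, ten replicates per species × temperature × size class, with deaths
checked every 24 h and pre-weighed batches of five sycamore leaf discs
(16.00 ± 3.27 mg air-dry mass, treated as an SD).

## Thermal preferenda (acute method)

Each individual's selected temperature is the **median** of its 15
recorded temperatures, avoiding pseudoreplication of repeated records.
The **acute preferendum** at an acclimation temperature is the mean of
those medians (± SE; a singleton group reports its SE as undefined, never
zero).  Fitting the acute means against acclimation temperature by OLS
gives the preference line `pref = a + b·T_acc`; the **final preferendum**
is its intersection with the 1:1 equality line, `a / (1 − b)`.  Because
this is a nonlinear function of correlated estimates, its CI is a
parametric bootstrap (default 1000 seeded draws) from the bivariate normal
sampling distribution of `(a, b)`.  With only three acclimation
temperatures the residual variance has a single degree of freedom, so the
bootstrap CI is honest but noisy; `|1 − b|` below 1e-6 raises a divergence
error (preference parallel to equality).

Control runs at uniform 20 °C are binned into twelve 10 cm track sections
(half-open bins, last bin closed) and tested with Pearson's chi-squared,
df = 11.  The tail probability is the regularised upper incomplete gamma
function (via `scipy.stats.chi2.sf`), verified in the test suite against
an independent series/continued-fraction implementation to 1e-10.

**Model comparison.**  Candidate models for the individual medians are all
additive subsets of {species, acclimation temperature, sex (, body size)}
plus the species × acclimation interaction whenever both main effects are
present.  Models are fitted by ordinary least squares with a Gaussian
likelihood; the parameter count for AICc includes the residual variance.
Ranking uses AICc; models with ΔAICc < 4 are retained, given Akaike
weights `exp(−Δ/2)/Σ exp(−Δ/2)`, and coefficients are model-averaged with
**zero substitution** for omitted terms (a configurable choice;
conditional averaging is the alternative).  The original analysis fitted
these fixed effects inside a mixed model with random track and run-time
effects; the REML machinery is deliberately out of scope here, and track
and run are available only as fixed blocking factors.  A `transform` hook
accepts a user-supplied monotone transform of the medians (the residual
leptokurtosis correction is otherwise unspecified); the default is none,
so coefficient tables are on the raw °C scale and are not numerically
comparable with results published on a transformed scale.

## Shredding efficiency

Efficiency is dry leaf mass consumed per **amphipod-day**: the number of
surviving animals per day summed over the three days.  Whether the day of
death counts is not defined by the measurement itself, so it is a config
switch: the default `partial` counts the check-day (an animal found dead
at the first 24 h check contributes 1 amphipod-day); `none` contributes
d − 1.  Replicates with a moulted animal (moulting suppresses feeding) or
zero amphipod-days are excluded with a recorded reason.  Control pots lose
mass only to leaching/microbial breakdown; when their mean fractional
loss is below 2% no correction is applied (the discount rule), otherwise
the mean control loss is subtracted proportionally.  Measured negative
consumption is floored at zero and flagged rather than excluded.

Body length and wet mass are collapsed by PCA on their 2 × 2 correlation
matrix; PC1 explains `(1 + r)/2` of the variance (93.8% at the generator's
default r = 0.876) and both loadings are constrained positive.  Size
matching is verified by one-way ANOVA on PC1 scores.  Efficiency is then
analysed by a species × temperature two-way ANOVA with temperature
categorical (eight levels), Type-I sums of squares on the balanced
design (Type-II fallback with a warning when exclusions unbalance it), and
stepwise deletion of a non-significant interaction.  Tukey HSD post-hoc
tests are out of scope.  Survival at 72 h is reported per cell with a
Wilson score 95% CI.

## Boltzmann–Arrhenius activation energies

Temperature is standardised as `x = 1/(k·T_ref) − 1/(k·T)` with
`k = 8.62e-5 eV/K` and `T_ref = 288.15 K`, so `x(15 °C) = 0` and warmer
water means larger `x`.  The Arrhenius fit regresses the **log of the
per-temperature mean rate** (means first, then ln — one point per
temperature, n = 8) on `x`; the slope estimates the activation energy in
eV with t-based 95% CIs on n − 2 df.  Rates are **mass-specific**
(g leaf · g body⁻¹ · day⁻¹, consumed mass divided by pot mean wet mass and
amphipod-days): the population projection explicitly multiplies a
mass-specific rate by mean body mass, and this convention keeps the two
stages consistent; a per-capita alternative can be fitted by passing
`rate_col="efficiency_mg_per_ad"`.  Estimates are classified against the
0.60–0.70 eV consumer–resource band as `within` (point estimate in band),
`overlapping-CI`, or `outside`.

The species ANCOVA compares nested linear models of the pooled ln-rate
points.  The default (`terms="overall"`) tests the full
species-by-temperature model (4 parameters) against the intercept-only
null, giving the F statistic of the full regression with df (3, 12) on a
2 × 8 design — the df bookkeeping of an `lm(y ~ species * x)` summary.
`terms="species"` instead compares against the common-line model,
isolating the species-linked terms with df (2, 12).

## Preference–performance coupling (ONLS)

Each experimental temperature defines a zone ± 1 °C.  Zones of 8/10 °C and
15.5/17.5 °C share a boundary point; membership uses closed intervals with
records at a shared boundary assigned to the nearer centre, ties
downward.  Habitat use is mean records per 15 °C-acclimated individual in
the zone; performance is mean leaf mass consumed per individual over 72 h,
dividing each pot by its surviving-animal exposure (amphipod-days /
3; dividing by stocked animals is the configurable alternative), which
partially absorbs the higher mortality at warm temperatures.

The model `performance = α + β / use` is fitted by orthogonal non-linear
least squares because both axes carry measurement error.  The objective is

    Σᵢ (uᵢ − uᵢ*)²/su² + (yᵢ − α − β/uᵢ*)²/sy²

minimised over `(α, β)` and the per-datum foot points `uᵢ*` (bounded below
by a positive floor of 1e-6 × max use).  `su`, `sy` are the pooled SEs of
the two axes, with unit weights when absent.  The inner foot-point search
is a vectorised coarse grid plus golden-section refinement (the observed
`uᵢ` is kept as a candidate, so the orthogonal RSS can never exceed the
vertical RSS); the outer search is Nelder–Mead from an OLS-on-(1/u)
initialisation plus four seeded jittered restarts.  Parameter SEs come
from the finite-difference Hessian of the profiled objective
(`cov = 2σ̂²H⁻¹`, `σ̂² = RSS/(n − 2)`), and the β t-test uses n − 2 df —
six when all eight zones are usable, which reproduces the printed p-values
for |t| = 2.915 (p = 0.027) and t = 0.830 (p = 0.438).  The optimiser is
checked against a zoomed brute-force grid oracle to 1e-3 relative.

## Population shredding capacity

For a hypothetical population of 100 animals,

    capacity (g leaf / 72 h) = rate₇₂ₕ × mean mass × survival × 100

with `rate₇₂ₕ = 3·exp(intercept + E_a·x(T))` from the all-data Arrhenius
fit, default mean masses 0.0305 g (*G. pulex*) and 0.0682 g
(*D. villosus*), and empirical (or generated) survival per temperature —
survival is always an input column, never digitised from a figure.  The
capacity identity holds exactly by construction and is unit-tested on
random inputs.  The capacity–temperature association is the Pearson
correlation over the eight design temperatures with
`t = r√(n−2)/√(1−r²)`; a numerically constant profile reports r = 0 with
a flag.  The species ratio is `100·(cap_A − cap_B)/cap_B`.

## Synthetic-data generator

The generator defines the study conditions and is first-class, tested
code.  Choices:

* **Movement** is not simulated: recorded temperatures are i.i.d. draws
  from a truncated normal around the acute preference line (sd 2 °C by
  default).  Downstream estimators only use the marginal distribution of
  records, so this exercises every estimator while making individuals
  exchangeable — real traces are autocorrelated, so passing tests show
  estimator correctness, not robustness to serial dependence.
* **15 records** per animal (intervals ending at 45 min); the alternative
  reading of the schedule (16) is configurable via the design.
* **Body sizes** are bivariate lognormal with CV 0.20 and log-scale
  correlation 0.876; size-matched pots draw both species from a common
  distribution (13.3 mm, 0.038 g).
* **Consumption** is generated mass-specifically with lognormal noise
  (sd 0.1 on the ln scale) so both size-matched and full-range designs are
  emulated; default intercepts/slopes are the all-data regression values
  (−4.46, 0.21 eV for *G. pulex*; −5.80, 0.68 eV for *D. villosus*).
* **Mortality** is a per-animal, per-24 h Bernoulli draw with a logistic
  temperature link.  No numeric survival values are published, so the
  defaults (logit intercept/slope −5.0/0.15 for *G. pulex*, −5.5/0.10 for
  *D. villosus*) were chosen once as realistic: warm-water survival ~0.6
  for the native vs ~0.9 for the invader at 22.5 °C, reproducing the
  reported ordering (the invader survives better at every temperature).
* **Moulting** is a 5% per-animal flag; controls lose uniform 0–2% mass,
  satisfying the < 2% discount rule by construction.
* Pipeline stages consume seeds spawned from one master `SeedSequence`,
  so enabling one generator never shifts another's draws; identical seed
  and config give byte-identical CSVs.

## Problem sizes and numerical tolerances

Parameter-recovery checks use 200 seeded replicates (mean recovered
activation energy within ±0.05 eV of the generating value at ln-noise
0.1; mean recovered final preferendum within ±0.3 °C at sd 2 °C, 30
animals per group), CI-coverage checks use 1000 simulated fits
(95% ± 3%), and the uniformity type-I-error check uses 400 seeds.  The
ONLS oracle comparison uses instances of 5–10 zones with O(1) parameters
and tolerance 1e-3 relative.  Chi-squared tails are validated to 1e-10
against the incomplete-gamma oracle; ANOVA sum-of-squares decomposition is
exact to 1e-8 relative on balanced data.

## Known limitations

* Random effects (track, run time) are not estimated; AICc values of the
  fixed-effects fits will differ from a mixed-model analysis even on
  identical data, although the candidate ranking logic is the same.
* The final-preferendum CI rests on three acclimation means (one residual
  df); it is reproducible but wide-tailed across seeds.
* The leptokurtosis transform of the original preference analysis is
  unspecified; untransformed coefficients are reported by default, so
  published coefficient tables on the transformed scale are not
  numerically reproduced.
* Depleted pots (leaf fully consumed) are flagged but still contribute
  their floored consumption; strong food limitation would bias rates low.
* ONLS assumes Gaussian errors on both axes with a single pooled scale per
  axis; per-zone heteroscedastic weighting is not implemented.
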