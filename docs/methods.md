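# Methods

## Population thermal-time threshold model

The forward model treats a seed population as a continuum of quantiles
g ∈ (0, 1).  Two thresholds vary across the population, both normal and
mapped from a single quantile rank (comonotonic coupling):

* Θ_cold(g) = Θ_cold(50%) + σ_Θ · Φ⁻¹(g) — the degree-days above T_base a
  seed must accumulate (°C·d);
* T_c(g) = T_c(50%) − σ_Tc · Φ⁻¹(g) — the seed's ceiling temperature (°C).

T_base and θ_warm are common to the whole population; this mirrors which
quantities germination studies report with SDs and which without.  The
comonotonic direction (fast seeds also have high ceilings) is the
conventional assumption in population threshold models; it makes
percentile ranks consistent across the two regimes, which the fitting
construction implicitly requires.  Each seed follows the sub-optimal rate
line up to its own intersection with the supra-optimal line, so its rate
profile is continuous, piecewise linear, and zero exactly at T_base and
its own T_c.

The expected cumulative germinated fraction has the closed form

    F(t; T) = p_viable · min(g₁, g₂)
    g₁ = Φ(((T − T_base)·t − Θ_cold(50%)) / σ_Θ)
    g₂ = Φ((T_c(50%) − T − θ_warm/t) / σ_Tc)

(g₂ → a step function as σ → 0).  At genuinely sub-optimal temperatures
g₂ is slack and F reduces to the familiar probit-in-thermal-time curve.
Two consequences of the min() coupling are worth knowing: at very early
times the fast tail is always ceiling-limited (so F is not strictly
monotone in T there), and near the optimum the slow comonotonic tail is
ceiling-limited, which depresses late-time percentages a little below the
pure sub-optimal form.  Both effects are small (≤ ~0.1% of the
population under the packaged parameter sets) but visible in exacting
property tests, which therefore assert monotonicity on the
thermal-limited branch.

### Event semantics

The thermal-time thresholds govern the *scored germination event* —
endosperm rupture (ER, radicle emergence), which is what germination
assays count and what the fitting stage consumes.  Testa rupture (TR)
precedes ER by a lognormal lag (median `er_lag_50`, shape
`lag_sigma_log`); the lag keeps TR strictly positive by clipping at
0.05 d.  Exogenous ABA stretches the lag by a saturating factor
1 + (M−1)·c/(c+K) (ceiling M = `lag_multiplier_aba`, default 3;
half-saturation K = 10 µM), delaying ER while leaving TR untouched — the
dose–lag relation is not tabulated anywhere, so both constants are free
configuration with defaults chosen to give a clearly visible 1–2 day ER
delay at tens of µM.  Because the lag draw is shared between the control
and treated realisation of a seed, an ABA run under the same rng stream
reproduces the TR time-course bit-for-bit.

## Simulator

`simulate_experiment` realizes dishes independently: each
(temperature, dish) pair receives a child stream spawned from the root
seed, seeds draw viability (Bernoulli p_viable), one threshold rank
(rejection-resampled if Θ ≤ 0 or T_c ≤ T_base, a negligible correction
for realistic parameters), and one lag deviate.  Events enter cumulative
counts at the first scoring time at or after they occur (daily bins,
closed on the right), which adds the familiar ~+0.5 d discretization to
every observed time.  Identical designs and seeds give bit-identical
records.

Dormancy states and treatments act only through p_viable:
p_viable = viability ceiling × released fraction, where darkness releases
nothing, water releases f_nd, GA or after-ripening releases f_nd + f_npd
(fluridone alone is a no-op; combined with GA it adds a configurable
increment, default 0.05), the GA + ethylene + nitrate cocktail releases
everything, and scarification substitutes a configurable coat-release
fraction.  Cold needs no rule of its own: low temperature slows both TR
and ER through the thermal-time model itself.

## Packaged study conditions

Three population presets carry the headline parameter values: black
after-ripened #1 (T_base 8 °C, Θ_cold(50%) 144 °C·d, T_c(50%) 35 °C,
broad distributions), brown #1 (cardinal temperatures ~2 °C higher, low
sharp ceiling at 31 °C), and seedlot #2 (T_opt ~22 °C, T_base 10.5 °C,
sharp Θ distribution); viable fractions default to 0.6, matching the
observed plateaus.  θ_warm is not reported directly anywhere and is
derived from the rate-line intersection identity
θ_warm = Θ_cold(50%)·(T_c − T_opt)/(T_opt − T_base).  The SDs of the two
threshold distributions are likewise unreported; the presets use 35 / 30
/ 15 °C·d for Θ_cold and 2.5 / 1.0 / 2.0 °C for T_c, ordered to respect
the qualitative broad-vs-sharp contrasts between the populations.

The freshly harvested dormant black #1 state uses layer fractions
f_nd : f_npd : f_dpd = 2/19 : 10/19 : 7/19 of viable seeds under a 0.95
viability ceiling, so the ideal treatment ladder is 10% (water), 60%
(GA/AR), 95% (full release) and 75% (scarified) — the observed ladder.

The recovery experiments use 3 dishes × 30 seeds at 9 temperatures with
daily scoring to day 60 (cold temperatures need ~8 weeks for slow
percentiles to plateau); the G_max assays score daily to day 14.  The
temperature grids place a point near each population's optimum (as a
gradient-plate design would): with the shared argmax temperature sitting
close to T_opt, that point lies essentially on both regression lines and
the classical two-line fit stays nearly unbiased.  At this scale a full
simulate-plus-fit cycle takes well under a second.

## Fitting engine

Dishes at one temperature are pooled, converted to percent of seeds sown,
and monotonized by a running maximum before percentile times are linearly
interpolated (curves are anchored at (0, 0); percentiles above the final
plateau are "not reached").  Percentiles are percent of *total seeds
sown*, 10, 20, … up to the largest multiple of 10 strictly below the
G_max estimate (itself the largest per-temperature plateau mean).

Regimes are split at the temperature with maximal rate for the reference
percentile (50, else the lowest available); the argmax temperature is
included in both regimes, as in classical two-line thermal-time fits.  A
monotone rate profile leaves the far side empty: the pipeline warns and
reports NaN ceiling parameters instead of failing.  Per-percentile
ordinary least squares (unweighted, as in standard practice) then gives
Θ_cold(g) = 1/slope and a per-percentile base-temperature intercept in
the sub-optimal region — the headline T_base is the x-intercept of the
reference percentile's line — and T_c(g) = x-intercept with
θ_warm = −1/median slope in the supra-optimal region.  Wrong-signed
percentile regressions are hard errors in strict mode and
dropped-with-diagnostics inside the pipeline, where a stray percentile
must not abort an otherwise sound fit; fewer than 3 temperatures per
percentile, fewer than 2 percentiles for a distribution fit, or fewer
than 4 temperatures overall are hard errors everywhere.

The threshold distributions come from probit regressions of the
per-percentile estimates against Φ⁻¹(g/G_ref), with G_ref the estimated
viable percentage, so ranks are quantiles within the viable population:
intercept = median, |slope| = SD (the ceiling slope is negative by
construction, hence the sign correction).  The probit slope is the
headline SD; the raw dispersion of the per-percentile estimates is kept
in the diagnostics.  T_opt is the intersection of the two median lines,
estimate_topt(T_base, Θ_cold(50%), T_c(50%), θ_warm); the intersection of
the two reference-percentile lines is reported as a diagnostic
alternative.

## What the simulator does and does not emulate

It reproduces replicate-dish binomial sampling, daily-scoring
discretization, threshold heterogeneity, treatment-dependent viable
fractions and the TR/ER event pair — the features the fitting stages are
sensitive to.  It does not emulate dormancy cycling over seasons,
hydrotime (water-potential) limitation, mechanistic hormone kinetics,
inter-dish environmental gradients, or scoring error in event
classification.  Passing recovery tests therefore demonstrate that the
analysis inverts the stated population model faithfully at realistic
sample sizes — not that real seedlots obey that model.

## Numerical choices and degenerate inputs

Zero-σ threshold distributions degenerate to step functions, not errors.
Slopes within 1e-10 (relative to the rate scale) of zero count as
wrong-signed.  Exact percentile nodes interpolate to the earliest
attaining time.  Zero germination anywhere raises an informative
pipeline error.  Cq tables accept NaN (no amplification): excluded from
the per-gene minimum, never imputed.  geNorm M uses sample SDs (ddof 1)
of pairwise log2 ratios; reference selection breaks ties
lexicographically so the chosen pair is deterministic.  Below-detection
hormone contents are encoded as 0 and carried as flags so ratios stay
numeric.

## Known limitations

The two-stage regression construction is the contract; a one-step
maximum-likelihood fit of the full threshold model would use the data
more efficiently but is deliberately out of scope.  T_base and θ_warm are
estimated from single reference regressions and inherit their noise.
G_max estimated as a max over temperatures is biased slightly upward at
small dish counts, which feeds the probit rank mapping; the effect is
visible as a few-percent inflation of Θ_cold(50%) at 3 × 30 seeds and
vanishes with sample size.  The ABA dose–lag constants and the
fluridone-with-GA increment are conventions, not measurements.
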