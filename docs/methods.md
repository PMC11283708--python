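# Methods

`ssbtax` simulates the long-run health and economic impact of a
sugar-sweetened beverage (SSB) tax on an adult population stratified by sex
and 5-year age band (20–100 years). The pipeline runs in four stages, each
compared against a do-nothing base case.

## 1. Demand response

A value-added tax of rate *r* with pass-through *p* raises consumer prices by
Δp = r·p (default 0.20 × 0.82 = 0.164). Demand responds through **marginal
(linear) price elasticities**: Δq = ε·Δp·q ml/day. We deliberately do not
compound in log space — with the alternative own-price elasticity −0.674 the
linear form gives a relative change of ε·Δp = −11.05%, whereas
exp(ε·ln(1+Δp)) − 1 would give about −9.7%; the linear form is the
convention the scenario presets are defined on and is the only one used.

Elasticity defaults: own-PE of SSBs −1.299, cross-PEs of fruit juice and
milk with respect to the SSB price +0.388 and +0.129, alternative own-PE
−0.674 (stored signed although its source prints the magnitude).

Consumption-dependent adjustments induce age heterogeneity:

* **Adjusted own-PE** (modification M1):
  ε_age = γ · ε · (θ̄_sex / θ_sex,age), with θ the age-band SSB intake and
  θ̄_sex the sex-level mean. Heavy consumers respond less elastically. γ
  defaults to the conventional 0.5, which balances only the original data;
  `gamma="solve"` computes γ = 1/mean(θ̄/θ) so that the within-sex mean of
  the adjusted elasticities equals ε exactly for any dataset (tests use this
  mode). θ̄_sex is the **unweighted** mean over age-band means by default;
  population weighting is available via `theta_bar_weighting="population"`.
  A zero SSB intake in any stratum is an error naming the stratum.
* **Adjusted cross-PE** (M4b): ε_cross,age = ε_cross · (θ_sex,age / θ̄_sex);
  heavy SSB consumers substitute more. The milk cross-PE is never adjusted
  (small value, low relevance). Zero intake yields zero substitution pull.
* **Underreporting** (M3): self-reported SSB intake (mean and SE) is
  multiplied by 1.86 in every stratum. Total energy intake E is *not*
  inflated by default — the mechanism is that an inflated baseline enlarges
  the absolute consumption change; `inflate_energy_with_underreporting=True`
  additionally adds the extra SSB calories to E, which damps the relative
  energy change by a few percent.

Post-tax consumption is clamped at ≥ 0 ml/day with a logged warning (large
adjusted elasticities can otherwise drive it negative). Arbitrary
combinations of switches are allowed but logged as non-preset
configurations; the ten presets flip one assumption at a time.

### Scenario presets

| name | change vs. main (20% tax, 82% pass-through, no substitution) |
|------|----------------------------------------------------------------|
| M1   | consumption-adjusted own-PE, γ = 0.5 |
| M2   | alternative own-PE −0.674 |
| M3   | SSB intake × 1.86 |
| M4a  | cross-PE substitution to juice and milk |
| M4b  | consumption-adjusted juice cross-PE |
| M4c  | substitution as calories: 61% of the caloric reduction compensated |
| S1 / S2 | tax rate 10% / 30% |
| S3   | fruit juice also taxed, at the average SSB own-PE; no cross effects |

Combining a juice tax (S3) with cross-price substitution is undefined and
rejected. Under M4c the compensation fraction is read as "61% of the
calories reduced are compensated", i.e. 39% of the gross change is retained;
the fraction is a config parameter, so reading it as 61% *retained* is a
one-line change (the source text is ambiguous on this point and we follow
its literal wording).

## 2. Energy and equilibrium weight

Volume changes convert to energy with fixed densities (SSB 48, fruit juice
45, milk 59 kcal per 100 ml, overridable). The long-run population weight
response uses the energy-balance equilibrium rule: a 1% sustained change in
total energy intake changes equilibrium body weight by ~0.7%, i.e.
Δw = 0.7 · (ΔE/E) · w. BMI shifts proportionally to weight at fixed height
(Δbmi = bmi · Δw/w), which avoids needing a height table and is the sole
kg→BMI bridge. Over-substitution (net energy gain, weight gain) is passed
through unclamped — it genuinely occurs in high-juice/low-SSB strata under
M4a/M4b.

## 3. BMI distribution and weight status

Each stratum's BMI is log-normal, moment-matched from its mean and SD
(σ² = ln(1 + sd²/mean²), μ = ln mean − σ²/2). The intervention shifts the
mean by Δbmi holding the SD fixed (an additive population shift, the
standard companion assumption to a PIF; a CV-preserving mode exists for
sensitivity). Overweight is 25 ≤ BMI < 30 and obesity BMI ≥ 30 (WHO
convention, configurable). Case changes are population × prevalence
difference; the two bands are computed independently because a downward
shift can *raise* overweight prevalence in high-BMI strata (obese crossing
down into the band).

## 4. Multi-state life table

Each cohort enters at its band's midpoint age as one homogeneous group with
a prevalence-initialized disease split and runs in annual cycles to age 100
through states {alive without T2DM, alive with T2DM, dead}; remission is 0.

The potential impact fraction lowers T2DM incidence:

PIF = 1 − ∫RR(x)f′(x)dx / ∫RR(x)f(x)dx, RR(x) = rr^(x − x_ref),

with rr the age-group relative risk per BMI unit (defaults 1.27/1.18/1.10/
1.06 for ages 20+/40+/60+/80+, held constant above the oldest group) and
f, f′ the pre/post BMI densities. The PIF is computed once per stratum from
its entry-age RR, applied from cycle 1 and constant thereafter (full tax
effectiveness in year one). It is invariant to x_ref, which cancels in the
ratio. Integrals run over BMI ∈ [10, 70] but are evaluated in the
standardized log variable z = (ln x − μ)/σ (limits clipped at ±12), which is
well conditioned for any σ: the default path is a 200-node Gauss–Legendre
rule (vectorized across strata); an adaptive-quadrature path with absolute
tolerance 1e−13 serves as the oracle and agrees to ~1e−12.

**Cycle arithmetic.** Within a cycle, competing exits from a state are
resolved with the joint exponential survival exp(−Σ hazards) applied to
cycle-start occupancy, exits split proportionally to hazards. There is no
within-cycle ordering, and for constant hazards disease-free survivorship
equals exp(−(i+m)·t) exactly. Applying independent per-transition
probabilities 1 − exp(−rate) to the same occupancy would violate that closed
form (e^(−i) + e^(−m) − 1 ≠ e^(−(i+m))), which is why the joint form is the
package's convention; probabilities can then never sum above 1, so the only
rate validation needed is finiteness and non-negativity. New cases created
within a cycle face mortality from the next cycle. Bookkeeping is
start-of-cycle with no half-cycle correction (1,000 immortal 20-year-olds
accumulate exactly 80,000 life years). Person conservation is asserted every
cycle at 1e−9 relative.

**Valuation.** Per cycle, HALY = alive·(1 − pyld_bg) − prevalent·dw, where
the background pYLD rate *excludes* T2DM disability (no double counting with
the disability weight, default 0.049). DALYs averted = Σ discounted
(HALY_int − HALY_base). Costs: scenario cost = prevalent·cost_with +
(alive − prevalent)·cost_without; savings are discounted base-minus-
intervention, so extra survivors automatically offset savings through
cost_without. Discounting is 3%/year from each cohort's entry (year 0
undiscounted); incident cases and prevalent years averted are reported
undiscounted.

## 5. Monte Carlo uncertainty

2,000 iterations by default. One joint parameter draw feeds the whole chain
per iteration — demand, weight, and MSLT stages see the same draw, and all
scenarios in a run share it (common random numbers), so cross-scenario
ratios are paired. This replaces the original two-tool split (R for the
weight stage, a spreadsheet add-in for the MSLT) with a single-stage design
that preserves correlations. Families: intakes and elasticities normal
(mean, SE; non-negative supports enforced by bounded redraw), pass-through
normal truncated to [0,1] (SD 0.05), RR log-normal (CV 5%, mean-preserving),
disability weight beta (SD 0.005), costs gamma (CV 10%). These dispersions
are declared package defaults, not claims about the original appendix, and
are all configurable. Uncertainty intervals are empirical 2.5/97.5
percentiles with linear interpolation (no BCa). Identical (seed, spec,
inputs) give bit-identical output. T2DM epidemiology, all-cause mortality
and the discount rate are not sampled.

## Synthetic data

The original inputs (a national nutrition survey and statutory-insurance
epidemiology) are restricted, so `ssbtax.synth` generates a complete world
with their statistical structure: SSB intake peaking at 20–24 (male ~420
ml/day) and declining 8–20% per band, male above female everywhere
(female/male ratio drawn in 0.55–0.70); juice and milk flat around 150–170
ml/day; energy declining from ~2600/2050 (m/f) to ~2100/1700 kcal/day; BMI
mean rising ~24→28 with age (SD 3.8–4.6, right-skewed via the log-normal);
T2DM incidence log-linear in age (5e−4 at 20, slope 0.068/yr, flat above
80); Gompertz all-cause mortality (6e−4 at 20, slope 0.075/yr, men ×1.4);
T2DM excess mortality as (HR − 1)·acm with HR 1.8; costs €4,900/€2,500 per
person-year with/without T2DM. Populations are integer-allocated by largest
remainder. Prevalence is produced by forward-running the package's own
illness–death recursion on the generated rates, so it is steady-state
consistent with the life table by construction.

These magnitudes are realistic for German adults but are *not* the original
population: green tests establish internal correctness of the machinery and
the qualitative ordering of scenarios, not the original study's headline
numbers, which require the restricted inputs. Real data in the documented
CSV schemas can be substituted directly.

## Numerical choices and limitations

* Gauss–Legendre order 200 for PIF (error ~1e−12 against adaptive
  quadrature); BMI domain [10, 70].
* Log-normal moment matching is exact; degenerate sd = 0 is allowed only as
  an oracle device.
* Clamping of post-tax consumption at zero is the only nonlinearity in the
  demand stage; it never binds at the preset parameter values on the default
  synthetic world.
* Only T2DM is modelled; no secular BMI trends, no age-specific disability
  weights, no tax revenue or productivity costs; cohorts are homogeneous
  within a band; the tax is fully effective from year one, which overstates
  early impact.
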