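# Methods

## Model structure

`pmslt` is a proportional multi-state lifetable: a population lifetable
coupled to independent per-disease three-state Markov models (disease-free,
diseased, dead from that disease). The "proportional" separation means the
disease sub-models run on proportions with no other-cause mortality inside
them — S + C + D is conserved per cohort — and the lifetable rescales their
outputs by survivorship. Disease-specific mortality changes feed back into
the lifetable's all-cause mortality, so a scenario that prevents disease
deaths also extends life (and therefore accrues extra life-years, QALYs and,
for survivors who remain prevalent, costs).

The modelled population is a closed cohort of everyone aged 19–99 at
baseline; each single-year-of-age/sex cohort is simulated in annual cycles
until age 100. Calendar trends in incidence, case fatality, costs and
intakes are frozen at their baseline values; the intervention effect
persists for life.

Annual cycles convert rates to probabilities with q = 1 − e^(−rate), which
keeps probabilities in [0, 1] for any non-negative rate and makes the
constant-hazard lifetable match its geometric closed form exactly (a unit
test asserts this to 1e-9).

## Exposure pathway

Sodium acts on disease only through systolic blood pressure:

* ΔSBP(a, s) = −β(a, s) · Δc(a, s) / 1000, with β the age/sex-band slope in
  mmHg per 1,000 mg/day and Δc the DRI-group sodium reduction mapped onto
  single ages (ages < 19 receive zero intervention);
* incidence rate ratio = RR₂₀(a, d)^(ΔSBP/20), the log-linear reading of a
  relative risk "per 20 mmHg";
* PIF = 1 − rate ratio (mean-shift mode). A distributional mode that
  averages RR over a discretised intake distribution is retained for
  sensitivity; under log-linear risk and a uniform shift it reduces exactly
  to the mean-shift PIF (asserted to 1e-12).

Because risk is log-linear in SBP, the baseline SBP *level* cancels: only
the shift matters. The SBP input table is still validated and carried (with
the 80+ band filled from the 60–79 value, mirroring the usual survey gap)
so that non-log-linear risk functions could be added without changing the
data contract.

The shipped β and RR₂₀ values are illustrative configuration in the range
reported by blood-pressure meta-analyses (β ≈ 1–3 mmHg per 1,000 mg/day
rising with age; RR₂₀ falling from ~2.0–2.4 at younger adult ages to
~1.3 at 80+, stroke above IHD). They are deliberately not presented as
authoritative estimates; applications should supply their own.

### Scenarios

Ten sodium-reduction scenarios ship by default: reduce-to-target for the
1,500 (AI) and 2,000 (WHO) mg/day recommendations; an absolute 459 mg/day
reduction for fully meeting packaged-food reformulation targets;
proportional reductions of 4.7/6.4/7.8% for FOPL purchase-shift evidence;
and absolute reductions of 73/131/182/259 mg/day for FOPL food-substitution
uptake tiers. Interventions are one-sided: no group's intake is ever
increased. Salt equivalents are reported at 2.5 g salt per g sodium with
decimal half-even rounding at two decimals.

## Case-fatality back-calculation

Case fatality f is identified from the observed (incidence, prevalence,
cause-specific mortality) triple under the three-state model. Two
estimators are provided:

* **direct**: f(a) = cause deaths / prevalent cases, with a small-count
  floor (ages with fewer than 5 prevalent cases borrow from the nearest
  valid age) and ages below 35 replaced by their prevalence-weighted mean
  (the ratio is too unstable in the young; the constancy convention is
  standard);
* **consistency refinement**: starting from the direct estimate, sweeps of
  an age-sequential solve adjust f so that forward-running the three-state
  recursion from age 0 with the observed incidence reproduces the observed
  prevalence. The recursion is triangular in age, so on self-consistent
  data one sweep is exact; sweeps iterate to a residual tolerance
  otherwise, clamping f to non-negative rates, and non-convergence is
  flagged with a warning rather than an exception.

On forward-simulated 1-year data the refinement recovers the generating
rates to machine precision (the recovery test requires ≤ 5% mean absolute
relative error over ages 40–90). The default *pipeline*, however, uses the
direct estimator: after real-world 5-year inputs are interpolated to single
years, the refinement fits year-over-year prevalence differences and
amplifies interpolation wiggle (observed MARE ≈ 56% on the synthetic
roundtrip, versus 2.7–5.4% for the direct estimator). The refinement is
available via `prepare_inputs(..., refine_case_fatality=True)` and is the
right tool when inputs are natively single-year and internally consistent.
No smoothing is applied beyond these rules.

## Age preprocessing

* **Count disaggregation** (5-year groups → single years) interpolates the
  cumulative sum with a monotone cubic (PCHIP) and differences it back:
  outputs are non-negative and every source group's total is conserved
  exactly. Grouped *rates* are first converted to event counts with the
  population, disaggregated, and divided back, preserving group event
  counts. "Temporal disaggregation" names a method family, not an
  algorithm; monotone-cumulative interpolation was chosen because it
  guarantees the two properties that matter downstream.
* **Tail extrapolation** (beyond the last observed group, typically 90+ →
  ages 91–100) fits a polynomial (default order 2, configurable 1–3) to the
  oldest six group midpoints and clamps predictions to [0, 1]. Open-ended
  terminal groups are assigned midpoint lo + 2.5 years — a convention that
  must be fixed somewhere for reproducibility. The fit is exact for
  polynomial inputs of degree ≤ the chosen order.
* **Band expansion** (SBP, cost, utility bands → single years) is
  piecewise-constant with the lower band edge inclusive; age intervals are
  closed [lo, hi].

## Economics

* Costs per prevalent case-year are built the burden-of-illness way:
  attributable direct costs per disease/band, plus unattributable direct
  costs allocated across diseases in proportion to attributable shares
  (the allocation conserves the unattributable total exactly), divided by
  prevalent cases per band, inflated to the analysis year (default factor
  1.17 for 2010→2019 healthcare CPI), and expanded to single years. No
  separate first-year/event cost is modelled; diseases are costed as
  prevalent cases.
* Utility per year = background utility (10-year bands) ×
  Π_d (1 − prev_d · dec_d). Multiplicative combination across diseases is
  the conservative standard; the code structure admits an additive variant.
* Discounting: factor (1 + r)^(−t), t = years since cohort start, year 0
  undiscounted. Default r = 1.5%/year, with 0% and 3% plus 10- and 50-year
  horizons in the sensitivity suite. Prevented incident-case counts are
  reported undiscounted (counts are counts); QALYs and costs are
  discounted.
* Savings are baseline − scenario (positive = saving).

Prevented-case headline counts are the closed sub-model differences,
population-weighted but not netted against other-cause death; at old ages
this counts cases among people who might have died of other causes first,
so it is a slightly generous incident-case convention. QALYs and costs, the
economic outcomes, are fully survivorship-rescaled.

## Monte Carlo uncertainty

Per iteration: RR₂₀ scaled by a log-normal factor per disease (σ_log = 0.10,
floored at RR = 1), SBP slopes by a non-negative normal factor (σ = 0.10),
DRI-group intake means drawn normal around their means with their standard
errors, per-case costs by a unit-mean gamma factor (CV = 0.20), and case
fatality by a log-normal factor per disease (σ_log = 0.10). These are the
parameter groups whose uncertainty dominates in this class of model; the
families and spreads are configuration, and setting every spread to zero
reproduces the deterministic run exactly (asserted bitwise). Intervals are
empirical 2.5th–97.5th percentiles; the point estimate reported alongside
is the deterministic run, with the Monte Carlo mean also emitted. Each
iteration uses an independent substream derived from (seed, iteration), so
results are invariant to execution order. The default is 5,000 iterations;
tests and the acceptance script use 200, which is enough for stable
interval endpoints at the tolerances asserted.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of national inputs: a 37.6-million
population with a Gompertz–Makeham mortality schedule (α + β·e^(γa),
sex-specific), pyramid = stationary shape × 2% log-normal noise,
renormalised to the requested total exactly; disease inputs
forward-simulated from known incidence (zero below 20, linear ramp to 35,
then log-linear with age, capped at 0.05/year) and case fatality (constant
below 35, exponential above); sodium intakes per DRI group rescaled so the
population-weighted mean is exactly 2,758 mg/day, with every group above
2,000 mg/day so the recommendation scenarios bite everywhere; SEs at 2% of
means (usual-intake SE structure is survey-specific, so it is free
configuration); SBP, cost and utility bands as described above.

It does **not** emulate: survey weighting, usual-intake estimation from
recalls, secular trends, comorbidity correlation between IHD and stroke,
regional or socioeconomic heterogeneity, or realistic Canadian marginals
beyond the sodium mean. Passing tests therefore demonstrate that the
*machinery* is correct (conservation, orderings, oracle agreement,
parameter recovery, fixed points), not that the shipped numbers describe
any real population. Headline national estimates require national input
extracts, which are inputs, not code.

## Numerical conventions and degenerate inputs

* Probabilities are never formed by clipping rates: q = 1 − e^(−rate).
* Zero-population or zero-prevalence cells propagate zeros rather than
  NaNs; division guards are explicit, and genuinely contradictory inputs
  (deaths with no prevalence anywhere, unattributable cost with no
  attributable base) raise `ValueError`.
* The null scenario is an exact fixed point: PIF ≡ 0 gives bitwise-zero
  differences for every outcome.
* Cohorts are simulated with numpy across start ages; a full deterministic
  ten-scenario run takes ~0.2 s, so the 200-iteration Monte Carlo used in
  tests completes in a few seconds and the 5,000-iteration default in
  under two minutes on one CPU.

## Known limitations

* Only the SBP-mediated pathway is modelled; effects of sodium on other
  outcomes (kidney disease, gastric cancer) are excluded, so benefits are
  conservative in that respect.
* No comorbid health-state interaction between IHD and stroke beyond the
  shared lifetable.
* Averted deaths' unrelated future healthcare costs are not re-added — a
  known open debate in multi-state lifetable costing; omitting them
  overstates savings slightly.
* Intervention costs and societal (productivity) effects are out of scope;
  outcomes are net healthcare savings, not cost-effectiveness ratios.
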