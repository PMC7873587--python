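# Methods

## The analysis model

The package evaluates sanitation behavior-change programs from a
*societal perspective*: every resource consumed is counted no matter who
paid. Costs are assembled bottom-up from seven categories — three
program categories borne by the implementer (management, training,
facilitation, measured from activity tracking and expenditure review)
and four local categories (local-actor time, community-member time,
hired labor, latrine hardware). Unpaid time enters as hours × a
value-of-time rate derived from local wages. Amounts are nominal USD of
the 2012–2014 study period; no discount rate or inflation adjustment is
applied because the horizon is two years. Internal arithmetic keeps
cent precision; report writers round to whole dollars.

Effectiveness is counted in households, on two measures:

* **stopping open defecation** — a household is classified OD if it
  reports open defecation *or* reports a private latrine that
  observation invalidates (full, unstable flooring, or not observable
  on survey day). Shared and communal latrine use counts as latrine
  use.
* **gaining ownership of a usable latrine** — ownership requires a
  latrine observed on survey day with stable flooring and not full.

The two measures are classified independently (use by report, ownership
by observation), so a household can be an OD-classified owner; the two
published outcome series are likewise independent.

Cost effectiveness is `CE_i = Cost / Outcome_i`, the societal cost of
converting one household, with a per-person variant dividing by mean
household size. The counterfactual is zero change absent the
intervention; no secular-trend adjustment is made. When an outcome
*worsened* the ratio would be negative and misleading, so the result is
carried as a flagged-undefined cell with a note rather than a number or
an exception — reports show blanks and log the reason. ICERs are the
standard Δcost/Δeffect with the dominance quadrants of the CE plane
labeled ("dominant" = cheaper and more effective, etc.).

### Counts from unrounded fractions

Achieving-household counts are derived from unrounded outcome-change
fractions and then rounded half away from zero. This matters for
reproducing printed tables: a printed "−10%" change over 1,624
households would give 162, but the underlying −10.34% gives the printed
count of 168. The bundled fixture therefore stores printed *counts*
alongside the (rounded) printed deltas, and CE is always computed from
counts. Residuals between recomputed and printed CE cells (e.g.
576,061/1,605 = 358.92 vs a printed 358.87) stem from rounding in the
printed inputs and stay below 1% relative; tests compare at that
tolerance and never by string equality.

## Monte Carlo sensitivity analysis

Costs were measured rather than estimated, so each of the seven
categories gets an independent conservative Uniform(center ± 30%)
distribution. Outcome changes get Normal(center, sd) on the
delta-fraction scale; where no empirical SD is available the default is
sd = 50% of |center| (the stated convention where impact-evaluation SDs
were missing; the study's own per-arm SD table was in an unavailable
supplement, so the fallback is the package default for *all* outcome
deltas and any SD can be supplied per parameter). Per draw, total cost
and the achieving-household count are recomputed — drawn delta × n
households, rounded half away from zero like the point-estimate chain,
so with all uncertainty switched off the PSA reproduces the CE point
estimate exactly. The 95% interval is the empirical 2.5th/97.5th
percentile (linear interpolation) of the draws with a positive count,
floored at zero; draws with a non-positive count are excluded from the
percentiles and reported as `fraction_undefined_draws`, the Monte Carlo
analogue of the negative-ratio suppression rule. Parameters are drawn
independently — nothing is asserted about cost–outcome correlation.
Default 1,000 draws; every generator is seeded and a (specs, n_draws,
seed) triple fully determines the result. If *every* draw is undefined
the run errors rather than reporting an empty interval.

Interval overlap between two arms is read as "the simulations do not
indicate that one intervention is more cost effective than the other";
it is a screening heuristic, not a hypothesis test.

## The synthetic generator

`generate_households` emulates the study's regional survey structure:
five regional profiles carry the published baseline margins (usable
latrine ownership 10–98%, OD 27–96%), mean household sizes (3.3–6.4)
and village sizes (29–123 households), with arm-specific effect sizes
taken from the published outcome table. Within a region:

* household size ~ round(Normal(mean, sd)) truncated at 1; the SD is a
  realism choice (≈2 persons, Ethiopia slightly wider) since only means
  were published;
* the OD and ownership margins are independent Bernoulli draws per
  household, then *realized* as survey fields by inverting the
  classifier: latrine-using owners report a private (or, with
  probability `shared_use_fraction`, a shared) latrine with a usable
  latrine observed; OD non-owners report open defecation, except a
  `unusable_fraction` slice who report a private latrine that
  observation invalidates (full, unstable, or unobserved, equally
  likely) — this is where the reclassification rule gets exercised;
  OD owners report open defecation with a usable latrine standing;
* follow-up waves are *panel transitions*, not resampled
  cross-sections: baseline-OD households flip to latrine use with
  probability |ΔOD|/baseline-OD (users flip to OD with probability
  ΔOD/(1−baseline-OD) in worsening regions), and likewise for
  ownership, so the marginal flip probability is exactly |Δ| and the
  empirical deltas are binomially distributed around the profile
  values;
* latrine age is Uniform over the inter-survey window for new
  latrines and older for pre-existing stock (no distribution was
  published; this supports recall-based baseline estimation);
* household spending and time are zero-inflated lognormals
  concentrated on latrine-gaining households, scaled to the profile
  means — right-skewed with many zeros, as household sanitation
  spending is.

An optional `village_icc` parameter adds a Beta-distributed
village-level random effect on the OD margin; the default is zero
because no within-village correlation was published.

What a green synthetic test establishes: the classification, costing,
CE and PSA stages are arithmetically correct and recover known
parameters from data with the study's margins and panel structure. What
it does not establish: anything about survey nonresponse, within-region
spatial structure, measurement error in latrine observation, or
correlated cost/outcome shocks — none of which are modeled.

Region-wide baselines combined with arm-specific deltas can be
infeasible (Oromia's +53% pilot ownership gain on the 51% pooled
baseline); `profile_for` clamps the delta to the feasible range with a
warning rather than inventing per-arm baselines that were never
published.

## Numerical and design choices

* **Rounding of derived counts**: half away from zero (no published
  rule); all count/fraction consistency holds to 0.5/n.
* **Time entries**: ledgers accept either monetized amounts or
  (hours, rate) pairs; when both are present the monetized value wins
  and a mismatch beyond one cent warns, since published tables report
  only monetized values.
* **Aggregation**: category-wise sums; exact additivity of totals and
  permutation invariance are tested properties. Shared program costs
  are allocated evenly across regions in the bundled data (the
  published per-region management splits are equal), but ledgers are
  free-form so any allocation can be supplied.
* **Baseline estimation modes**: measured (two survey waves),
  recall-based (latrine age vs months since intervention start), and
  conservative (baseline OD = follow-up OD + Δownership, clamped to
  [0,1] with a warning). The package never guesses which mode produced
  a given published cell; both are exposed.
* **Suppression is data, not control flow**: undefined CE results and
  all-undefined PSA runs surface as flagged values and logged cells;
  only genuinely invalid inputs (negative costs, unknown practice
  labels, schema violations) raise.
* **Determinism**: all randomness flows through
  `numpy.random.default_rng` seeds; the pipeline derives a stable
  per-(arm, region) PSA stream from the base seed via CRC32 so results
  do not depend on iteration order.

## Limitations

The bundled fixture is the published aggregate table, not raw survey
records; per-household heterogeneity in the reference analysis is
therefore synthetic only. ICER reference values beyond direct
arithmetic on the published columns were in an unavailable supplement,
as were the per-arm outcome SDs. No health-impact extrapolation
(DALYs), benefit-cost ratios, within-household use measurement, or
plotting beyond the CI summary table is provided.
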