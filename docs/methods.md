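# Methods

## Model and assumptions

The engine computes probabilistic steady-state mass balances of one
nanomaterial per scenario over a directed compartment graph covering the
complete product lifecycle and the receiving environment. Key modeling
assumptions:

* **Steady state per reference year.** A constant mass transfer over
  one-year periods; lifetime release from products on the market is folded
  into the sampled release coefficients rather than modeled as explicit
  in-use stock dynamics with delays. The reference year is 2014.
* **Independent sampling.** All inputs (amounts, shares, coefficients) are
  sampled independently; no correlation structure is imposed. Where
  dependence matters physically — outflow fractions of one compartment
  competing for the same mass — it is restored by the normalization step,
  not by correlated sampling.
* **Nano-form specificity.** The balance tracks the nanomaterial, not the
  element. Chemical transformation (e.g. sulfidation of nano-Ag/ZnO during
  sewage treatment) is a transfer into an explicit *elimination*
  compartment, so transformed mass leaves the balance visibly instead of
  disappearing.
* **Landfill and recycling are no-release stores.** Both are explicit sink
  nodes with zero outflow; alternative scenarios can add outflows without
  changing the engine.
* **No within-compartment fate.** Dissolution kinetics,
  aggregation-dependent settling and similar processes are out of scope;
  sedimentation and atmospheric settling enter only as transfer-coefficient
  distributions.

## Input distributions

Six families cover the inputs encountered in practice: `point`,
`uniform(lower, upper)` (data-poor min–max ranges),
`triangular(lower, mode, upper)` (expert best guess with bounds),
`normal_truncated(mean, sd)` (truncated at 0), `lognormal(mu, sigma)`
(skewed production data), and `expert_mixture` (equally weighted
components for divergent expert opinions). Supports are nonnegative by
construction; a distribution used as a transfer coefficient must have
support within [0, 1] (so the unbounded families are rejected there by
validation). One seeded `numpy.random.Generator` is threaded through the
whole pipeline and the seed is recorded in the run manifest.

## Outflow normalization

Independently sampled outflow fractions of an origin rarely sum to one.
Per origin and iteration: if the draws sum above 1, each is divided by the
sum (relative magnitudes preserved; rejection sampling would bias the
marginals); if below 1, the deficit goes to the origin's configured
*residual* compartment. The residual may be any distinct compartment, not
only a terminal one: "remainder" pathways between flow-through
compartments (STP → effluent, freshwater → seawater) are exactly the
dominant routes one wants as residuals, because expressing them as
`1 − Σ(explicit draws)` keeps the physical coupling between competing
fractions. A side effect worth knowing: when explicit draws can sum above
1 (e.g. sludge 0.85–0.97 plus elimination 0–0.05), the residual acquires a
point mass at exactly 0; the summary statistics handle such atoms
explicitly.

## Solver

Production path: direct dense solve of (I − Tᵀ)m = u per iteration,
batched over iterations in chunks of 20,000 (~20 compartments → ~300 MB
peak, ~2 s for 10⁵ iterations on one CPU). A spectral-radius check on T
rejects total-retention cycles with an error naming the strongly connected
compartments. A Jacobi fixed-point iteration (m ← u + Tᵀm, relative
tolerance 1e−10, max 10,000 sweeps) is retained purely as an independent
test oracle; the two paths agree to <1e−8 relative on randomized cyclic
systems. Round-off negatives below 1e−9 of scale are clipped to zero;
larger negativity is an error, not a warning.

## Concentrations and units

Internal mass-flow unit is t/y. Concentration units are `<mass>/<amount>`
strings (mass t…pg; amount L, m³ or kg); conversion factors are exact
powers of ten, so L↔m³ and t→µg round-trips are exact to machine
precision. Flow-through compartments: concentration = annual inflow ÷
annual throughput (volume or mass), with the throughput itself a sampled
distribution. Sinks: annual inflow ÷ stock mass = yearly increase; the
accumulated 2000–2014 value multiplies the 2014 increase by
Σₖ₌₁¹⁵ k/15 = 8 (linear deposition ramp from (1/15)·D in 2000 to D in
2014 — the endpoint choice that makes the 2014 deposition equal the
modeled 2014 release exactly). A constant-rate ramp (factor 15) is kept as
a sensitivity variant. Whether a water body's geometry is a static volume
or an annual exchange volume is a configuration choice; the synthetic
scenarios use annual throughput, flagged in the output basis column.

## Summary statistics

Reported per quantity: modal value, empirical 2.5%/97.5% quantiles
(linear interpolation between order statistics), and the fraction of
exactly-zero samples. Rounding for publication tables is to two
significant digits, half-to-even.

Mode estimation: if more than half the samples are exactly 0 the mode is
0 (transformation-dominated pathways genuinely are most probably zero).
Otherwise the positive samples are histogrammed with bins equal-width in
log10 (Freedman–Diaconis width), each bin's density *in linear units*
(count ÷ linear width) is computed, and the estimate is the
density-weighted geometric center of all bins within 90% of the peak
density. Two deliberate choices: (1) the linear-density correction — the
count-densest log bin estimates the mode of log X, i.e. the median of X,
which for lognormal(0,1) is 1 rather than the true mode e^(−σ²)=0.368;
(2) averaging the near-maximal region — FD bins are far narrower than the
flat top of these heavy-tailed densities, so a single-bin argmax wanders
by several bin widths under multinomial noise, while the region center is
stable (benchmarked at n=10⁵ on lognormal(0,1): max error 0.028 versus
excursions beyond 0.1 for the raw argmax).

One consequence to read correctly: for flows downstream of a
zero-to-complete sedimentation coefficient the linear density peaks near
the lower support edge, so the mode can fall *below* the 2.5% quantile.
The mode is a density peak, not a central quantile; both are reported.

Source/receiver share tables divide each receiver's modal inflows by
their sum, so shares add to 100% before rounding. The archetype-contract
shares (below) instead summarize per-iteration share samples with the
modal estimator — the appropriate statistic for "most frequently modeled
routing".

## Synthetic scenarios

The five archetypes share one 23-compartment Denmark-plausible backbone
and differ in production magnitude and use-phase routing:

| archetype | production (t/y) | dominant use-phase route |
|---|---|---|
| cosmetics_dominated | triangular(20, 60, 200) | wastewater (residual, ~0.66–0.92) |
| composite_dominated | triangular(0.5, 2, 10) | recycling 0.25–0.40, incineration 0.30–0.45, rest landfill |
| wood_preservative | triangular(5, 15, 40) | soils 0.05–0.13 direct; bulk to waste wood routes |
| tire_wear | uniform(1000, 3000) | runoff to freshwater/soils; recycling + incineration |
| low_volume_electronics | uniform(0.001, 0.05) | collection/recycling; ≤1e−4 to wastewater |

Fixed structural conventions: STP removes 85–97% of particles to sludge
(0–5% eliminated, remainder to effluent); the incinerator retains mineral
particles almost completely in bottom/fly ash (stack release 1e−4–1e−3)
and destroys carbon-based ones (combustion as elimination, ashes 0.5–2%
each); sedimentation is uniform(0, 1) — the full spectrum from none to
complete; atmospheric settling removes ~93% to surfaces split by area
share, the rest advected out. Geometries: effluent 6–8×10¹¹ L/y, sludge
1.1–1.5×10⁸ kg/y dry, incinerated waste 3.0–3.8×10⁹ kg/y, freshwater
1–3×10¹³ L/y, marine exchange 1–5×10¹⁴ L/y, air mixing 0.5–2×10¹⁵ m³/y,
soil stocks 2×10¹¹–7×10¹² kg, sediment stocks 10⁹–5×10¹⁰ kg. These
magnitudes are order-of-magnitude national statistics, chosen once so
outputs land in interpretable unit ranges; configs carry a `synthetic`
provenance tag.

What the generator does *not* emulate: real survey-derived allocation
between dozens of product categories, correlated parameter knowledge,
material-specific elimination chemistry beyond the combustible/mineral
split, and any particular published concentration values. Passing tests
therefore demonstrate engine correctness and structural plausibility of
the synthetic conditions — not agreement with any specific national
assessment. Transcribing a real parameter set into the scenario schema is
supported (it is just a YAML file) but no such data ships with the
package.

## Problem sizes and runtime

Default pipeline runs use 10⁵ iterations (≈3 s for a 23-compartment
archetype including summaries). The test suite uses 10⁵ draws for
distribution-recovery checks, 10³–10⁴ iterations for conservation and
archetype-contract checks, and 4 seeds × 4×10³ iterations per archetype
for the twin-recovery property; the analysis drivers default to 2×10⁴
iterations. These sizes were chosen as the smallest that leave the checked
statistics' Monte-Carlo wobble an order of magnitude below the asserted
tolerances.

## Known limitations

* Steady-state only: no multi-year stock-and-flow dynamics, no product
  lifetime distributions, no landfill leachate.
* Independence of inputs may understate tail widths where real parameters
  co-vary (e.g. production volume and release factor).
* The accumulated sink concentrations inherit the linearity of the ramp
  assumption; any other growth history just rescales the factor 8.
* Modal values of near-edge-peaked distributions are sensitive to the
  lower support region; report them together with the 95% range, never
  alone.
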