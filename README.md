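# nanomfa

Probabilistic material flow analysis (MFA) and predicted environmental
concentrations (PEC) for engineered nanomaterials (ENM).

Environmental risk assessment of nanomaterials — nano-TiO₂ in sunscreens,
carbon nanotubes in composites, micronized copper in treated wood, carbon
black in tires — needs exposure concentrations, but trace-analytical
measurement of nanoparticles in the environment is not yet possible.
Exposure must therefore be modeled: the mass of a material is tracked
through the whole lifecycle of the products containing it (production →
manufacturing → use → wastewater treatment, incineration, recycling,
landfill) into the environmental compartments (freshwater, seawater, their
sediments, soils, air), with every input — production volume, allocation
shares, transfer coefficients — treated as a probability distribution
rather than a point estimate.

This package is for exposure modelers and ecotoxicologists who need
distributional PEC estimates, and for anyone building national-scale
substance flow models with quantified uncertainty.

## Model

A scenario is a directed compartment graph. Sources receive external
input (t/y), flow-through compartments pass their mass on within the year,
and terminal compartments absorb it: accumulating sinks (soils, sediments,
landfill), elimination (chemical transformation of the nano-form, e.g.
sulfidation in sewage treatment), and export. Each edge carries a transfer
coefficient distribution on [0, 1].

One Monte-Carlo iteration draws every input and coefficient, normalizes
each compartment's outflow fractions to sum to one (proportional
renormalization above one; a configured residual pathway receives any
deficit), and solves the steady-state balance

    m = u + Tᵀ m        ⇔        (I − Tᵀ) m = u

for the throughput vector m given inputs u and coefficient matrix T.
Recycling loops are fine as long as they leak (spectral radius < 1). Edge
flows are mᵢ·Tᵢⱼ; mass is conserved exactly on every iteration. The
default 100,000 iterations yield full flow and concentration
distributions, summarized the way exposure assessments report them: the
modal (most probable) value and the 2.5–97.5% range.

Concentrations: flow-through compartments divide annual inflow by annual
throughput (µg/L, mg/kg, ng/m³...); sinks divide by stock mass to get a
yearly increase, and a linear deposition ramp over the 2000–2014 release
period accumulates Σₖ₌₁¹⁵ (k/15)·D = 8·D for a 2014 annual increase D.

Because real parameterizations are survey-based, a synthetic generator
provides five archetypal lifecycles (`cosmetics_dominated`,
`composite_dominated`, `wood_preservative`, `tire_wear`,
`low_volume_electronics`) with Denmark-plausible compartment geometries —
structurally faithful stand-ins, not survey numbers (see
`docs/methods.md`).

## Worked example

```sh
nanomfa synth --archetype cosmetics_dominated --seed 1 --out scenario.yaml
nanomfa run --scenario scenario.yaml --n-iter 100000 --seed 2 --out run/
```

`run/flows.csv` then holds per-edge modal flows with 95% intervals,
`run/concentrations.csv` the concentration summaries, e.g. (seed 1 run,
rounded to two significant digits):

```
compartment          basis                  unit    mode   q025   q975
sludge               annual_flowthrough     mg/kg   310    150    870
freshwater           annual_flowthrough     ng/L    180    62     1000
sludge_treated_soil  accumulated_2000_2014  µg/kg   160    76     480
```

Read: for a cosmetics-type material with ~20–200 t/y consumption, sewage
sludge most probably carries ~310 mg/kg (95% range 150–870); soils
receiving that sludge have most probably accumulated ~160 µg/kg over
2000–2014. A `manifest.json` (seed, iteration count, config hash) makes
every table reproducible bit-for-bit.

The same steps as a scripted narrative live under `analysis/`:
`01_generate_scenarios.py` → `02_run_monte_carlo.py` →
`03_concentration_tables.py` → `04_source_receiver_shares.py`, writing
collated tables under `results/`.

In Python:

```python
from nanomfa import solve_steady_state

sol = solve_steady_state(
    {"use": 100.0},
    {("use", "stp"): 1.0, ("stp", "sludge"): 0.9, ("stp", "effluent"): 0.1},
)
sol.edge_flows[("stp", "sludge")]   # 90.0 t/y
sol.edge_flows[("stp", "effluent")] # 10.0 t/y
```

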