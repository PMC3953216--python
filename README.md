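# spanflow

Spatially explicit ecosystem-service assessment for researchers and
analysts who need more than a supply map: **who** benefits, **how much**
of the service actually reaches them, and **where** it is lost on the way.

Most rapid assessment methods stop at *potential* supply. `spanflow`
models each benefit as a spatio-temporal flow of a *service carrier*
(water, sediment, scenic information, CO₂) from **source** regions,
past **sink** regions that absorb it, to **use** regions where
beneficiaries demand it. Demand may be *rival* (each user depletes the
carrier) or *non-rival* (a view enjoyed by many); a benefit may be
*provisioning* (carrier contact is good: drinking water) or *preventive*
(carrier contact is harm and sinks supply the benefit: flood or sediment
regulation).

## The model

Every simulation runs the router twice — a **possible** pass with all
sink capacities forced to zero and an **actual** pass with sinks active —
and assembles the full output-map taxonomy by subtraction:

| map | meaning |
|---|---|
| theoretical source/sink/use | in-situ supply, absorption capacity, demand — no flow |
| possible source/use/flow | what flow paths can deliver, ignoring sinks |
| actual source/sink/use/flow | delivery with sinks and flows active |
| blocked X = possible X − actual X | flow stopped by sinks |
| inaccessible X = theoretical X − possible/actual X | supply or demand with no flow connection |

Four routers cover the common carrier classes: `d8_downslope`
(single-direction steepest-descent hydrologic routing, one sweep in
topological order with sink-then-use processing per cell),
`line_of_sight` (terrain-interpolated visibility with sink attenuation),
`access_cost` (8-connected least-cost access with cost-ordered rival
allocation), and `global_mix` (a well-mixed global pool).

Around the flow core:

* **Production functions** — discrete Bayesian networks with exact
  variable-elimination inference, additive-smoothing CPT training, and
  per-cell spatial application; results are paired value/uncertainty maps
  (coefficient of variation for numeric nodes, Shannon diversity −Σp ln p
  for categorical ones).
* **Hybrid erosion** — soil loss A = R·K·LS·C·P on gentle slopes and a
  probabilistic steep-slope network strictly above a 20 % slope
  threshold, fused into one seamless per-cell distribution.
* **Monte-Carlo propagation** — seeded joint draws of probabilistic
  source/sink/use layers through the flow model, yielding mean and CV
  maps for every output.
* **Model assembly** — multi-criteria ranking of candidate datasets and
  models (semantic and scale specificity, resolution, semantic distance,
  currency, user rank — default 50), recursive concept resolution with
  spatial predicate partitions, scenario overrides, and JSON provenance.

## Worked example

```python
from spanflow import BenefitSpec, LandscapeSpec, make_span_case, run_span, sustainability_sweep

benefit = BenefitSpec("provisioning", "rival", "water", "m3/yr")
problem, _ = make_span_case(LandscapeSpec(seed=11, n_rows=16, n_cols=16), benefit)
outputs = run_span(problem)
print(outputs.totals())
sweep = sustainability_sweep(problem, [1.0, 2.0, 5.0, 10.0, 20.0])
print(sweep)
```

Running `python examples/03_water_flow_span.py` (the same computation)
prints:

```
theoretical source (in-situ supply):         380 m3/yr
theoretical use (in-situ demand):           1132 m3/yr
possible use (flows, sinks off):             170 m3/yr
actual use (flows and sinks):                 27 m3/yr
blocked use (lost to sinks):                 143 m3/yr
inaccessible use (no flow connection):       962 m3/yr
carrier exported at terminals:               195 m3/yr

demand sweep: current need 1132, supply ceiling 222 -> ratio 20%
```

Reading: of 1132 m³/yr demanded, only 170 even has a flow path from a
source (the rest is *inaccessible*), sinks absorb 143 of that
(*blocked*), and 27 is actually delivered. Scaling demand shows the
landscape could deliver at most 222 m³/yr — a sustainability ratio of
20 % of current need. A ratio near 100 % means demand is barely met;
far above it means headroom for growth.

The other scripts in `examples/` each demonstrate one capability:
terrain and grid I/O, Bayesian production functions, scenic/access
routing, hybrid erosion, and uncertainty propagation plus model assembly.

## Command line

```sh
spanflow synth --seed 3 --out case/          # synthetic case directory
spanflow run --problem case/problem.yaml --out out/
spanflow sweep --problem case/problem.yaml --multipliers 1,2,5,10
spanflow mc --problem case/problem.yaml --draws 200 --seed 1 --spread 0.2 --out mc/
spanflow resolve --registry registry.yaml --concept water-supply
spanflow compare --base out/ --alt growth=alt/ --out table.csv
```

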