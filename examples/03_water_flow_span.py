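"""Route a rival provisioning carrier (water) downslope from sources
through sinks to users and read the full output-map taxonomy, then sweep
demand to find the sustainability ceiling."""

from spanflow import BenefitSpec, LandscapeSpec, make_span_case, run_span, sustainability_sweep

benefit = BenefitSpec("provisioning", "rival", "water", "m3/yr")
problem, expected = make_span_case(LandscapeSpec(seed=11, n_rows=16, n_cols=16),
                                   benefit)
outputs = run_span(problem)
totals = outputs.totals()

print("theoretical source (in-situ supply):  "
      f"{totals['theoretical_source']:10.0f} m3/yr")
print("theoretical use (in-situ demand):     "
      f"{totals['theoretical_use']:10.0f} m3/yr")
print("possible use (flows, sinks off):      "
      f"{totals['possible_use']:10.0f} m3/yr")
print("actual use (flows and sinks):         "
      f"{totals['actual_use']:10.0f} m3/yr")
print("blocked use (lost to sinks):          "
      f"{totals['blocked_use']:10.0f} m3/yr")
print("inaccessible use (no flow connection):"
      f"{totals['inaccessible_use']:10.0f} m3/yr")
print("carrier exported at terminals:        "
      f"{outputs.run_log['exported_actual']:10.0f} m3/yr")

sweep = sustainability_sweep(problem, [1.0, 2.0, 5.0, 10.0, 20.0])
print(f"\ndemand sweep: current need {sweep.current_need:.0f}, supply "
      f"ceiling {sweep.max_potential:.0f} -> ratio {sweep.ratio}%")
print("a ratio near 100% means demand is barely met; far above means "
      "ample headroom for growth")
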