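"""Breath-by-breath analysis of a simulated analyzer trace.

Detects breaths from the CO2/O2 record alone (no access to ground truth),
extracts inspired and end-tidal values, and converts end-tidal CO2 to
partial pressure.
"""

from co2challenge import (
    analyze_trace,
    build_default_protocol,
    simulate_closed_loop,
    to_partial_pressure,
)
from co2challenge.presets import preset

protocol = build_default_protocol()
scenario, circuit, controller = preset("subject_additional")
result = simulate_closed_loop(protocol, scenario, circuit, controller, seed=1)

records = analyze_trace(result.trace, mode="spontaneous", system="additional")
print(f"detected {len(records)} breaths from the trace "
      f"(simulator truth: {len(result.breaths)})")

baseline = records[records.t_s < 60]
print(f"initial baseline: inspired CO2 {baseline.insp_co2_mean.mean():.3f} %, "
      f"end-tidal CO2 {baseline.et_co2.mean():.2f} % "
      f"(= {to_partial_pressure(baseline.et_co2.mean()):.1f} mmHg)")

box5 = records[(records.t_s > 265) & (records.t_s < 288)]
print(f"5 % box: inspired CO2 {box5.insp_co2_mean.mean():.2f} %, "
      f"end-tidal {box5.et_co2.mean():.2f} % -- the alveolar level tracks the stimulus")
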