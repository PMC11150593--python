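"""The flow-proportional admixture controller in numbers.

Mixing a measured respiratory gas flow with a proportional stream of pure
CO2 sets the inspired fraction exactly; the same arithmetic predicts the
unavoidable O2 dilution and the safety clamp resolves conflicts with the
19 % inspired-O2 floor by reducing the CO2 target.
"""

from co2challenge import (
    AIR,
    FlowSample,
    GasFractions,
    additional_flow_ratio,
    clamp_target,
    reservoir_setpoints,
    resulting_fo2i,
    setpoint_from_flow,
)

ratio = additional_flow_ratio(0.05, AIR, additional_fco2=1.0)
print(f"5 % target from CO2-free air with pure CO2: ratio M_add/M_res = {ratio:.6f} (= 1/19)")
print(f"  at 8 L/min sensed flow the CO2 setpoint is {setpoint_from_flow(FlowSample(0, 8.0), ratio):.4f} L/min")
print(f"  inspired O2 drops from 20.9 % to {100 * resulting_fo2i(AIR.fo2, ratio):.3f} %")

lean = GasFractions(fco2=0.0, fo2=0.20)
print(f"with a 20.0 % O2 carrier the same target gives "
      f"{100 * resulting_fo2i(lean.fo2, ratio):.1f} % inspired O2 -- exactly the safety floor")

print(f"a 6 % request is clamped to {100 * clamp_target(0.06, AIR):.1f} % (hard 5 % ceiling)")

sp = reservoir_setpoints(GasFractions(fco2=0.05, fo2=0.21), total_flow=8.0)
print(f"reservoir reference blender, 5 % CO2 / 21 % O2 at 8 L/min: "
      f"O2 {sp.q_o2:.2f} + CO2 {sp.q_co2:.2f} + N2 {sp.q_n2:.2f} = {sp.total:.2f} L/min")
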