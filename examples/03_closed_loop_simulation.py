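"""One closed-loop run: spontaneous subject, admixture system.

Simulates the full default protocol, then reads the ground-truth channel:
delivered inspired CO2 during the 5 % box, the chemoreflex-driven rise in
breathing rate, and the alveolar (end-tidal) response.
"""

from co2challenge import build_default_protocol, simulate_closed_loop
from co2challenge.presets import preset

protocol = build_default_protocol()
scenario, circuit, controller = preset("subject_additional")
result = simulate_closed_loop(protocol, scenario, circuit, controller, seed=1)

print(f"trace: {len(result.trace)} analyzer samples at 60 Hz, "
      f"{len(result.breaths)} breaths in {protocol.duration:.0f} s")

b = result.breaths
box5 = b[(b.t_start > 255) & (b.t_start < 282)]
print(f"5 % box plateau: delivered inspired CO2 {box5.delivered_co2_percent.mean():.2f} % "
      "(the 2 L/min actuator cap trims the peaks of reflex-deepened breaths)")
print(f"breathing rate: {b.rate_bpm.min():.1f} -> {b.rate_bpm.max():.1f} /min "
      "(CO2 chemoreflex)")

truth = result.truth
print(f"alveolar CO2: {truth.alv_co2_percent.iloc[0]:.2f} % at rest, "
      f"{truth.alv_co2_percent.max():.2f} % peak during the challenge")
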