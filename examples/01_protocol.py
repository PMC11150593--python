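"""Build, inspect and serialize the standard inspired-CO2 target function.

The default protocol is the ~9 min assessment sequence: three 45 s boxes
(1, 3, 5 %), a 60 s ramp to 5 % and a 60 s half-sinusoid peaking at 5 %,
separated by baselines.
"""

from pathlib import Path

from co2challenge import build_default_protocol, read_protocol, target_fco2i_at, write_protocol

protocol = build_default_protocol()
print(f"protocol {protocol.name!r}: {len(protocol.segments)} segments, "
      f"{protocol.duration:.0f} s total ({protocol.duration / 60:.2f} min)")

for t in (0.0, 70.0, 170.0, 250.0, 360.0, 465.0):
    print(f"  target at t={t:5.0f} s : {100 * target_fco2i_at(protocol, t):.2f} % CO2")

print(f"  time-integral of the target: {protocol.integral():.4f} fraction*s "
      "(box + ramp + half-sine areas)")

path = Path("scratch_protocol.json")
write_protocol(protocol, path)
assert read_protocol(path) == protocol
path.unlink()
print("  JSON round trip: exact")
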