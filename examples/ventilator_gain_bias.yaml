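# Volume-control test-lung run with a biased flow sensor (see README).
# Usage: co2challenge simulate --config examples/ventilator_gain_bias.yaml \
#            --seed 1 --out run/
scenario:
  kind: ventilator
  settings: {mode: volume_control, tidal_volume: 500, t_insp: 1.5, rate: 12}
  mechanics: {compliance: 40, resistance: 5, frc: 2000, dead_space: 100}
circuit:
  inlet_position: near_flow_sensor
  mixing_volume: 300
  transport_volume: 400
  analyzer_noise_sd: 0.05
controller:
  system: additional
  additional_fco2_percent: 100
  sensor_gain: 0.93
  setpoint_cap_lpm: 2.0
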