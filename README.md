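# co2challenge

Toolkit for **inspired-CO₂ gas challenges**: stimulus-protocol definition,
flow-proportional CO₂ admixture control, a closed-loop respiratory
simulator, and fully automated breath-by-breath analysis of gas-analyzer
traces with per-stimulus target-accuracy metrics.

## Background

Cerebrovascular-reactivity (CVR) imaging measures the change in cerebral
blood flow per unit of a controlled vasoactive stimulus, most commonly a
step in the fractional CO₂ concentration of the inspired gas (FCO₂i).
Classical delivery systems pre-mix O₂/CO₂/N₂ into a breathing reservoir,
which is hard to reconcile with the one-way valves of a mechanical
ventilator. The *additional-CO₂* approach instead measures the respiratory
gas flow and injects a proportional stream of concentrated CO₂ into the
inspiratory limb. For a target FCO₂i `T`, respiratory-gas CO₂ fraction
`c` and additional-gas CO₂ fraction `a`, the two-stream mass balance

```
T = (c·Ṁres + a·Ṁadd) / (Ṁres + Ṁadd)   ⇒   Ṁadd/Ṁres = (T − c) / (a − T)
```

fixes the admixture ratio; the mixed fraction is then independent of the
flow waveform, which is what makes the method work identically in
mechanical ventilation and spontaneous breathing. Since the added gas is
O₂-free, inspired O₂ is diluted by `1/(1 + Ṁadd/Ṁres)`; safety limits cap
FCO₂i at 5 % and floor FO₂i at 19 %, resolving conflicts by reducing the
CO₂ target.

The alveolar (≈ end-tidal) response follows the steady-state gas
relations `FO₂A = FO₂i − V̇O₂/V̇A` and `FCO₂A = FCO₂i + V̇CO₂/V̇A`, with
partial pressures `P = F·(Patm − PH₂O)` (760 / 47 mmHg).

The package provides, as importable modules and a thin CLI:

- `protocol` — piecewise FCO₂i target functions (baseline / box / ramp /
  half-sine), JSON (de)serialization, safety clamping, and the standard
  555 s assessment protocol;
- `controller` — admixture ratio, O₂-dilution arithmetic, per-sample
  mass-flow setpoints, and the three-gas reservoir reference blender;
- `simulator` — a seeded closed-loop simulator: ventilator (volume/pressure
  control) or chemoreflex-driven spontaneous breathing, circuit transport
  with configurable inlet placement, a dynamic alveolar compartment, and a
  60 Hz gas analyzer with first-order response, sampling delay and noise;
- `breath_analysis` — breath detection from the CO₂/O₂ trace, inspired
  peak/baseline/mean and end-tidal extraction, alignment, 5 s binning and
  bootstrap confidence intervals across runs;
- `metrics` — per-stimulus mean target deviation with transition removal
  (boxes lose their first 10 s and last 5 s, ramps their last 5 s);
- `workflows` — the end-to-end accuracy studies.

## Worked example

```python
from co2challenge.workflows import subject_accuracy_study

study = subject_accuracy_study(seeds=(1, 2, 3, 4, 5, 6), noise_sd=0.05)
print(study.report.entries[["stimulus", "signed_mean_pp", "abs_mean_pp", "n"]])
print(f"max |deviation| over stimuli: {study.report.overall_max_abs_pp:.3f} pp")
```

prints (abridged)

```
   stimulus    signed_mean_pp  abs_mean_pp   n
   box_1pct             0.024        0.024   6
   box_3pct             0.023        0.023   6
   box_5pct            -0.250        0.250   6
     ramp_1            -0.007        0.034  11
half_sine_1            -0.019        0.060  12
max |deviation| over stimuli: 0.250 pp
```

Six simulated subjects breathe through the default ~9 min protocol while
the controller injects CO₂ in proportion to the sensed flow; the traces
are segmented into breaths, inspired values are binned into 5 s bins and
compared with the target after transition removal. Every stimulus is hit
to better than 0.4 percentage points; the largest deviation sits in the
5 % box, where the 2 L/min actuator cap trims the peaks of
chemoreflex-deepened breaths. A flow sensor that under-reads by a factor
0.93 instead produces a steady undershoot matching the closed form
`100·(0.05 − rg/(1+rg)) = 0.334 pp` (see `examples/05_target_accuracy.py`).

The `examples/` directory holds one short narrative script per capability;
the same pipelines are scriptable from the shell:

```sh
co2challenge simulate --preset subject_additional --seed 1 --out run/
co2challenge analyze run/trace.csv --mode spontaneous --out run/
co2challenge report run/aggregate.csv --bound-pp 0.4
```

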