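# Methods

This note documents the models behind `co2challenge`, the defaults and why
they were chosen, the numerical choices, and what the synthetic studies do
and do not demonstrate.

## Units and conventions

Gas concentrations are dimensionless volume fractions everywhere inside
the library; files, configuration and printed output use volume percent.
Flows are L/min at the interfaces and L/s internally; volumes are mL.
Time is continuous seconds from protocol start, and protocol segments are
half-open `[start, end)` so the target function is single-valued at joins.
Partial pressures use `P = F·(Patm − PH₂O)` with 760 and 47 mmHg
(95.06 kPa dry-gas pressure at body temperature).

## Stimulus protocols

A protocol is an ordered list of segments: `baseline` (target 0), `box`
(constant plateau), `ramp` (linear from a start level, default 0, to an
end level) and `half_sine` (the first half period of a sinusoid, so a
60 s segment implies a 120 s full period). The standard assessment
protocol is 60 s baseline; 45 s boxes at 1, 3, 5 % with 45 s baselines
between; a 60 s ramp 0→5 %; a 60 s half-sine peaking at 5 %; and a final
60 s baseline — 555 s in all, 11 segments.

Safety clamping caps any target at 5 % CO₂ and enforces a 19 % inspired-O₂
floor. Because the additional gas carries no O₂, the only way to honour
the floor is to reduce the CO₂ target: the largest admissible target
against a carrier with CO₂ fraction `c`, O₂ fraction `f` and additional
gas concentration `a` is `a − 0.19·(a − c)/f`. Over-limit protocols are
clamped with a logged warning rather than refused, so a run never aborts
mid-acquisition.

## Admixture controller

The two-stream mass balance gives the admixture ratio
`r = (T − c)/(a − T)`; remixing at `r` reproduces `T` exactly, which the
tests assert to machine precision. The per-sample actuator setpoint is
`r · g · Q` for sensed flow `Q` and sensor gain `g`, capped at 2 L/min (a
bounded actuator protects against corrupt flow samples) and zero for
non-positive flow (expiration). The gain parameter models a flow-sensor
calibration bias — a sensor calibrated on turbulent flow under-reads
laminar ventilator flow — and shifts the delivered plateau to
`rg/(1+rg)`, an undershoot of 0.334 pp at `g = 0.93` on a 5 % box.

The reservoir reference system blends O₂/CO₂/N₂ at fixed fractions of a
total fresh-gas flow (default 8 L/min, about the upper end of resting
adult minute ventilation, so gas use is comparable to the admixture
method's).

## Closed-loop simulator

Fixed-step explicit integration, default `dt = 10 ms`, one seeded
generator per run (seed echoed in the result), bit-identical traces for
identical seeds.

**Flow sources.** Volume control delivers `VT/Tinsp` of respiratory gas at
constant flow — injected CO₂ adds on top, so the delivered volume grows by
`(1+rg)`. Pressure control and the spontaneous subject fix the *total*
inspiratory flow — `(Pinsp/R)·exp(−τ/RC)` and a half-sinusoid of the
demanded tidal volume respectively — with the flow sensor upstream of the
inlet, so respiratory flow is `Qtotal/(1+rg)` and tidal volume is
unaffected by admixture. Expiration is passive first-order emptying of
the lung volume (time constant `R·C` for the lung, a quarter of the
expiratory time for the subject).

**Chemoreflex.** The subject scales alveolar ventilation by
`max(0, 1 + G·ΔPCO₂A)` (kPa), applied to breathing rate at constant tidal
volume, re-evaluated at each breath onset. The default gain
`G = 0.3 /kPa` is a modelling choice in the range of resting human
hypercapnic ventilatory responses, not a measured value; defaults
(VT 500 mL, 14 /min, VD 150 mL, FRC 3 L, V̇O₂ 0.25, V̇CO₂ 0.20 L/min) give a
resting end-tidal CO₂ of ≈ 4.1 % (29 mmHg) and roughly double ventilation
during a sustained 5 % challenge.

**Circuit.** Injected gas is advected through up to two well-mixed
compartments in series — the humidifier (default 300 mL; the physical
part's size is unspecified, the default is config-exposed) and the tubing
between inlet and sampling port (default 400 mL). With the inlet near the
flow sensor (ventilator circuit) both volumes lie between injection and
airway, producing the slow rise of inspired CO₂; with the inlet near the
sampling port (subject circuit) the mixture appears at the airway within
one step. Well-mixed compartments rather than full advection: they
capture the rise-time ordering with two parameters and keep the
integrator unconditionally stable at `k = Q·dt/V ≤ 1`.

**Alveolar compartment.** One well-mixed store of volume FRC:
`d(FA)/dt = [V̇A·(Fi − FA) ± V̇gas]/FRC`, whose fixed point is the steady
state relation `FO₂A = FO₂i − V̇O₂/V̇A`, `FCO₂A = FCO₂i + V̇CO₂/V̇A`. In the
loop, ventilation acts only while inspiratory flow runs
(`V̇A_inst = Qtotal·(1 − VD/VT)`), metabolism continuously; the cycle mean
converges to the algebraic steady state and the isolated ODE converges to
it within 1e-6. Test-lung runs set V̇O₂ = V̇CO₂ = 0, so expired gas equals
inspired after washout. Anatomical dead space is modelled for the
capnogram: the first VD of expired volume carries the last-inspired gas,
then alveolar gas follows.

**Reservoir arm.** The reservoir is a 700 mL plug-flow column refilled at
the fresh-gas flow; a breath that outruns the stored mixture entrains room
air, which reproduces the late-inspiration CO₂ declines seen when the
chemoreflex pushes minute ventilation above 8 L/min. The mixture
composition relaxes toward the blender setpoint with the column's
turnover time.

**Analyzer.** The sampling port sees inspired gas during inspiration and
expired gas during expiration. Its reading passes a first-order response
(default 0.2 s, a typical sidestream figure; also the source of the
exponential phase transitions the detector exploits), a pure 3 s sampling
delay, uniform 60 Hz resampling, and additive Gaussian noise (default SD
0.05 pp — small against the 0.4 pp accuracy scale and plausible for a
sidestream analyzer). The sensed-flow channel is recorded without delay.

## Breath analysis

Detection thresholds a lightly median-smoothed signal at the midpoint of a
rolling 10 s min/max. Ventilated traces are segmented on CO₂.
Spontaneous traces are segmented on **O₂**: expired gas is always O₂-poor
by `V̇O₂/V̇A`, whereas the CO₂ contrast collapses and briefly inverts
whenever a stimulus drives the inspired level through the alveolar level
(early in each box). Candidate expirations must last ≥ 0.5 s and show a
local CO₂ *or* O₂ excursion ≥ 0.3 pp; in spontaneous mode each must also
pass an exponential-shape test on the inspiratory O₂ rebound (log-linear
fit up to the rebound peak, R² ≥ 0.5), which rejects threshold-crossing
artifacts. The original analyses of this kind were semi-automated with
manual review; this implementation is fully automated, and the shape test
is a constructed stand-in for such a step, not a reimplementation of any
particular script.

Inspired windows are the gaps between accepted expirations with both
edges stripped to within 10 % of the window floor (threshold crossings
sit mid-transition, so raw windows start on the end-tidal decay and may
end on the next rise). Reservoir-system traces first keep only the early
50 % of the inspiration — late declines are dead-space-bound gas and are
deliberately ignored — and strip edges within that early window. Peak and
baseline are the smoothed extrema; the unsmoothed window mean is the
representative inspired value (extrema of noisy samples are order-statistic
biased, means are not). End-tidal values are the median of the last
100 ms of the expiratory CO₂ plateau, located by walking back from the
detected phase edge. Records are timestamped at the centre of the
inspired window.

Alignment: ventilated series are shifted 8 s toward zero (3 s sampling
delay plus several breaths of circuit dead-space transport); spontaneous
series apply no shift by default, but the deviation pipelines pass the
known 3 s instrument delay so measured series sit on the protocol clock —
without that, a pure transport lag masquerades as a target error of
`lag × slope` (≈ 0.5 pp on the half-sine), which is an instrument
property, not a control error. Binning uses 5 s bins; aggregation across
runs reports the mean of per-run bin means with a seeded nonparametric
bootstrap 95 % CI (over runs when several are given, over within-bin
samples for a single run). End-tidal channels subtract each run's own
initial-60 s mean before aggregating. Empty bins are flagged missing,
never zero-filled.

## Deviation metrics

Per protocol segment, deviation = measured − target at matched times,
after transition removal: boxes lose their first 10 s and last 5 s, ramps
their last 5 s, half-sines and baselines are kept whole (for the default
protocol: 3×30 s + 55 s + 60 s of stimulus evaluation time). "Mean
deviation" is ambiguous between signed and absolute; both are reported,
and the headline statistic — the maximum across stimuli — conservatively
uses the mean absolute deviation. Baselines are reported as entries but
excluded from the headline maximum, which is quoted over the stimuli.
Bootstrap CIs are over samples within the window and are labelled as such.

## Study sizes and what the tests show

The acceptance studies use six seeded runs of the full 555 s protocol for
the spontaneous arm (the study size of the corresponding bench/volunteer
assessments) and single noiseless runs for deterministic mechanisms; at
10 ms steps each run integrates in well under a second, so the whole
suite stays desk-scale. Synthetic subjects breathe perfectly regularly,
never swallow, move or leak, and their chemoreflex is a one-parameter
rate scaling; passing tests therefore demonstrate correctness of the
control law, the transport/alveolar model and the analysis pipeline under
realistic noise and delays — not performance on human recordings, whose
artifact burden and phase-identification difficulty are outside what this
generator emulates.

## Known limitations

- The circuit is lumped; intra-breath concentration gradients along the
  tubing are only resolved at compartment granularity.
- The chemoreflex acts on rate alone; real subjects deepen breaths too.
- O₂ is tracked as a diluted bystander; there is no O₂ administration.
- The ventilated analysis path applies one fixed 8 s shift to all runs,
  as in the procedure it mirrors, although the true transport delay
  varies with tidal volume and rate.
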