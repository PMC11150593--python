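"""Closed-loop respiratory simulator and synthetic trace generator.

The simulator couples four pieces into one fixed-step loop:

* a flow source — a ventilator (volume- or pressure-control inflation of a
  passive test lung) or a spontaneously breathing subject whose breathing
  rate rises with alveolar CO2 (a simple central chemoreflex);
* the admixture controller (or the reservoir blender) acting on the sensed
  respiratory flow;
* a breathing circuit — the injected CO2 is advected through one or two
  well-mixed compartments (humidifier, tubing) whose placement relative to
  the sampling port sets the rise time of inspired-gas changes;
* a single well-mixed alveolar compartment obeying
  ``d(FA)/dt = [VA_inst * (Fi - FA) +/- Vgas] / FRC``, whose steady state is
  the classical alveolar gas relation ``FO2A = FO2i - VO2/VA`` and
  ``FCO2A = FCO2i + VCO2/VA``.

The gas analyzer at the sampling port sees inspired gas during inspiration
and expired gas (anatomical dead-space gas first, then alveolar gas) during
expiration; its output passes a first-order response, a pure sampling
delay, uniform resampling and additive Gaussian noise.  Everything random
is drawn from one seeded generator, so identical seeds and configurations
give bit-identical traces.

Flows are handled internally in L/s; the public interfaces use L/min and
mL, the bedside units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union
import warnings

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .controller import AIR, GasFractions
from .protocol import SafetyLimits, StimulusProtocol

__all__ = [
    "VentilatorSettings",
    "LungMechanics",
    "SubjectModel",
    "CircuitConfig",
    "ControllerConfig",
    "ReservoirConfig",
    "VentilatorScenario",
    "SubjectScenario",
    "SimulationResult",
    "SimulationError",
    "BreathPattern",
    "ventilator_flow",
    "spontaneous_ventilation",
    "steady_state_alveolar",
    "alveolar_derivatives",
    "simulate_closed_loop",
]

#: Standard dry-gas conversion: P_gas = F_gas * (P_atm - P_H2O).
P_ATM_MMHG = 760.0
P_H2O_MMHG = 47.0
MMHG_TO_KPA = 0.1333224


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator inflation settings.

    ``volume_control`` delivers ``tidal_volume`` mL at constant flow over
    ``t_insp`` seconds; ``pressure_control`` applies ``p_insp`` cmH2O above
    PEEP for ``t_insp`` seconds, the flow decaying with the circuit's RC
    time constant so the delivered volume is set by pressure and compliance
    alone.
    """

    mode: str = "volume_control"
    tidal_volume: float = 500.0  # mL, volume control
    p_insp: float = 15.0  # cmH2O above PEEP, pressure control
    t_insp: float = 1.5  # s
    rate: float = 12.0  # breaths/min
    peep: float = 5.0  # cmH2O

    def __post_init__(self) -> None:
        if self.mode not in ("volume_control", "pressure_control"):
            raise ValueError(f"unknown ventilator mode {self.mode!r}")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not (0 < self.t_insp < 60.0 / self.rate):
            raise ValueError("t_insp must lie within the breath period")
        if self.mode == "volume_control" and self.tidal_volume <= 0:
            raise ValueError("volume control requires tidal_volume > 0")
        if self.mode == "pressure_control" and self.p_insp <= 0:
            raise ValueError("pressure control requires p_insp > 0")

    @property
    def period(self) -> float:
        return 60.0 / self.rate


@dataclass(frozen=True)
class LungMechanics:
    """Passive (test-)lung mechanics and gas-store geometry."""

    compliance: float = 40.0  # mL/cmH2O
    resistance: float = 5.0  # cmH2O/(L/s)
    frc: float = 2000.0  # mL
    dead_space: float = 100.0  # mL

    def __post_init__(self) -> None:
        if min(self.compliance, self.resistance, self.frc, self.dead_space) <= 0:
            raise ValueError("all lung mechanics parameters must be > 0")
        if self.dead_space >= self.frc:
            raise ValueError("dead_space must be smaller than frc")

    @property
    def rc(self) -> float:
        """Expiratory time constant R*C in seconds."""
        return self.resistance * self.compliance / 1000.0


@dataclass(frozen=True)
class SubjectModel:
    """Spontaneously breathing subject.

    ``chemoreflex_gain`` is the fractional increase in alveolar ventilation
    per kPa rise of alveolar PCO2 above the subject's own baseline; the
    increase is realized through breathing rate at constant tidal volume.
    """

    tidal_volume: float = 500.0  # mL
    rate_baseline: float = 14.0  # breaths/min
    vo2: float = 0.25  # L/min O2 consumption
    vco2: float = 0.20  # L/min CO2 production
    dead_space: float = 150.0  # mL
    frc: float = 3000.0  # mL
    chemoreflex_gain: float = 0.3  # /kPa
    insp_fraction: float = 0.4  # inspiratory duty cycle Ti/Ttot

    def __post_init__(self) -> None:
        if self.tidal_volume <= self.dead_space:
            raise ValueError("tidal_volume must exceed dead_space")
        if self.vo2 < 0 or self.vco2 < 0:
            raise ValueError("vo2 and vco2 must be >= 0")
        if not (0.1 <= self.insp_fraction <= 0.7):
            raise ValueError("insp_fraction out of physiological range")

    @property
    def alveolar_ventilation(self) -> float:
        """Baseline alveolar ventilation in L/min."""
        return self.rate_baseline * (self.tidal_volume - self.dead_space) / 1000.0


@dataclass(frozen=True)
class CircuitConfig:
    """Breathing-circuit geometry and analyzer characteristics.

    ``inlet_position`` places the CO2 inlet either right after the flow
    sensor (ventilator circuit: injected gas must wash through the
    humidifier and tubing before reaching the airway) or immediately
    proximal to the sampling port (subject circuit).  ``analyzer_noise_sd``
    is in volume percentage points of the analyzer reading.
    """

    inlet_position: str = "near_sampling_port"
    mixing_volume: float = 300.0  # mL, humidifier
    transport_volume: float = 400.0  # mL, tubing inlet -> sampling port
    sampling_delay: float = 3.0  # s
    sample_rate: float = 60.0  # Hz
    analyzer_noise_sd: float = 0.05  # percentage points
    analyzer_response: float = 0.2  # s, first-order time constant

    def __post_init__(self) -> None:
        if self.inlet_position not in ("near_flow_sensor", "near_sampling_port"):
            raise ValueError(f"unknown inlet_position {self.inlet_position!r}")
        if min(self.mixing_volume, self.transport_volume) < 0:
            raise ValueError("circuit volumes must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass(frozen=True)
class ReservoirConfig:
    """Reservoir blender: fresh-gas flow, target O2 and column volume."""

    total_flow_lpm: float = 8.0
    fo2: float = 0.21
    volume_ml: float = 700.0


@dataclass(frozen=True)
class ControllerConfig:
    """Which gas system drives the run and with what parameters.

    ``sensor_gain`` models a flow-sensor calibration bias: the controller
    sees ``gain * true flow``, so a gain below 1 (laminar flow reading low)
    produces a proportional undershoot of the delivered CO2 fraction.
    """

    system: str = "additional"
    additional_fco2: float = 1.0
    sensor_gain: float = 1.0
    setpoint_cap_lpm: float = 2.0
    limits: SafetyLimits = field(default_factory=SafetyLimits)
    reservoir: ReservoirConfig = field(default_factory=ReservoirConfig)

    def __post_init__(self) -> None:
        if self.system not in ("additional", "reservoir"):
            raise ValueError(f"unknown system {self.system!r}")
        if self.sensor_gain <= 0:
            raise ValueError("sensor_gain must be > 0")


@dataclass(frozen=True)
class VentilatorScenario:
    settings: VentilatorSettings = field(default_factory=VentilatorSettings)
    mechanics: LungMechanics = field(default_factory=LungMechanics)
    gas: GasFractions = AIR  # respiratory gas from the ventilator


@dataclass(frozen=True)
class SubjectScenario:
    subject: SubjectModel = field(default_factory=SubjectModel)
    ambient: GasFractions = AIR


Scenario = Union[VentilatorScenario, SubjectScenario]


@dataclass
class SimulationResult:
    """Analyzer trace plus ground truth of one closed-loop run.

    ``trace`` is the uniformly sampled analyzer record (t_s, fco2_percent,
    fo2_percent, flow_lpm); ``truth`` the per-step state history and
    ``breaths`` the per-breath flow-weighted delivered inspired fractions.
    """

    trace: pd.DataFrame
    truth: pd.DataFrame
    breaths: pd.DataFrame
    seed: int
    config: dict


@dataclass(frozen=True)
class BreathPattern:
    rate: float  # breaths/min
    tidal_volume: float  # mL


def ventilator_flow(settings: VentilatorSettings, mech: LungMechanics, t: float) -> float:
    """Inspiratory flow (L/min) of the unassisted ventilator at time ``t``.

    Volume control: constant ``tidal_volume / t_insp`` during inspiration.
    Pressure control: ``(p_insp / R) * exp(-tau / RC)``.  Zero during the
    expiratory phase (passive deflation is handled by the lung model).
    """
    tau = t % settings.period
    if tau >= settings.t_insp:
        return 0.0
    if settings.mode == "volume_control":
        return settings.tidal_volume / 1000.0 / settings.t_insp * 60.0
    return settings.p_insp / mech.resistance * math.exp(-tau / mech.rc) * 60.0


def spontaneous_ventilation(
    subject: SubjectModel, alveolar_pco2: float, baseline_pco2: float
) -> BreathPattern:
    """Instantaneous breath pattern under the CO2 chemoreflex.

    Alveolar ventilation is scaled by
    ``max(0, 1 + gain * (PCO2A - PCO2A_baseline))`` (pressures in kPa),
    realized as a rate change at constant tidal volume.
    """
    factor = max(0.0, 1.0 + subject.chemoreflex_gain * (alveolar_pco2 - baseline_pco2))
    return BreathPattern(rate=subject.rate_baseline * factor, tidal_volume=subject.tidal_volume)


def steady_state_alveolar(inspired: GasFractions, subject: SubjectModel) -> GasFractions:
    """Steady-state alveolar fractions for constant inspired gas.

    ``FO2A = FO2i - VO2/VA`` and ``FCO2A = FCO2i + VCO2/VA`` with VA the
    baseline alveolar ventilation; values are clipped to [0, 1] with a
    warning if the parameters are inconsistent enough to require it.
    """
    va = subject.alveolar_ventilation
    if va <= 0:
        raise SimulationError("alveolar ventilation must be > 0")
    fo2 = inspired.fo2 - subject.vo2 / va
    fco2 = inspired.fco2 + subject.vco2 / va
    if not (0.0 <= fo2 <= 1.0 and 0.0 <= fco2 <= 1.0):
        warnings.warn("steady-state alveolar fractions clipped to [0, 1]", stacklevel=2)
    return GasFractions(fco2=min(max(fco2, 0.0), 1.0), fo2=min(max(fo2, 0.0), 1.0))


def alveolar_derivatives(
    fa: tuple[float, float],
    fi: tuple[float, float],
    va_lps: float,
    vco2_lps: float,
    vo2_lps: float,
    frc_l: float,
) -> tuple[float, float]:
    """Time derivatives (1/s) of the alveolar (CO2, O2) fractions.

    ``d(FA)/dt = [VA_inst * (Fi - FA) +/- Vgas] / FRC`` — ventilation drives
    the store toward the inspired gas while metabolism adds CO2 and removes
    O2.  Exposed separately so the dynamic compartment can be checked
    against the steady-state relation in isolation.
    """
    dco2 = (va_lps * (fi[0] - fa[0]) + vco2_lps) / frc_l
    do2 = (va_lps * (fi[1] - fa[1]) - vo2_lps) / frc_l
    return dco2, do2


def alveolar_pressure_kpa(fraction: float) -> float:
    """Alveolar partial pressure (kPa) of a dry-gas fraction."""
    return fraction * (P_ATM_MMHG - P_H2O_MMHG) * MMHG_TO_KPA


def _clamped_target_series(
    protocol: StimulusProtocol,
    times: np.ndarray,
    respiratory: GasFractions,
    limits: SafetyLimits,
    additional_fco2: float,
) -> np.ndarray:
    """Vectorized protocol evaluation followed by safety clamping."""
    target = np.zeros_like(times)
    for _, seg, t0, t1 in protocol.iter_windows():
        m = (times >= t0) & (times < t1)
        if not m.any():
            continue
        tau = times[m] - t0
        if seg.kind in ("baseline", "box"):
            target[m] = seg.level
        elif seg.kind == "ramp":
            target[m] = seg.start_level + (seg.level - seg.start_level) * tau / seg.duration
        else:
            target[m] = seg.level * np.sin(np.pi * tau / seg.duration)
    target = np.minimum(target, limits.max_fco2i)
    if respiratory.fo2 < limits.min_fo2i:
        raise SimulationError("respiratory gas O2 below the configured safety floor")
    # inspired O2 floor: T <= a - m*(a - c)/fo2_res
    ceiling = additional_fco2 - limits.min_fo2i * (
        additional_fco2 - respiratory.fco2
    ) / respiratory.fo2
    return np.minimum(target, max(ceiling, respiratory.fco2))


class _TransportChain:
    """Well-mixed compartments in series between gas inlet and airway."""

    def __init__(self, volumes_ml, initial: tuple[float, float]):
        self.volumes = [v / 1000.0 for v in volumes_ml if v > 0]
        self.state = [list(initial) for _ in self.volumes]

    def step(self, inflow: tuple[float, float], q_lps: float, dt: float) -> tuple[float, float]:
        if not self.volumes:
            return inflow
        upstream = inflow
        for vol, comp in zip(self.volumes, self.state):
            k = min(q_lps * dt / vol, 1.0)
            comp[0] += k * (upstream[0] - comp[0])
            comp[1] += k * (upstream[1] - comp[1])
            upstream = (comp[0], comp[1])
        return upstream


def simulate_closed_loop(
    protocol: StimulusProtocol,
    scenario: Scenario,
    circuit: CircuitConfig | None = None,
    controller: ControllerConfig | None = None,
    seed: int = 0,
    dt: float = 0.01,
) -> SimulationResult:
    """Run the full closed loop over one protocol and return the record.

    Fixed-step explicit integration at ``dt`` seconds: flow source ->
    gain-scaled flow sensor -> proportional setpoint -> inlet injection ->
    circuit transport -> airway -> alveolar compartment, with the analyzer
    sampling the port.  See the module docstring for the model details.
    """
    circuit = circuit or CircuitConfig()
    controller = controller or ControllerConfig()
    rng = np.random.default_rng(seed)

    is_subject = isinstance(scenario, SubjectScenario)
    if controller.system == "reservoir" and not is_subject:
        raise SimulationError(
            "the reservoir system cannot drive a ventilator circuit "
            "(one-way valves block reservoir control)"
        )
    res_gas = scenario.ambient if is_subject else scenario.gas
    duration = protocol.duration
    n = int(round(duration / dt))
    times = np.arange(n) * dt

    target = _clamped_target_series(
        protocol, times, res_gas, controller.limits, controller.additional_fco2
    )
    a = controller.additional_fco2
    ratio = (target - res_gas.fco2) / (a - target)
    cap_lps = controller.setpoint_cap_lpm / 60.0
    gain = controller.sensor_gain

    if is_subject:
        subject = scenario.subject
        frc_l = subject.frc / 1000.0
        vd_l = subject.dead_space / 1000.0
        vt_l = subject.tidal_volume / 1000.0
        eff = 1.0 - subject.dead_space / subject.tidal_volume
        vco2_lps, vo2_lps = subject.vco2 / 60.0, subject.vo2 / 60.0
        fa0 = steady_state_alveolar(res_gas, subject)
        pco2_base = alveolar_pressure_kpa(fa0.fco2)
    else:
        settings, mech = scenario.settings, scenario.mechanics
        frc_l = mech.frc / 1000.0
        vd_l = mech.dead_space / 1000.0
        eff = 1.0 - mech.dead_space / max(settings.tidal_volume, mech.dead_space * 2)
        vco2_lps = vo2_lps = 0.0  # passive test lung
        fa0 = res_gas

    fa = [fa0.fco2, fa0.fo2]
    chain = _TransportChain(
        [circuit.mixing_volume, circuit.transport_volume]
        if circuit.inlet_position == "near_flow_sensor"
        else [],
        (res_gas.fco2, res_gas.fo2),
    )

    use_reservoir = controller.system == "reservoir"
    res_cfg = controller.reservoir
    res_mix = [res_gas.fco2, res_cfg.fo2]  # reservoir mixture composition
    res_col_l = res_cfg.volume_ml / 1000.0  # mixture column currently stored
    res_vol_l = res_cfg.volume_ml / 1000.0
    res_fill_lps = res_cfg.total_flow_lpm / 60.0

    # breath scheduling
    if is_subject:
        breath_start, patt = 0.0, spontaneous_ventilation(subject, pco2_base, pco2_base)
        period = 60.0 / max(patt.rate, 1.0)
        t_insp = subject.insp_fraction * period
    else:
        breath_start, period, t_insp = 0.0, settings.period, settings.t_insp

    port = [res_gas.fco2, res_gas.fo2]
    ds_store = [res_gas.fco2, res_gas.fo2]  # anatomical dead-space contents
    last_insp = [res_gas.fco2, res_gas.fo2]
    v_lung = 0.0  # L above relaxation volume
    v_expired = 0.0

    port_co2 = np.empty(n)
    port_o2 = np.empty(n)
    deliv_co2 = np.empty(n)
    deliv_o2 = np.empty(n)
    alv_co2 = np.empty(n)
    alv_o2 = np.empty(n)
    added = np.empty(n)
    sensed = np.empty(n)

    breaths: list[dict] = []
    acc_fq = [0.0, 0.0]
    acc_q = 0.0

    def finish_breath(t_end: float) -> None:
        nonlocal acc_q
        if acc_q > 1e-9:
            breaths.append(
                {
                    "t_start": breath_start,
                    "t_end": t_end,
                    "delivered_co2_percent": 100.0 * acc_fq[0] / acc_q,
                    "delivered_o2_percent": 100.0 * acc_fq[1] / acc_q,
                    "inspired_volume_ml": 1000.0 * acc_q,
                    "rate_bpm": 60.0 / period,
                }
            )
        acc_fq[0] = acc_fq[1] = 0.0
        acc_q = 0.0

    for i in range(n):
        t = times[i]
        tau = t - breath_start
        if tau >= period:
            finish_breath(t)
            breath_start = t
            tau = 0.0
            v_expired = 0.0
            if is_subject:
                patt = spontaneous_ventilation(
                    subject, alveolar_pressure_kpa(fa[0]), pco2_base
                )
                period = 60.0 / max(patt.rate, 1.0)
                t_insp = subject.insp_fraction * period

        inspiring = tau < t_insp
        if inspiring:
            if is_subject:
                q_total = (
                    math.pi * vt_l / (2.0 * t_insp) * math.sin(math.pi * tau / t_insp)
                )
            elif settings.mode == "volume_control":
                q_res_src = settings.tidal_volume / 1000.0 / settings.t_insp
                q_total = None  # determined by source + admixture below
            else:
                q_total = settings.p_insp / mech.resistance * math.exp(-tau / mech.rc)
        else:
            q_total = 0.0

        r = ratio[i]
        q_add = 0.0
        if inspiring and not use_reservoir:
            if not is_subject and settings.mode == "volume_control":
                # source pushes a fixed respiratory flow; CO2 adds on top
                q_res = q_res_src
                q_add = min(r * gain * q_res, cap_lps)
                q_total = q_res + q_add
            else:
                # total inspiratory flow fixed by mechanics / subject demand;
                # the sensor sits upstream of the inlet and sees q_res only
                q_res = q_total / (1.0 + r * gain)
                q_add = r * gain * q_res
                if q_add > cap_lps:
                    q_add = cap_lps
                    q_res = q_total - q_add
        elif inspiring:
            q_res = q_total
        else:
            q_res = 0.0

        # reservoir column dynamics (refills at fresh-gas flow, drains when
        # the breath outruns it; composition relaxes toward the setpoint)
        if use_reservoir:
            k_mix = res_fill_lps * dt / res_vol_l
            res_mix[0] += k_mix * (target[i] - res_mix[0])
            res_mix[1] += k_mix * (res_cfg.fo2 - res_mix[1])
            drain = (q_total if inspiring else 0.0) - res_fill_lps
            res_col_l = min(max(res_col_l - drain * dt, 0.0), res_vol_l)

        if inspiring and q_total > 0.0:
            if use_reservoir:
                mix = (
                    (res_mix[0], res_mix[1]) if res_col_l > 0.0 else (res_gas.fco2, res_gas.fo2)
                )
            else:
                mix = (
                    (res_gas.fco2 * q_res + a * q_add) / q_total,
                    res_gas.fo2 * q_res / q_total,
                )
            inspired_gas = chain.step(mix, q_total, dt)
            port[0], port[1] = inspired_gas
            last_insp[0], last_insp[1] = inspired_gas
            acc_fq[0] += inspired_gas[0] * q_total * dt
            acc_fq[1] += inspired_gas[1] * q_total * dt
            acc_q += q_total * dt
            v_lung += q_total * dt
            va_inst = q_total * eff
            fa[0] += (va_inst * (inspired_gas[0] - fa[0]) + vco2_lps) * dt / frc_l
            fa[1] += (va_inst * (inspired_gas[1] - fa[1]) - vo2_lps) * dt / frc_l
        else:
            if not inspiring:
                tau_exp = (
                    (period - t_insp) / 4.0 if is_subject else max(mech.rc, 0.05)
                )
                q_exp = v_lung / tau_exp
                v_lung = max(v_lung - q_exp * dt, 0.0)
                if q_exp * dt > 1e-9:
                    if v_expired < vd_l:
                        port[0], port[1] = ds_store
                    else:
                        port[0], port[1] = fa
                    v_expired += q_exp * dt
            fa[0] += vco2_lps * dt / frc_l
            fa[1] -= vo2_lps * dt / frc_l

        if tau + dt >= t_insp and inspiring:
            ds_store[0], ds_store[1] = last_insp  # gas left in the dead space

        fa[0] = min(max(fa[0], 0.0), 1.0)
        fa[1] = min(max(fa[1], 0.0), 1.0)

        port_co2[i] = port[0]
        port_o2[i] = port[1]
        deliv_co2[i] = last_insp[0]
        deliv_o2[i] = last_insp[1]
        alv_co2[i] = fa[0]
        alv_o2[i] = fa[1]
        added[i] = q_add * 60.0
        sensed[i] = gain * q_res * 60.0

        if not (math.isfinite(fa[0]) and math.isfinite(port[0])):
            raise SimulationError(f"non-finite simulator state at t={t:.3f} s")
    finish_breath(duration)

    # --- analyzer chain: first-order response, pure delay, 60 Hz sampling,
    # additive Gaussian noise ---------------------------------------------
    def analyzer(signal_pct: np.ndarray) -> np.ndarray:
        tau_a = circuit.analyzer_response
        if tau_a <= 0:
            return signal_pct
        k = min(dt / tau_a, 1.0)
        out, _ = lfilter([0.0, k], [1.0, k - 1.0], signal_pct, zi=[signal_pct[0]])
        return out

    n_samp = int(round(duration * circuit.sample_rate))
    ts = np.arange(n_samp) / circuit.sample_rate
    filt_co2 = analyzer(100.0 * port_co2)
    filt_o2 = analyzer(100.0 * port_o2)
    t_src = ts - circuit.sampling_delay
    meas_co2 = np.interp(t_src, times, filt_co2, left=filt_co2[0])
    meas_o2 = np.interp(t_src, times, filt_o2, left=filt_o2[0])
    if circuit.analyzer_noise_sd > 0:
        meas_co2 = meas_co2 + rng.normal(0.0, circuit.analyzer_noise_sd, n_samp)
        meas_o2 = meas_o2 + rng.normal(0.0, circuit.analyzer_noise_sd, n_samp)
    flow_samp = np.interp(ts, times, sensed)

    trace = pd.DataFrame(
        {"t_s": ts, "fco2_percent": meas_co2, "fo2_percent": meas_o2, "flow_lpm": flow_samp}
    )
    truth = pd.DataFrame(
        {
            "t_s": times,
            "target_percent": 100.0 * target,
            "delivered_co2_percent": 100.0 * deliv_co2,
            "delivered_o2_percent": 100.0 * deliv_o2,
            "alv_co2_percent": 100.0 * alv_co2,
            "alv_o2_percent": 100.0 * alv_o2,
            "added_flow_lpm": added,
        }
    )
    config = {
        "scenario": "subject" if is_subject else "ventilator",
        "scenario_params": vars(scenario.subject) if is_subject else {
            "settings": vars(scenario.settings),
            "mechanics": vars(scenario.mechanics),
        },
        "circuit": vars(circuit),
        "controller": {
            "system": controller.system,
            "additional_fco2": controller.additional_fco2,
            "sensor_gain": controller.sensor_gain,
            "setpoint_cap_lpm": controller.setpoint_cap_lpm,
            "limits": vars(controller.limits),
            "reservoir": vars(controller.reservoir),
        },
        "protocol": protocol.name,
        "dt": dt,
        "seed": seed,
    }
    return SimulationResult(
        trace=trace, truth=truth, breaths=pd.DataFrame(breaths), seed=seed, config=config
    )
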