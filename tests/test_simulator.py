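"""Flow sources, alveolar dynamics and the closed simulation loop."""

import math

import numpy as np
import pandas as pd
import pytest

from co2challenge.controller import AIR, GasFractions
from co2challenge.protocol import StimulusProtocol, StimulusSegment
from co2challenge.simulator import (
    CircuitConfig,
    ControllerConfig,
    LungMechanics,
    SimulationError,
    SubjectModel,
    SubjectScenario,
    VentilatorScenario,
    VentilatorSettings,
    alveolar_derivatives,
    simulate_closed_loop,
    spontaneous_ventilation,
    steady_state_alveolar,
    ventilator_flow,
)

NOISELESS = dict(analyzer_noise_sd=0.0)


def quiet_subject(**kw):
    """Subject without the CO2 ventilatory reflex (fixed breathing)."""
    return SubjectModel(chemoreflex_gain=0.0, **kw)


@pytest.fixture(scope="module")
def box_run_noiseless(short_box_protocol):
    scenario = SubjectScenario(subject=quiet_subject())
    circuit = CircuitConfig(inlet_position="near_sampling_port", **NOISELESS)
    return simulate_closed_loop(short_box_protocol, scenario, circuit, seed=0)


class TestVentilatorFlow:
    def test_volume_control_constant_flow(self):
        s = VentilatorSettings(mode="volume_control", tidal_volume=500, t_insp=1.5, rate=12)
        assert ventilator_flow(s, LungMechanics(), 0.5) == pytest.approx(20.0)

    def test_expiration_has_no_inspiratory_flow(self):
        s = VentilatorSettings(mode="volume_control", tidal_volume=500, t_insp=1.5, rate=12)
        assert ventilator_flow(s, LungMechanics(), 3.0) == 0.0

    def test_pressure_control_flow_decays_exponentially(self):
        s = VentilatorSettings(mode="pressure_control", p_insp=15, t_insp=1.9, rate=12)
        mech = LungMechanics(compliance=40, resistance=5)
        flows = [ventilator_flow(s, mech, t) for t in (0.0, 0.5, 1.0, 1.8)]
        assert flows[0] == pytest.approx(15 / 5 * 60)
        assert all(b < a for a, b in zip(flows, flows[1:]))
        assert flows[-1] / flows[0] == pytest.approx(math.exp(-1.8 / mech.rc), rel=1e-9)


class TestSpontaneousVentilation:
    def test_no_gain_means_baseline_pattern(self):
        subject = quiet_subject()
        patt = spontaneous_ventilation(subject, 8.0, 5.0)
        assert patt.rate == subject.rate_baseline
        assert patt.tidal_volume == subject.tidal_volume

    def test_gain_scales_ventilation(self):
        subject = SubjectModel(chemoreflex_gain=0.3)
        patt = spontaneous_ventilation(subject, 6.0, 5.0)
        assert patt.rate == pytest.approx(1.3 * subject.rate_baseline)

    def test_ventilation_floored_at_zero(self):
        subject = SubjectModel(chemoreflex_gain=0.3)
        assert spontaneous_ventilation(subject, 0.0, 5.0).rate == 0.0


class TestSteadyStateAlveolar:
    def test_co2_relation(self):
        # VA = 10/min * (500 - 100) mL = 4 L/min; FCO2A = 0 + 0.2/4
        subject = SubjectModel(rate_baseline=10, tidal_volume=500, dead_space=100, vco2=0.2)
        out = steady_state_alveolar(GasFractions(0.0, 0.21), subject)
        assert out.fco2 == pytest.approx(0.05, abs=1e-12)

    def test_o2_relation(self):
        # VA = 12.5 * 0.4 = 5 L/min; FO2A = 0.21 - 0.25/5 = 0.16
        subject = SubjectModel(rate_baseline=12.5, tidal_volume=500, dead_space=100, vo2=0.25)
        out = steady_state_alveolar(GasFractions(0.0, 0.21), subject)
        assert out.fo2 == pytest.approx(0.16, abs=1e-12)

    def test_no_metabolism_degenerates_to_inspired(self):
        subject = SubjectModel(vco2=0.0, vo2=0.25)
        out = steady_state_alveolar(GasFractions(0.03, 0.21), subject)
        assert out.fco2 == pytest.approx(0.03, abs=1e-15)

    def test_dynamic_compartment_converges_to_steady_state(self):
        """Fixed ventilation + constant inspired gas -> the alveolar ODE
        settles on the algebraic steady state (tolerance 1e-6)."""
        subject = SubjectModel()
        inspired = GasFractions(0.05, 0.199)
        expected = steady_state_alveolar(inspired, subject)
        fa = [0.04, 0.16]
        va = subject.alveolar_ventilation / 60.0
        dt = 0.05
        for _ in range(40000):
            d = alveolar_derivatives(
                tuple(fa),
                (inspired.fco2, inspired.fo2),
                va,
                subject.vco2 / 60.0,
                subject.vo2 / 60.0,
                subject.frc / 1000.0,
            )
            fa[0] += d[0] * dt
            fa[1] += d[1] * dt
        assert fa[0] == pytest.approx(expected.fco2, abs=1e-6)
        assert fa[1] == pytest.approx(expected.fo2, abs=1e-6)


class TestClosedLoop:
    def test_plateau_delivery_matches_target(self, box_run_noiseless):
        """Ideal mixing at the port: per-breath delivered inspired CO2 hits
        the 5 % box target within 0.05 pp once the plateau is established."""
        b = box_run_noiseless.breaths
        plateau = b[(b.t_start > 40) & (b.t_start < 175)]
        assert len(plateau) > 10
        assert np.abs(plateau.delivered_co2_percent - 5.0).max() < 0.05

    def test_all_baseline_stays_ambient(self):
        protocol = StimulusProtocol((StimulusSegment("baseline", 60.0),))
        scenario = SubjectScenario(subject=quiet_subject())
        res = simulate_closed_loop(
            protocol, scenario, CircuitConfig(**NOISELESS), seed=0
        )
        assert np.abs(res.truth.delivered_co2_percent).max() < 1e-9
        assert res.truth.added_flow_lpm.max() == 0.0

    def test_gain_bias_closed_form(self, short_box_protocol):
        """Sensor gain g shifts the plateau to 100*r*g/(1+r*g), the
        laminar-flow under-reading mechanism."""
        scenario = VentilatorScenario(
            settings=VentilatorSettings(mode="volume_control", tidal_volume=500, t_insp=1.5, rate=12)
        )
        circuit = CircuitConfig(inlet_position="near_flow_sensor", **NOISELESS)
        res = simulate_closed_loop(
            short_box_protocol, scenario, circuit, ControllerConfig(sensor_gain=0.93), seed=0
        )
        b = res.breaths
        plateau = b[b.t_start > 120].delivered_co2_percent.mean()
        r, g = 1 / 19, 0.93
        assert plateau == pytest.approx(100 * r * g / (1 + r * g), abs=1e-3)

    def test_alveolar_converges_to_steady_state_in_the_loop(self):
        """Constant 5 % inspired CO2 drives the in-loop alveolar compartment
        to the algebraic steady state (cycle-mean comparison)."""
        protocol = StimulusProtocol(
            (StimulusSegment("box", 400.0, level=0.05),), name="const-5pct"
        )
        subject = quiet_subject()
        scenario = SubjectScenario(subject=subject)
        res = simulate_closed_loop(
            protocol, scenario, CircuitConfig(**NOISELESS), seed=0
        )
        delivered = res.truth.delivered_co2_percent.iloc[-1] / 100.0
        inspired = GasFractions(delivered, res.truth.delivered_o2_percent.iloc[-1] / 100.0)
        expected = steady_state_alveolar(inspired, subject)
        tail = res.truth[res.truth.t_s > 380]
        assert tail.alv_co2_percent.mean() / 100.0 == pytest.approx(expected.fco2, abs=0.002)
        assert tail.alv_o2_percent.mean() / 100.0 == pytest.approx(expected.fo2, abs=0.002)

    def test_dt_halving_convergence(self, short_box_protocol):
        scenario = SubjectScenario(subject=quiet_subject())
        circuit = CircuitConfig(**NOISELESS)
        coarse = simulate_closed_loop(short_box_protocol, scenario, circuit, seed=0, dt=0.01)
        fine = simulate_closed_loop(short_box_protocol, scenario, circuit, seed=0, dt=0.005)

        def plateau(res):
            b = res.breaths
            return b[(b.t_start > 60) & (b.t_start < 175)].delivered_co2_percent.mean() / 100.0

        assert abs(plateau(coarse) - plateau(fine)) < 1e-4

    def test_inlet_placement_orders_rise_time(self, short_box_protocol):
        """Injection near the flow sensor must rise strictly slower than
        injection at the sampling port (circuit volume in between)."""
        scenario = VentilatorScenario(
            settings=VentilatorSettings(mode="volume_control", tidal_volume=500, t_insp=1.5, rate=12)
        )

        def rise_time(inlet):
            circuit = CircuitConfig(inlet_position=inlet, **NOISELESS)
            res = simulate_closed_loop(short_box_protocol, scenario, circuit, seed=0)
            tr = res.truth[res.truth.t_s >= 30.0]
            d = tr.delivered_co2_percent.to_numpy()
            t = tr.t_s.to_numpy()
            plateau = d[-2000:].mean()
            t10 = t[np.argmax(d >= 0.1 * plateau)]
            t90 = t[np.argmax(d >= 0.9 * plateau)]
            return t90 - t10

        assert rise_time("near_flow_sensor") > rise_time("near_sampling_port")

    def test_admixture_grows_vc_tidal_volume_but_not_pc(self, short_box_protocol):
        """Volume control pushes a fixed respiratory volume, so added CO2
        comes on top; pressure control fixes the total inflation."""
        baseline_only = StimulusProtocol((StimulusSegment("baseline", 180.0),))
        circuit = CircuitConfig(inlet_position="near_sampling_port", **NOISELESS)

        def tidal(mode, protocol, **kw):
            settings = VentilatorSettings(mode=mode, t_insp=1.5, rate=12, **kw)
            res = simulate_closed_loop(
                protocol, VentilatorScenario(settings=settings), circuit, seed=0
            )
            b = res.breaths
            return b[b.t_start > 120].inspired_volume_ml.mean()

        vc_on = tidal("volume_control", short_box_protocol, tidal_volume=500)
        vc_off = tidal("volume_control", baseline_only, tidal_volume=500)
        assert vc_on > vc_off * 1.03
        assert vc_on == pytest.approx(vc_off * (1 + 1 / 19), rel=1e-3)

        pc_on = tidal("pressure_control", short_box_protocol, p_insp=15)
        pc_off = tidal("pressure_control", baseline_only, p_insp=15)
        assert pc_on == pytest.approx(pc_off, rel=1e-6)

    def test_fractions_stay_physical(self, box_run_noiseless):
        truth = box_run_noiseless.truth
        for col in ["delivered_co2_percent", "delivered_o2_percent", "alv_co2_percent", "alv_o2_percent"]:
            assert truth[col].between(0.0, 100.0).all()
        assert (
            truth.delivered_co2_percent + truth.delivered_o2_percent
        ).max() <= 100.0 + 1e-9

    def test_identical_seeds_give_identical_traces(self, short_box_protocol):
        scenario = SubjectScenario(subject=quiet_subject())
        a = simulate_closed_loop(short_box_protocol, scenario, seed=7)
        b = simulate_closed_loop(short_box_protocol, scenario, seed=7)
        c = simulate_closed_loop(short_box_protocol, scenario, seed=8)
        pd.testing.assert_frame_equal(a.trace, b.trace)
        assert not a.trace.fco2_percent.equals(c.trace.fco2_percent)

    def test_reservoir_on_ventilator_is_rejected(self, short_box_protocol):
        with pytest.raises(SimulationError):
            simulate_closed_loop(
                short_box_protocol,
                VentilatorScenario(),
                controller=ControllerConfig(system="reservoir"),
            )

    def test_reservoir_arm_tracks_target_and_entrains_room_air_under_reflex(
        self, short_box_protocol
    ):
        """With 8 L/min fresh gas the reservoir covers quiet breathing, but
        once the chemoreflex raises minute ventilation the column empties
        and late-inspiration gas falls toward room air."""
        scenario = SubjectScenario(subject=SubjectModel(chemoreflex_gain=0.5))
        circuit = CircuitConfig(inlet_position="near_sampling_port", **NOISELESS)
        res = simulate_closed_loop(
            short_box_protocol,
            scenario,
            circuit,
            ControllerConfig(system="reservoir"),
            seed=0,
        )
        truth = res.truth
        plateau = truth[(truth.t_s > 60) & (truth.t_s < 175)]
        # the mixture itself reaches the 5 % target...
        assert plateau.delivered_co2_percent.max() > 4.8
        # ...but per-breath means dip once room air is entrained late
        b = res.breaths
        late = b[(b.t_start > 120) & (b.t_start < 175)]
        assert late.delivered_co2_percent.min() < 4.5


def test_settings_validation():
    with pytest.raises(ValueError):
        VentilatorSettings(mode="jet")
    with pytest.raises(ValueError):
        VentilatorSettings(t_insp=6.0, rate=12)
    with pytest.raises(ValueError):
        LungMechanics(dead_space=2500, frc=2000)
    with pytest.raises(ValueError):
        SubjectModel(tidal_volume=100, dead_space=150)
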