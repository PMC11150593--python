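"""Ready-made experimental configurations.

Three presets mirror the three experimental arms the method is assessed
in: the admixture system driving a ventilated test lung, the admixture
system with a spontaneously breathing subject, and the reservoir reference
system with the same subject.  ``iso_like_test_cases`` provides a
representative bench set of 14 ventilator conditions (7 volume-control and
7 pressure-control) spanning common adult settings; it is a stand-in
spread of tidal volumes, pressures, rates and compliances, replaceable via
configuration.
"""

from __future__ import annotations

from .simulator import (
    CircuitConfig,
    ControllerConfig,
    LungMechanics,
    ReservoirConfig,
    SubjectModel,
    SubjectScenario,
    VentilatorScenario,
    VentilatorSettings,
)

__all__ = ["preset", "PRESET_NAMES", "iso_like_test_cases"]

PRESET_NAMES = ("ventilator_additional", "subject_additional", "subject_reservoir")


def preset(name: str):
    """Return ``(scenario, circuit, controller)`` for a named arm."""
    if name == "ventilator_additional":
        return (
            VentilatorScenario(),
            CircuitConfig(
                inlet_position="near_flow_sensor", mixing_volume=300.0, transport_volume=400.0
            ),
            ControllerConfig(system="additional"),
        )
    if name == "subject_additional":
        return (
            SubjectScenario(),
            CircuitConfig(inlet_position="near_sampling_port", transport_volume=50.0),
            ControllerConfig(system="additional"),
        )
    if name == "subject_reservoir":
        return (
            SubjectScenario(),
            CircuitConfig(inlet_position="near_sampling_port", transport_volume=50.0),
            ControllerConfig(system="reservoir", reservoir=ReservoirConfig()),
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def iso_like_test_cases() -> list[tuple[VentilatorSettings, LungMechanics]]:
    """14 representative ventilator bench conditions (7 VC + 7 PC)."""
    vc = [
        (500, 1.5, 12, 50, 5),
        (300, 1.0, 20, 20, 5),
        (400, 1.2, 15, 30, 10),
        (500, 1.5, 15, 40, 5),
        (600, 1.6, 12, 50, 10),
        (700, 1.8, 10, 60, 5),
        (800, 2.0, 10, 60, 10),
    ]
    pc = [
        (10, 1.0, 20, 20, 5),
        (12, 1.2, 15, 30, 5),
        (15, 1.5, 15, 40, 10),
        (15, 1.5, 12, 50, 5),
        (20, 1.6, 12, 50, 10),
        (22, 1.8, 10, 60, 5),
        (25, 2.0, 10, 60, 10),
    ]
    cases = []
    for vt, ti, rate, c, peep in vc:
        cases.append(
            (
                VentilatorSettings(
                    mode="volume_control", tidal_volume=vt, t_insp=ti, rate=rate, peep=peep
                ),
                LungMechanics(compliance=c, resistance=5.0, frc=max(4 * vt, 1500), dead_space=100.0),
            )
        )
    for p, ti, rate, c, peep in pc:
        cases.append(
            (
                VentilatorSettings(
                    mode="pressure_control", p_insp=p, t_insp=ti, rate=rate, peep=peep
                ),
                LungMechanics(compliance=c, resistance=5.0, frc=2000.0, dead_space=100.0),
            )
        )
    return cases
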