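"""Flow-proportional CO2 admixture control and reservoir gas blending.

The admixture method injects a stream of concentrated CO2 into the
inspiratory limb in proportion to the measured respiratory gas flow.  For a
target inspired fraction ``T``, respiratory-gas CO2 fraction ``c`` and
additional-gas CO2 fraction ``a`` the mass balance of the two streams

    T = (c * M_res + a * M_add) / (M_res + M_add)

inverts to the admixture ratio ``M_add / M_res = (T - c) / (a - T)``, which
is what the controller tracks sample by sample.  The reference reservoir
system instead pre-mixes O2, CO2 and N2 at fixed flows; its setpoints are
straightforward fractions of the total fresh-gas flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GasFractions",
    "FlowSample",
    "ReservoirSetpoints",
    "ControllerError",
    "AIR",
    "additional_flow_ratio",
    "resulting_fo2i",
    "setpoint_from_flow",
    "reservoir_setpoints",
]


class ControllerError(ValueError):
    """Unreachable target or infeasible mixture."""


@dataclass(frozen=True)
class GasFractions:
    """CO2 and O2 volume fractions of a gas stream (balance is inert)."""

    fco2: float
    fo2: float

    def __post_init__(self) -> None:
        for name, v in (("fco2", self.fco2), ("fo2", self.fo2)):
            if not (0.0 <= v <= 1.0 and math.isfinite(v)):
                raise ControllerError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.fco2 + self.fo2 > 1.0 + 1e-12:
            raise ControllerError(
                f"fco2 + fo2 = {self.fco2 + self.fo2} exceeds 1"
            )


#: Room air / CO2-free medical air.
AIR = GasFractions(fco2=0.0, fo2=0.209)


@dataclass(frozen=True)
class FlowSample:
    """One reading of the respiratory gas mass flow (L/min) at time t (s)."""

    t: float
    flow: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.flow):
            raise ControllerError(f"non-finite flow sample at t={self.t}")


@dataclass(frozen=True)
class ReservoirSetpoints:
    """Mass-flow setpoints (L/min) of the three-gas reservoir blender."""

    q_o2: float
    q_co2: float
    q_n2: float

    @property
    def total(self) -> float:
        return self.q_o2 + self.q_co2 + self.q_n2


def additional_flow_ratio(target: float, respiratory: GasFractions, additional_fco2: float) -> float:
    """Admixture ratio M_add/M_res delivering ``target`` inspired CO2.

    Solves the two-stream mass balance; mixing the streams at the returned
    ratio reproduces the target fraction exactly.

    Raises
    ------
    ControllerError
        If the target is at or above the additional-gas concentration
        (unreachable) or below the respiratory-gas concentration (CO2
        cannot be removed by adding gas).
    """
    if not (0.0 < additional_fco2 <= 1.0):
        raise ControllerError(f"additional_fco2 must be in (0, 1], got {additional_fco2}")
    if target >= additional_fco2:
        raise ControllerError(
            f"target {target} unreachable with additional gas at {additional_fco2}"
        )
    if target < respiratory.fco2:
        raise ControllerError(
            f"target {target} below respiratory CO2 {respiratory.fco2}: "
            "CO2 cannot be removed by admixture"
        )
    return (target - respiratory.fco2) / (additional_fco2 - target)


def resulting_fo2i(respiratory_fo2: float, ratio: float) -> float:
    """Inspired O2 fraction after admixing an O2-free stream at ``ratio``.

    Adding CO2 dilutes every other component of the respiratory gas by the
    factor ``1 / (1 + ratio)``.
    """
    if ratio < 0:
        raise ControllerError(f"ratio must be >= 0, got {ratio}")
    return respiratory_fo2 / (1.0 + ratio)


def setpoint_from_flow(sample: FlowSample, ratio: float, cap_lpm: float = 2.0) -> float:
    """Mass-flow-controller setpoint (L/min of additional gas).

    Proportional to the measured respiratory flow, capped at ``cap_lpm``
    (bounded actuator), and zero whenever the sensed flow is non-positive
    (expiration / no flow).
    """
    if ratio < 0:
        raise ControllerError(f"ratio must be >= 0, got {ratio}")
    if sample.flow <= 0.0:
        return 0.0
    return min(ratio * sample.flow, cap_lpm)


def reservoir_setpoints(target: GasFractions, total_flow: float) -> ReservoirSetpoints:
    """Three-gas setpoints realizing ``target`` at ``total_flow`` L/min.

    O2 and CO2 flows are the target fractions of the total; N2 carries the
    remainder, so the three setpoints always sum to ``total_flow``.
    """
    if total_flow <= 0:
        raise ControllerError(f"total_flow must be > 0, got {total_flow}")
    if target.fco2 + target.fo2 > 1.0:
        raise ControllerError("target fractions sum above 1: infeasible mixture")
    q_co2 = target.fco2 * total_flow
    q_o2 = target.fo2 * total_flow
    q_n2 = total_flow - q_co2 - q_o2
    return ReservoirSetpoints(q_o2=q_o2, q_co2=q_co2, q_n2=q_n2)
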