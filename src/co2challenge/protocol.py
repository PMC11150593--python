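"""Inspired-CO2 stimulus protocols.

A stimulus protocol is an ordered piecewise target function for the
fractional CO2 concentration of the inspired gas (FCO2i).  Four segment
shapes are supported: constant ``baseline`` (zero target), constant ``box``
plateaus, linear ``ramp`` transitions and ``half_sine`` bumps (the first
half period of a sinusoid).  Concentrations are dimensionless fractions
everywhere inside the library; protocol files on disk use volume percent,
the conventional display unit, and the conversion happens exactly once at
I/O time.

Time is continuous seconds from protocol start.  Segment boundaries are
half-open ``[start, end)`` so the target is single-valued at every join.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

log = logging.getLogger(__name__)

SEGMENT_KINDS = ("baseline", "box", "ramp", "half_sine")

#: Hard ceiling on any stimulus level, matching the standard safety practice
#: for hypercapnic gas challenges (5 % inspired CO2).
DEFAULT_MAX_FCO2I = 0.05
#: Floor on the inspired O2 fraction that admixture may not violate.
DEFAULT_MIN_FO2I = 0.19


class ProtocolError(ValueError):
    """Invalid protocol definition or out-of-range evaluation."""


class SafetyConfigurationError(ProtocolError):
    """The ambient/respiratory gas already violates a safety limit."""


@dataclass(frozen=True)
class StimulusSegment:
    """One piece of the target function.

    Parameters
    ----------
    kind:
        ``baseline``, ``box``, ``ramp`` or ``half_sine``.
    duration:
        Segment length in seconds, strictly positive.
    level:
        CO2 volume fraction: the box plateau, ramp end point or half-sine
        peak.  Baselines have level 0.
    start_level:
        Ramp starting fraction (ignored for other kinds), default 0.
    """

    kind: str
    duration: float
    level: float = 0.0
    start_level: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ProtocolError(f"unknown segment kind {self.kind!r}")
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise ProtocolError(f"segment duration must be > 0, got {self.duration}")
        for name, value in (("level", self.level), ("start_level", self.start_level)):
            if not (0.0 <= value <= 1.0):
                raise ProtocolError(f"segment {name} must be a fraction in [0, 1], got {value}")
        if self.kind == "baseline" and self.level != 0.0:
            raise ProtocolError("baseline segments must have level 0")

    def value_at(self, tau: float) -> float:
        """Target fraction ``tau`` seconds into this segment."""
        if self.kind in ("baseline", "box"):
            return self.level
        if self.kind == "ramp":
            return self.start_level + (self.level - self.start_level) * tau / self.duration
        # half_sine: first half of a sinusoid whose full period is 2*duration
        return self.level * math.sin(math.pi * tau / self.duration)

    def integral(self) -> float:
        """Analytic integral of the target over the segment (fraction * s)."""
        if self.kind in ("baseline", "box"):
            return self.level * self.duration
        if self.kind == "ramp":
            return 0.5 * (self.start_level + self.level) * self.duration
        return self.level * (2.0 / math.pi) * self.duration


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered sequence of stimulus segments with a name."""

    segments: tuple[StimulusSegment, ...]
    name: str = "protocol"

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ProtocolError("protocol must contain at least one segment")

    @property
    def duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    def segment_starts(self) -> list[float]:
        starts, t = [], 0.0
        for seg in self.segments:
            starts.append(t)
            t += seg.duration
        return starts

    def iter_windows(self) -> Iterator[tuple[int, StimulusSegment, float, float]]:
        """Yield ``(index, segment, t_start, t_end)`` for every segment."""
        t = 0.0
        for i, seg in enumerate(self.segments):
            yield i, seg, t, t + seg.duration
            t += seg.duration

    def integral(self) -> float:
        return sum(seg.integral() for seg in self.segments)


@dataclass(frozen=True)
class SafetyLimits:
    """Hard bounds on inspired gas composition.

    ``max_fco2i`` caps the CO2 target; ``min_fo2i`` is the inspired-O2 floor
    the admixture must not violate (the additional gas is O2-free, so adding
    CO2 dilutes O2).
    """

    max_fco2i: float = DEFAULT_MAX_FCO2I
    min_fo2i: float = DEFAULT_MIN_FO2I

    def __post_init__(self) -> None:
        if not (0.0 < self.max_fco2i < 1.0):
            raise ProtocolError(f"max_fco2i must be in (0, 1), got {self.max_fco2i}")
        if not (0.0 < self.min_fo2i < 1.0):
            raise ProtocolError(f"min_fo2i must be in (0, 1), got {self.min_fo2i}")


def build_default_protocol() -> StimulusProtocol:
    """The standard ~9 min assessment target function.

    60 s baseline, then three 45 s boxes at 1, 3 and 5 % separated by 45 s
    baselines, a 60 s ramp from 0 to 5 %, and a 60 s half-sinusoid peaking
    at 5 % (half of a 120 s period), each stimulus after the boxes preceded
    by a 45 s baseline and the whole protocol closed by a 60 s baseline.
    Total duration 555 s.
    """
    b45 = StimulusSegment("baseline", 45.0)
    segments = (
        StimulusSegment("baseline", 60.0),
        StimulusSegment("box", 45.0, level=0.01),
        b45,
        StimulusSegment("box", 45.0, level=0.03),
        b45,
        StimulusSegment("box", 45.0, level=0.05),
        b45,
        StimulusSegment("ramp", 60.0, level=0.05, start_level=0.0),
        b45,
        StimulusSegment("half_sine", 60.0, level=0.05),
        StimulusSegment("baseline", 60.0),
    )
    return StimulusProtocol(segments, name="default-co2-target")


def target_fco2i_at(protocol: StimulusProtocol, t: float) -> float:
    """Evaluate the protocol target fraction at time ``t`` (seconds).

    Segments are half-open ``[start, end)``; ``t`` must satisfy
    ``0 <= t < protocol.duration``.
    """
    if not (0.0 <= t < protocol.duration):
        raise ProtocolError(
            f"t={t} outside protocol {protocol.name!r} range [0, {protocol.duration})"
        )
    for _, seg, t0, t1 in protocol.iter_windows():
        if t0 <= t < t1:
            return seg.value_at(t - t0)
    # floating-point edge: t indistinguishable from total duration
    raise ProtocolError(f"t={t} could not be located in protocol {protocol.name!r}")


def clamp_target(
    fco2i_request: float,
    ambient,
    limits: SafetyLimits | None = None,
    additional_fco2: float = 1.0,
) -> float:
    """Clamp a requested inspired-CO2 fraction to the safety limits.

    The request is capped at ``limits.max_fco2i`` and, if necessary, reduced
    further so the inspired O2 resulting from the admixture (see
    :func:`co2challenge.controller.resulting_fo2i`) stays at or above
    ``limits.min_fo2i``.  The CO2 target is always the quantity reduced;
    the system has no O2 source with which to raise FO2i instead.

    Parameters
    ----------
    ambient:
        :class:`~co2challenge.controller.GasFractions` of the respiratory
        (carrier) gas.
    additional_fco2:
        CO2 fraction of the additional gas (default pure CO2).

    The operation is idempotent.
    """
    from .controller import additional_flow_ratio, resulting_fo2i

    limits = limits or SafetyLimits()
    if not (0.0 <= fco2i_request <= 1.0):
        raise ProtocolError(f"requested FCO2i must be a fraction, got {fco2i_request}")
    if ambient.fo2 < limits.min_fo2i:
        raise SafetyConfigurationError(
            f"ambient O2 fraction {ambient.fo2} is already below the floor {limits.min_fo2i}"
        )
    target = min(fco2i_request, limits.max_fco2i)
    if target <= ambient.fco2:
        return target
    ratio = additional_flow_ratio(target, ambient, additional_fco2)
    if resulting_fo2i(ambient.fo2, ratio) >= limits.min_fo2i - 1e-15:
        return target
    # Largest target whose dilution keeps FO2i at the floor:
    # FO2i = fo2 * (f_add - T) / (f_add - fco2_res)  >=  min_fo2i
    ceiling = additional_fco2 - limits.min_fo2i * (additional_fco2 - ambient.fco2) / ambient.fo2
    clamped = max(ambient.fco2, min(target, ceiling))
    log.warning(
        "CO2 target %.4f reduced to %.4f to keep inspired O2 at the %.3f floor",
        fco2i_request, clamped, limits.min_fo2i,
    )
    return clamped


# ---------------------------------------------------------------------------
# JSON serialization (percent on disk, fractions in memory)

PROTOCOL_SCHEMA_VERSION = 1


def protocol_to_dict(protocol: StimulusProtocol) -> dict:
    segments = []
    for seg in protocol.segments:
        entry: dict = {"kind": seg.kind, "duration_s": seg.duration, "fco2_percent": seg.level * 100.0}
        if seg.kind == "ramp":
            entry["start_fco2_percent"] = seg.start_level * 100.0
        segments.append(entry)
    return {"version": PROTOCOL_SCHEMA_VERSION, "name": protocol.name, "segments": segments}


def protocol_from_dict(data: dict) -> StimulusProtocol:
    if not isinstance(data, dict) or "segments" not in data:
        raise ProtocolError("protocol file must be a JSON object with a 'segments' list")
    version = data.get("version", PROTOCOL_SCHEMA_VERSION)
    if version != PROTOCOL_SCHEMA_VERSION:
        raise ProtocolError(f"unsupported protocol schema version {version}")
    segments = []
    for i, raw in enumerate(data["segments"]):
        try:
            kind = raw["kind"]
            duration = float(raw["duration_s"])
            level = float(raw.get("fco2_percent", 0.0)) / 100.0
            start = float(raw.get("start_fco2_percent", 0.0)) / 100.0
            segments.append(StimulusSegment(kind, duration, level=level, start_level=start))
        except (KeyError, TypeError, ValueError, ProtocolError) as exc:
            raise ProtocolError(f"invalid segment {i}: {exc}") from exc
    return StimulusProtocol(tuple(segments), name=str(data.get("name", "protocol")))


def read_protocol(path: str | Path) -> StimulusProtocol:
    """Load a stimulus protocol from a JSON file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ProtocolError(f"malformed protocol JSON in {path}: {exc}") from exc
    return protocol_from_dict(data)


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    """Write a protocol as JSON; ``read_protocol`` inverts this exactly."""
    with open(path, "w") as fh:
        json.dump(protocol_to_dict(protocol), fh, indent=2)
        fh.write("\n")
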