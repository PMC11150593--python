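"""Per-stimulus inspired-CO2 target-deviation metrics.

The accuracy of a run (or an aggregate of runs) is summarized as the mean
deviation between the measured and target inspired CO2 within each
stimulus, in volume percentage points, after removing transition periods:
the first 10 s and last 5 s of every box stimulus and the last 5 s of the
ramp.  Half-sine stimuli are evaluated in full, and baselines are reported
as entries of their own.  Both the signed mean (bias) and the mean absolute
deviation are reported; the headline accuracy statistic is the maximum of
the per-stimulus mean absolute deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol, target_fco2i_at

__all__ = [
    "MetricsError",
    "StimulusWindow",
    "DeviationReport",
    "BOX_HEAD_REMOVAL_S",
    "BOX_TAIL_REMOVAL_S",
    "RAMP_TAIL_REMOVAL_S",
    "stimulus_windows",
    "mean_target_deviation",
]

log = logging.getLogger(__name__)

BOX_HEAD_REMOVAL_S = 10.0
BOX_TAIL_REMOVAL_S = 5.0
RAMP_TAIL_REMOVAL_S = 5.0


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class StimulusWindow:
    """Evaluation window of one protocol segment (transitions removed)."""

    index: int
    kind: str
    label: str
    t_start: float
    t_end: float
    empty: bool = False

    @property
    def duration(self) -> float:
        return max(self.t_end - self.t_start, 0.0)


@dataclass
class DeviationReport:
    """Per-stimulus deviation table plus the headline statistic.

    ``entries`` columns: stimulus, kind, signed_mean_pp, abs_mean_pp,
    ci_low_pp, ci_high_pp (bootstrap 95 % CI of the signed mean), n.
    ``overall_max_abs_pp`` is the maximum mean absolute deviation across
    the non-baseline stimuli that contributed samples.
    """

    entries: pd.DataFrame
    overall_max_abs_pp: float
    ci_scope: str  # what the bootstrap resampled: "samples"


def stimulus_windows(protocol: StimulusProtocol) -> list[StimulusWindow]:
    """Evaluation windows for every segment of the protocol.

    Boxes lose their first 10 s and last 5 s, ramps their last 5 s;
    half-sine stimuli and baselines are evaluated in full.  A segment
    shorter than its exclusions yields an empty, flagged window.
    """
    if all(seg.kind == "baseline" for seg in protocol.segments):
        raise MetricsError("protocol contains no stimulus segments")
    windows = []
    counters: dict[str, int] = {}
    for i, seg, t0, t1 in protocol.iter_windows():
        counters[seg.kind] = counters.get(seg.kind, 0) + 1
        label = f"{seg.kind}_{counters[seg.kind]}"
        if seg.kind == "box":
            label = f"box_{seg.level * 100:g}pct"
            t0e, t1e = t0 + BOX_HEAD_REMOVAL_S, t1 - BOX_TAIL_REMOVAL_S
        elif seg.kind == "ramp":
            t0e, t1e = t0, t1 - RAMP_TAIL_REMOVAL_S
        else:
            t0e, t1e = t0, t1
        empty = t1e <= t0e
        if empty:
            log.warning("segment %s shorter than its transition removal: empty window", label)
            t1e = t0e
        windows.append(StimulusWindow(i, seg.kind, label, t0e, t1e, empty))
    return windows


def mean_target_deviation(
    series: pd.DataFrame,
    protocol: StimulusProtocol,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DeviationReport:
    """Per-stimulus deviation of a measured inspired-CO2 series.

    ``series`` holds ``t_s`` (protocol clock, s) and ``value`` (volume %),
    e.g. per-breath inspired means or binned aggregate means.  Samples are
    matched to segments with the protocol's half-open boundaries, so a
    sample exactly on a join belongs to the later segment.
    """
    if series.empty:
        raise MetricsError("empty measured series")
    t = series["t_s"].to_numpy(float)
    v = series["value"].to_numpy(float)
    finite = np.isfinite(v)
    t, v = t[finite], v[finite]
    if len(t) == 0:
        raise MetricsError("measured series contains no finite values")
    if t.max() >= protocol.duration + 1e-6:
        raise MetricsError(
            f"series extends to {t.max():.1f} s, beyond the {protocol.duration:.1f} s protocol"
        )

    rng = np.random.default_rng(seed)
    alpha = 0.5 * (1.0 - ci_level)
    rows = []
    for w in stimulus_windows(protocol):
        m = (t >= w.t_start) & (t < w.t_end)
        n = int(m.sum())
        if w.empty or n == 0:
            rows.append(
                {
                    "stimulus": w.label,
                    "kind": w.kind,
                    "signed_mean_pp": np.nan,
                    "abs_mean_pp": np.nan,
                    "ci_low_pp": np.nan,
                    "ci_high_pp": np.nan,
                    "n": 0,
                }
            )
            continue
        target = np.array([100.0 * target_fco2i_at(protocol, ti) for ti in t[m]])
        dev = v[m] - target
        draws = rng.integers(0, n, size=(n_boot, n))
        boot = dev[draws].mean(axis=1)
        rows.append(
            {
                "stimulus": w.label,
                "kind": w.kind,
                "signed_mean_pp": float(dev.mean()),
                "abs_mean_pp": float(np.abs(dev).mean()),
                "ci_low_pp": float(np.quantile(boot, alpha)),
                "ci_high_pp": float(np.quantile(boot, 1.0 - alpha)),
                "n": n,
            }
        )
    entries = pd.DataFrame(rows)
    stim = entries[(entries["kind"] != "baseline") & (entries["n"] > 0)]
    overall = float(stim["abs_mean_pp"].max()) if len(stim) else float("nan")
    return DeviationReport(entries=entries, overall_max_abs_pp=overall, ci_scope="samples")
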