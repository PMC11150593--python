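"""Breath-by-breath analysis of gas-analyzer traces.

Takes a uniformly sampled CO2/O2 concentration record (volume percent,
~60 Hz) and recovers, fully automatically: breath phases, per-breath
inspired peak/baseline/mean and end-tidal values, a time-aligned series,
and binned cross-run aggregates with bootstrap confidence intervals.

Phase detection is threshold-based with an adaptive threshold (midpoint of
a rolling minimum/maximum).  Ventilated (test-lung) traces are segmented on
the CO2 channel.  Spontaneous traces are segmented on the O2 channel —
expired gas is always O2-poor relative to inspired gas by VO2/VA, whereas
the CO2 contrast briefly vanishes (and flips sign) whenever a stimulus
pushes the inspired level through the alveolar level — and each candidate
expiration must additionally pass an exponential-shape test on the
inspiratory O2 rebound before it is accepted, which rejects artifacts that
merely cross the threshold.

All accept/reject decisions are data-driven; there is no interactive
correction step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisError",
    "NoBreathsDetectedError",
    "BreathPhase",
    "AggregateSeries",
    "detect_breath_phases",
    "extract_breath_records",
    "analyze_trace",
    "align_and_resample",
    "records_to_series",
    "bin_and_aggregate",
    "to_partial_pressure",
]

#: Time shift applied to ventilated-mode series: 3 s analyzer sampling delay
#: plus ~5 s of circuit dead-space transport at typical ventilator settings.
VENTILATED_TIME_SHIFT_S = 8.0

RECORD_COLUMNS = [
    "t_s",
    "insp_co2_peak",
    "insp_co2_base",
    "insp_co2_mean",
    "insp_o2_peak",
    "insp_o2_base",
    "insp_o2_mean",
    "et_co2",
    "et_o2",
    "insp_start_s",
    "exp_end_s",
]


class AnalysisError(ValueError):
    pass


class NoBreathsDetectedError(AnalysisError):
    pass


@dataclass(frozen=True)
class BreathPhase:
    """One breath: inspiration followed by the accepted expiration (s)."""

    insp_start: float
    insp_end: float
    exp_start: float
    exp_end: float

    def __post_init__(self) -> None:
        if not (self.insp_start < self.insp_end <= self.exp_start < self.exp_end):
            raise AnalysisError(f"inconsistent breath phase {self}")


@dataclass
class AggregateSeries:
    """Binned cross-run aggregate: bin centers, mean and 95 % CI."""

    data: pd.DataFrame  # bin_t_s, mean, ci_low, ci_high, n
    bin_width: float
    n_runs: int


def _smooth(x: np.ndarray, samples: int) -> np.ndarray:
    if samples <= 1:
        return x
    return (
        pd.Series(x).rolling(samples, center=True, min_periods=1).median().to_numpy()
    )


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of contiguous True stretches."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))

def _rebound_shape_ok(o2: np.ndarray, r2_min: float, rise_min: float = 0.05) -> bool:
    """Does the post-expiration O2 segment look like an exponential rebound?

    Fits ``y = A - B exp(-t/tau)`` via log-linearisation against the segment
    ceiling and requires a net rise plus a minimum goodness of fit.
    """
    if len(o2) < 6:
        return False
    peak = int(np.argmax(o2))
    if peak >= 5:
        o2 = o2[: peak + 1]  # fit the rise only, not the ensuing plateau/fall
    if float(np.max(o2)) - o2[0] < max(rise_min, 0.3):
        return False
    ceiling = float(np.max(o2)) + 0.02
    z = np.log(ceiling - o2)
    x = np.arange(len(z), dtype=float)
    slope, intercept = np.polyfit(x, z, 1)
    if slope >= 0:
        return False
    resid = z - (slope * x + intercept)
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    if ss_tot <= 0:
        return False
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2 >= r2_min


def detect_breath_phases(
    trace: pd.DataFrame,
    mode: str = "spontaneous",
    min_duration: float = 0.5,
    min_excursion: float = 0.3,
    window_s: float = 10.0,
    shape_r2: float = 0.5,
) -> list[BreathPhase]:
    """Segment an analyzer trace into breaths.

    Parameters
    ----------
    trace:
        DataFrame with columns ``t_s``, ``fco2_percent``, ``fo2_percent``,
        uniformly sampled.
    mode:
        ``"ventilated"`` (CO2 threshold crossings) or ``"spontaneous"``
        (O2 threshold crossings plus the rebound shape test).
    min_duration, min_excursion:
        Acceptance floor for an expiration: at least this long (s) and with
        at least this much local signal excursion (percentage points);
        shorter/flatter events are treated as analyzer glitches.

    Raises
    ------
    NoBreathsDetectedError
        For flat traces or when no candidate survives the acceptance rules.
    """
    if mode not in ("ventilated", "spontaneous"):
        raise AnalysisError(f"unknown analysis mode {mode!r}")
    if len(trace) < 10:
        raise NoBreathsDetectedError("trace too short")
    t = trace["t_s"].to_numpy(float)
    co2 = trace["fco2_percent"].to_numpy(float)
    o2 = trace["fo2_percent"].to_numpy(float)
    dt = float(np.median(np.diff(t)))

    k_med = max(3, int(round(0.08 / dt)) | 1)
    co2_s = _smooth(co2, k_med)
    o2_s = _smooth(o2, k_med)
    sig = co2_s if mode == "ventilated" else -o2_s

    win = max(5, int(round(window_s / dt)))
    s = pd.Series(sig)
    rmin = s.rolling(win, center=True, min_periods=1).min().to_numpy()
    rmax = s.rolling(win, center=True, min_periods=1).max().to_numpy()
    threshold = 0.5 * (rmin + rmax)

    co2_series = pd.Series(co2_s)
    co2_amp = (
        co2_series.rolling(win, center=True, min_periods=1).max()
        - co2_series.rolling(win, center=True, min_periods=1).min()
    ).to_numpy()
    o2_amp = rmax - rmin if mode == "spontaneous" else np.zeros_like(co2_amp)

    if np.ptp(sig) < 0.05:
        raise NoBreathsDetectedError("flat trace: no threshold crossings")

    candidates = _true_runs(sig > threshold)
    accepted: list[tuple[int, int]] = []
    min_len = int(round(min_duration / dt))
    for k, (start, end) in enumerate(candidates):
        if end - start < min_len:
            continue
        mid = (start + end) // 2
        if mode == "ventilated":
            if co2_amp[mid] < min_excursion:
                continue
        else:
            if co2_amp[mid] < min_excursion and o2_amp[mid] < min_excursion:
                continue
            # fit the inspiratory O2 rebound, stopping before the next
            # candidate expiration begins
            nxt = candidates[k + 1][0] if k + 1 < len(candidates) else len(o2_s)
            seg_end = min(end + int(round(1.5 / dt)), nxt, len(o2_s))
            # a candidate truncated by the end of the recording has no
            # rebound to judge; keep it rather than drop a real breath
            truncated = len(o2_s) - end < int(round(0.3 / dt))
            if not truncated and not _rebound_shape_ok(o2_s[end:seg_end], shape_r2):
                continue
        accepted.append((start, end))

    phases: list[BreathPhase] = []
    min_gap = max(2, int(round(0.2 / dt)))
    prev_end = 0 if (not accepted or accepted[0][0] > min_gap) else None
    for start, end in accepted:
        if prev_end is not None and start - prev_end >= min_gap:
            phases.append(
                BreathPhase(
                    insp_start=t[prev_end],
                    insp_end=t[start],
                    exp_start=t[start],
                    exp_end=t[min(end, len(t) - 1)],
                )
            )
        prev_end = end
    if not phases:
        raise NoBreathsDetectedError("no breaths satisfied the acceptance rules")
    return phases


def _strip_edges(seg: np.ndarray, frac: float = 0.1) -> tuple[int, int]:
    """Indices ``(j0, j1)`` of the settled interior of an inspired window.

    Phase edges found by threshold crossing sit mid-transition, so the raw
    window starts on the analyzer decay from the end-tidal plateau and may
    end on the rise into the next expiration.  Both edges are stripped down
    to within ``frac`` of the window floor; flat windows are untouched.
    """
    vmin = float(np.min(seg))
    j0, j1 = 0, len(seg)
    v0 = float(seg[0])
    if v0 - vmin > 0.1:
        below = np.nonzero(seg <= vmin + frac * (v0 - vmin))[0]
        if len(below):
            j0 = int(below[0])
    v_end = float(seg[-1])
    if v_end - vmin > 0.1:
        below = np.nonzero(seg <= vmin + frac * (v_end - vmin))[0]
        if len(below):
            j1 = int(below[-1]) + 1
    if j1 - j0 < 2:
        return 0, len(seg)
    return j0, j1


def _plateau_end(seg: np.ndarray, frac: float = 0.1) -> int:
    """Index one past the last sample still on the expiratory CO2 plateau.

    The detected expiration end sits on the decay edge; the end-tidal value
    must come from the plateau itself.
    """
    vmax, vmin = float(np.max(seg)), float(np.min(seg))
    if vmax - vmin <= 0.2:
        return len(seg)
    on_plateau = np.nonzero(seg >= vmax - frac * (vmax - vmin))[0]
    return int(on_plateau[-1]) + 1 if len(on_plateau) else len(seg)


def extract_breath_records(
    trace: pd.DataFrame,
    phases: list[BreathPhase],
    system: str = "additional",
    early_fraction: float = 0.5,
    et_window: float = 0.1,
) -> pd.DataFrame:
    """Per-breath inspired and end-tidal values.

    Inspired peak/baseline are the extrema of the (lightly smoothed) CO2
    and O2 signals over the inspired analysis window; ``*_mean`` columns
    hold the unsmoothed window mean, the representative inspired value.
    For ``system="reservoir"`` the window is restricted to the first
    ``early_fraction`` of the inspiration (late declines toward room air
    are dead-space gas and deliberately ignored).  End-tidal values are the
    median of the final ``et_window`` seconds of the expiration, which
    resists single-sample noise.  Breaths are timestamped at the centre of
    the inspired analysis window.
    """
    if system not in ("additional", "reservoir"):
        raise AnalysisError(f"unknown system {system!r}")
    if not phases:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    t = trace["t_s"].to_numpy(float)
    co2 = trace["fco2_percent"].to_numpy(float)
    o2 = trace["fo2_percent"].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    k_med = max(3, int(round(0.08 / dt)) | 1)
    co2_s = _smooth(co2, k_med)
    o2_s = _smooth(o2, k_med)

    rows = []
    for ph in phases:
        i0, i1 = np.searchsorted(t, [ph.insp_start, ph.insp_end])
        e0, e1 = np.searchsorted(t, [ph.exp_start, ph.exp_end])
        if i1 - i0 < 3 or e1 - e0 < 2:
            continue
        # reservoir mode: restrict to the early inspiration before stripping,
        # so the late decline toward room air never defines the window floor
        i1_eff = (
            max(i0 + int(round(early_fraction * (i1 - i0))), i0 + 3)
            if system == "reservoir"
            else i1
        )
        s0, s1 = _strip_edges(co2_s[i0:i1_eff])
        j0, j1 = i0 + s0, i0 + s1
        if j1 - j0 < 2:
            j0, j1 = i0, i1_eff
        n_et = max(2, int(round(et_window / dt)))
        e_end = e0 + _plateau_end(co2_s[e0:e1])
        et_slice = slice(max(e_end - n_et, e0), e_end)
        rows.append(
            {
                "t_s": 0.5 * (t[j0] + t[j1 - 1]),
                "insp_co2_peak": float(np.max(co2_s[j0:j1])),
                "insp_co2_base": float(np.min(co2_s[j0:j1])),
                "insp_co2_mean": float(np.mean(co2[j0:j1])),
                "insp_o2_peak": float(np.max(o2_s[j0:j1])),
                "insp_o2_base": float(np.min(o2_s[j0:j1])),
                "insp_o2_mean": float(np.mean(o2[j0:j1])),
                "et_co2": float(np.median(co2[et_slice])),
                "et_o2": float(np.median(o2[et_slice])),
                "insp_start_s": ph.insp_start,
                "exp_end_s": ph.exp_end,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def analyze_trace(
    trace: pd.DataFrame, mode: str = "spontaneous", system: str = "additional", **kwargs
) -> pd.DataFrame:
    """Detection and extraction in one step; returns the records table."""
    phases = detect_breath_phases(trace, mode=mode, **kwargs)
    return extract_breath_records(trace, phases, system=system)


def records_to_series(
    records: pd.DataFrame, channel: str = "insp_co2_mean", time_shift: float = 0.0
) -> pd.DataFrame:
    """Per-breath series ``(t_s, value)`` with an optional time shift.

    ``time_shift`` is subtracted from the record times; pass the analyzer
    sampling delay to place the series on the protocol clock.
    """
    return pd.DataFrame(
        {"t_s": records["t_s"].to_numpy(float) - time_shift, "value": records[channel].to_numpy(float)}
    )


def align_and_resample(
    records: pd.DataFrame,
    mode: str,
    channel: str = "insp_co2_mean",
    grid_step: float = 1.0,
    sampling_delay: float = 0.0,
) -> pd.DataFrame:
    """Linear interpolation of per-breath values onto a uniform grid.

    Ventilated mode shifts times by 8 s toward zero (analyzer sampling
    delay plus circuit dead-space transport); spontaneous mode shifts by
    ``sampling_delay`` only, which defaults to 0 — the 5 s binning stage
    absorbs the residual delay there.
    """
    if len(records) < 2:
        raise AnalysisError("need at least 2 breath records to resample")
    shift = VENTILATED_TIME_SHIFT_S if mode == "ventilated" else sampling_delay
    t = records["t_s"].to_numpy(float) - shift
    v = records[channel].to_numpy(float)
    order = np.argsort(t)
    t, v = t[order], v[order]
    start = np.ceil(t[0] / grid_step) * grid_step
    grid = np.arange(start, t[-1] + 1e-9, grid_step)
    return pd.DataFrame({"t_s": grid, "value": np.interp(grid, t, v)})


def bin_and_aggregate(
    runs: list[pd.DataFrame],
    bin_width: float = 5.0,
    baseline_window: float = 60.0,
    baseline_subtract: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> AggregateSeries:
    """Bin per-run series and aggregate across runs with bootstrap CIs.

    Each run is a ``(t_s, value)`` frame.  With ``baseline_subtract`` (the
    end-tidal convention) each run is first reduced by its own mean over
    the initial ``baseline_window`` seconds.  Per bin, the mean of the
    per-run bin means is reported together with a seeded nonparametric
    bootstrap CI — over runs when several are given, over samples within
    the bin for a single run.  Bins no run contributes to are reported with
    ``n = 0`` and NaN values rather than zeros.
    """
    if not runs:
        raise AnalysisError("need at least one run")
    rng = np.random.default_rng(seed)
    prepared = []
    t_max = 0.0
    for run in runs:
        t = run["t_s"].to_numpy(float)
        v = run["value"].to_numpy(float)
        keep = t >= 0
        t, v = t[keep], v[keep]
        if baseline_subtract:
            base = v[t < baseline_window]
            if len(base) == 0:
                raise AnalysisError("no samples inside the baseline window")
            v = v - base.mean()
        prepared.append((t, v))
        if len(t):
            t_max = max(t_max, t[-1])

    n_bins = int(np.floor(t_max / bin_width)) + 1
    per_run = np.full((len(prepared), n_bins), np.nan)
    sample_bins: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    for r, (t, v) in enumerate(prepared):
        idx = np.floor(t / bin_width).astype(int)
        for b in range(n_bins):
            vals = v[idx == b]
            if len(vals):
                per_run[r, b] = vals.mean()
                sample_bins[b].append(vals)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_run, axis=0)
    n_per_bin = np.sum(~np.isnan(per_run), axis=0)
    mean[n_per_bin == 0] = np.nan

    alpha = 0.5 * (1.0 - ci_level)
    ci_low = np.full(n_bins, np.nan)
    ci_high = np.full(n_bins, np.nan)
    n_runs = len(prepared)
    if n_runs > 1:
        draws = rng.integers(0, n_runs, size=(n_boot, n_runs))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            boot = np.nanmean(per_run[draws, :], axis=1)  # n_boot x n_bins
            ci_low = np.nanquantile(boot, alpha, axis=0)
            ci_high = np.nanquantile(boot, 1.0 - alpha, axis=0)
    else:
        for b in range(n_bins):
            if not sample_bins[b]:
                continue
            vals = np.concatenate(sample_bins[b])
            draws = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boot = vals[draws].mean(axis=1)
            ci_low[b] = np.quantile(boot, alpha)
            ci_high[b] = np.quantile(boot, 1.0 - alpha)

    data = pd.DataFrame(
        {
            "bin_t_s": (np.arange(n_bins) + 0.5) * bin_width,
            "mean": mean,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "n": n_per_bin,
        }
    )
    return AggregateSeries(data=data, bin_width=bin_width, n_runs=n_runs)


def to_partial_pressure(
    fraction_percent, p_atm: float = 760.0, p_h2o: float = 47.0
):
    """Convert a dry-gas volume percent to partial pressure in mmHg.

    ``P = (percent / 100) * (P_atm - P_H2O)`` with the conventional
    760 / 47 mmHg figures at body temperature.  Linear and invertible;
    accepts scalars or arrays.
    """
    arr = np.asarray(fraction_percent, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise AnalysisError("percent values must lie in [0, 100]")
    out = arr / 100.0 * (p_atm - p_h2o)
    return float(out) if np.isscalar(fraction_percent) else out
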