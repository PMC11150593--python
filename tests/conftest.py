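"""Shared fixtures: protocols, synthetic capnogram builders, short runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

from co2challenge import build_default_protocol
from co2challenge.protocol import StimulusProtocol, StimulusSegment


@pytest.fixture(scope="session")
def default_protocol():
    return build_default_protocol()


@pytest.fixture(scope="session")
def short_box_protocol():
    """30 s baseline followed by a long 5 % box (washout studies)."""
    return StimulusProtocol(
        (StimulusSegment("baseline", 30.0), StimulusSegment("box", 150.0, level=0.05)),
        name="box-5pct",
    )


def make_capnogram(
    rate_bpm: float = 12.0,
    duration: float = 60.0,
    fs: float = 60.0,
    insp_co2: float = 0.0,
    exp_co2: float = 5.0,
    insp_o2: float = 20.9,
    exp_o2: float = 16.0,
    exp_fraction: float = 0.5,
    tau: float = 0.15,
    noise_sd: float = 0.0,
    seed: int = 0,
    start_phase: str = "insp",
) -> pd.DataFrame:
    """Synthetic analyzer trace: a smoothed square-wave capnogram.

    Each breath period starts with the inspiration (low CO2, high O2)
    unless ``start_phase`` is ``"exp"``.  A first-order response with time
    constant ``tau`` reproduces the exponential transitions of a sidestream
    analyzer.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    period = 60.0 / rate_bpm
    phase = (t % period) / period
    exp_mask = phase >= (1.0 - exp_fraction) if start_phase == "insp" else phase < exp_fraction
    co2 = np.where(exp_mask, exp_co2, insp_co2).astype(float)
    o2 = np.where(exp_mask, exp_o2, insp_o2).astype(float)
    if tau > 0:
        k = min(1.0 / (fs * tau), 1.0)
        co2, _ = lfilter([0.0, k], [1.0, k - 1.0], co2, zi=[co2[0]])
        o2, _ = lfilter([0.0, k], [1.0, k - 1.0], o2, zi=[o2[0]])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        co2 = co2 + rng.normal(0.0, noise_sd, n)
        o2 = o2 + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"t_s": t, "fco2_percent": co2, "fo2_percent": o2, "flow_lpm": 0.0})


@pytest.fixture
def capnogram_factory():
    return make_capnogram
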