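"""Quadrature rotary-encoder decoding into gait distance and speed.

The running wheel (90 mm diameter) drives a 256 counts-per-revolution
encoder whose two output channels are square waves in quadrature.  A
4x state-machine decode (every edge counts) converts the channel pair
into signed counts; distance follows from counts / (4 * cpr) times the
wheel circumference and speed is binned into 1 s intervals for
synchronization with imaging timestamps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import get_logger

__all__ = ["decode_quadrature", "synchronize"]

log = get_logger("awakeretina.gait")

# gray-code state index for (A, B): forward rotation steps +1 through
# 00 -> 01 -> 11 -> 10
_STATE_INDEX = np.array([0, 1, 3, 2])  # index by A*2 + B


def decode_quadrature(
    chA: np.ndarray,
    chB: np.ndarray,
    sample_rate: float,
    cpr: int = 256,
    wheel_diameter: float = 0.090,
) -> dict:
    """Decode A/B pulse trains into cumulative distance and 1 s speeds.

    Returns a dict with the per-sample signed cumulative distance (m),
    a per-1-s-bin speed table (magnitude, m/s), the total signed count,
    and the illegal-transition count (both channels toggling within one
    sample; > 1 % of transitions logs a warning).
    """
    a = (np.asarray(chA) > 0).astype(np.int8)
    b = (np.asarray(chB) > 0).astype(np.int8)
    if a.shape != b.shape:
        raise ValueError("channels must have the same length")
    if cpr <= 0 or wheel_diameter <= 0:
        raise ValueError("cpr and wheel_diameter must be positive")
    states = _STATE_INDEX[(a.astype(int) << 1) | b.astype(int)]
    d = np.diff(states)
    step = ((d + 1) % 4) - 1  # -1, 0, +1 legal; +2/-2 illegal
    illegal = step == 2
    n_trans = int(np.count_nonzero(d))
    n_illegal = int(illegal.sum())
    step = np.where(illegal, 0, step)
    if n_trans and n_illegal / n_trans > 0.01:
        log.warning("%.1f%% illegal quadrature transitions",
                    100.0 * n_illegal / n_trans)
    counts = np.concatenate([[0], np.cumsum(step)])
    circumference = np.pi * wheel_diameter
    distance = counts / (4.0 * cpr) * circumference  # m, signed
    t = np.arange(a.size) / sample_rate

    n_bins = max(int(np.floor(t[-1])) + 1, 1) if a.size else 0
    bins = []
    for k in range(n_bins):
        sel = (t >= k) & (t < k + 1)
        if not sel.any():
            bins.append(dict(time_s=k + 0.5, speed_m_s=np.nan))
            continue
        i0, i1 = np.nonzero(sel)[0][[0, -1]]
        dt = t[i1] - t[i0]
        dd = abs(distance[i1] - distance[i0])
        bins.append(dict(time_s=k + 0.5, speed_m_s=dd / dt if dt > 0 else 0.0))
    return {
        "time_s": t,
        "distance_m": distance,
        "counts": counts,
        "speed_bins": pd.DataFrame(bins),
        "n_illegal": n_illegal,
        "n_transitions": n_trans,
        "cpr": cpr,
        "wheel_diameter_m": wheel_diameter,
    }


def synchronize(gait: dict, imaging_timestamps: np.ndarray) -> pd.DataFrame:
    """Pair each imaging sample with the 1 s gait bin containing it.

    Samples outside the gait recording are marked missing (NaN speed),
    never zero.  Raises when the time ranges do not overlap at all.
    """
    ts = np.asarray(imaging_timestamps, dtype=float)
    bins = gait["speed_bins"]
    bin_start = bins["time_s"].to_numpy() - 0.5
    lo, hi = bin_start[0], bin_start[-1] + 1.0
    if ts.size == 0 or ts.max() < lo or ts.min() >= hi:
        raise ValueError("imaging and gait recordings do not overlap in time")
    idx = np.floor(ts - lo).astype(int)
    inside = (idx >= 0) & (idx < len(bins))
    speed = np.full(ts.size, np.nan)
    speed[inside] = bins["speed_m_s"].to_numpy()[idx[inside]]
    return pd.DataFrame({
        "imaging_time_s": ts,
        "gait_bin": np.where(inside, idx, -1),
        "gait_speed_m_s": speed,
    })
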