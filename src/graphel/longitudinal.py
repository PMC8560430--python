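"""Longitudinal 1 kHz impedance tracking for microelectrode arrays.

A channel is *working* on a given day when its 1 kHz impedance
magnitude is measurable and strictly below a threshold (2 MΩ by
default, the practical limit for a usable signal-to-noise ratio on
high-input-impedance acquisition systems).  Unmeasurable channels —
open-circuit failures — are recorded as NaN.  Because the failures seen
in soak tests are irreversible opens, a channel only counts as failed
from the first day of a *persistent* nonworking stretch that lasts to
the end of the record; a single bad measurement is not failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import numpy.typing as npt
import pandas as pd

__all__ = [
    "WORKING_THRESHOLD_OHM",
    "ChannelTimecourse",
    "ArraySummary",
    "classify_channel",
    "array_yield",
    "summarize_timecourse",
    "detect_failure_day",
    "read_timecourse_csv",
    "write_summary_csv",
]

WORKING_THRESHOLD_OHM = 2e6


@dataclass(frozen=True)
class ChannelTimecourse:
    """1 kHz impedance of one channel over days; NaN = unmeasurable/open."""

    channel_id: str
    timepoints: npt.NDArray[np.float64]
    z_1khz: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        z = np.asarray(self.z_1khz, dtype=float)
        if t.size == 0 or t.shape != z.shape:
            raise ValueError("timepoints and z_1khz must be equal-length and non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(z[~np.isnan(z)] <= 0):
            raise ValueError("impedance values must be positive where present")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "z_1khz", z)


@dataclass(frozen=True)
class ArraySummary:
    """Per-timepoint working-channel statistics for one array.

    ``mean`` / ``sd`` are over working channels only (sample SD, n−1;
    NaN where fewer than 2 working channels).  ``yield_fraction`` counts
    working channels over all channels.  ``failure_day`` is the first
    day from which no channel works again, or None.
    """

    timepoints: npt.NDArray[np.float64]
    mean: npt.NDArray[np.float64]
    sd: npt.NDArray[np.float64]
    yield_fraction: npt.NDArray[np.float64]
    n_working: npt.NDArray[np.int_]
    n_channels: int
    failure_day: float | None


def classify_channel(z_1khz: float | None, threshold: float = WORKING_THRESHOLD_OHM) -> str:
    """'working' iff the value is present and strictly below threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if z_1khz is None or (isinstance(z_1khz, float) and math.isnan(z_1khz)):
        return "nonworking"
    return "working" if z_1khz < threshold else "nonworking"


def _working_mask(values: npt.NDArray[np.float64], threshold: float) -> npt.NDArray[np.bool_]:
    v = np.asarray(values, dtype=float)
    return ~np.isnan(v) & (v < threshold)


def array_yield(values: Sequence[float], threshold: float = WORKING_THRESHOLD_OHM) -> float:
    """Fraction of channels working (absent values count as nonworking)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(
        [np.nan if x is None else float(x) for x in values], dtype=float
    )
    if v.size == 0:
        raise ValueError("empty channel list")
    return float(np.count_nonzero(_working_mask(v, threshold)) / v.size)


def _union_timepoints(channels: Sequence[ChannelTimecourse]) -> npt.NDArray[np.float64]:
    return np.unique(np.concatenate([c.timepoints for c in channels]))


def summarize_timecourse(
    channels: Sequence[ChannelTimecourse],
    threshold: float = WORKING_THRESHOLD_OHM,
) -> ArraySummary:
    """Mean/SD/yield over working channels at each timepoint.

    Channels may cover different timepoints; a channel not measured at a
    timepoint counts as nonworking there (union-of-days axis).
    """
    channels = list(channels)
    if not channels:
        raise ValueError("no channels given")
    days = _union_timepoints(channels)
    n_ch = len(channels)
    grid = np.full((n_ch, days.size), np.nan)
    for i, c in enumerate(channels):
        idx = np.searchsorted(days, c.timepoints)
        grid[i, idx] = c.z_1khz

    working = _working_mask(grid, threshold)
    n_working = working.sum(axis=0)
    mean = np.full(days.size, np.nan)
    sd = np.full(days.size, np.nan)
    for j in range(days.size):
        vals = grid[working[:, j], j]
        if vals.size >= 1:
            mean[j] = vals.mean()
        if vals.size >= 2:
            sd[j] = vals.std(ddof=1)

    yield_frac = n_working / n_ch
    failure_day = None
    dead = ~np.any(working, axis=0)
    if dead[-1]:
        # first day of the terminal all-dead stretch
        j = days.size - 1
        while j > 0 and dead[j - 1]:
            j -= 1
        failure_day = float(days[j])

    return ArraySummary(
        timepoints=days,
        mean=mean,
        sd=sd,
        yield_fraction=yield_frac,
        n_working=n_working.astype(int),
        n_channels=n_ch,
        failure_day=failure_day,
    )


def detect_failure_day(
    channel: ChannelTimecourse, threshold: float = WORKING_THRESHOLD_OHM
) -> float | None:
    """First day of the terminal nonworking stretch, or None.

    Failure must persist to the end of the record: a channel that is
    nonworking on one day but measurable again later has not failed
    (opens are irreversible).  A channel that never works fails at its
    first timepoint.
    """
    working = _working_mask(channel.z_1khz, threshold)
    if working[-1]:
        return None
    j = working.size - 1
    while j > 0 and not working[j - 1]:
        j -= 1
    return float(channel.timepoints[j])


# ---------------------------------------------------------------------------
# CSV interfaces (long format: array_id, channel_id, day, z_1khz_ohm)
# ---------------------------------------------------------------------------


def read_timecourse_csv(path) -> dict[str, list[ChannelTimecourse]]:
    """Read a long-format CSV into {array_id: [ChannelTimecourse, ...]}.

    Empty ``z_1khz_ohm`` cells mean unmeasurable (open) channels.
    """
    df = pd.read_csv(path, dtype={"array_id": str, "channel_id": str})
    required = {"array_id", "channel_id", "day", "z_1khz_ohm"}
    if not required.issubset(df.columns):
        raise ValueError(f"timecourse CSV needs columns {sorted(required)}")
    out: dict[str, list[ChannelTimecourse]] = {}
    for (array_id, channel_id), g in df.groupby(["array_id", "channel_id"], sort=True):
        g = g.sort_values("day")
        out.setdefault(array_id, []).append(
            ChannelTimecourse(
                channel_id=channel_id,
                timepoints=g["day"].to_numpy(dtype=float),
                z_1khz=g["z_1khz_ohm"].to_numpy(dtype=float),
            )
        )
    return out


def write_summary_csv(summary: ArraySummary, path) -> pd.DataFrame:
    """Write per-day summary (day, mean_ohm, sd_ohm, yield) to CSV."""
    df = pd.DataFrame(
        {
            "day": summary.timepoints,
            "mean_ohm": summary.mean,
            "sd_ohm": summary.sd,
            "yield": summary.yield_fraction,
        }
    )
    df.to_csv(path, index=False)
    return df
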