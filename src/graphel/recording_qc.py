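"""Chronic-recording quality metrics for ECoG traces.

Covers the metrics used to judge whether an implanted surface electrode
still records usefully: RMS noise on stimulus-free segments,
stimulus-locked trial averaging with per-epoch baseline subtraction,
onset-latency estimation against a baseline-SD criterion, and
trial-averaged short-time band power expressed in dB relative to the
pre-stimulus baseline (visual stimulation typically produces an
on-response tens of ms after stimulus onset and a sustained high-band
power increase, e.g. 140–200 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import numpy.typing as npt
from scipy import signal

__all__ = [
    "RecordingTrace",
    "StimulusProtocol",
    "EvokedResult",
    "BandPowerResult",
    "rms_noise",
    "epoch_and_average",
    "onset_latency",
    "band_power_spectrogram",
]


@dataclass(frozen=True)
class RecordingTrace:
    """Single-channel trace in µV at a fixed sampling rate."""

    samples: npt.NDArray[np.float64]
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if s.size == 0 or not np.all(np.isfinite(s)):
            raise ValueError("samples must be non-empty and finite")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> npt.NDArray[np.float64]:
        return self.start_time + np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus onset times (s) with per-trial duration and orientations.

    Default protocol: 4 s drifting-grating presentations, inter-stimulus
    interval 7–9 s, one of 12 orientations (30° apart) per trial.
    """

    onsets: npt.NDArray[np.float64]
    duration: float = 4.0
    isi_range: tuple[float, float] = (7.0, 9.0)
    orientations_deg: npt.NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        o = np.asarray(self.onsets, dtype=float)
        if o.size == 0 or np.any(np.diff(o) <= 0):
            raise ValueError("onsets must be non-empty and strictly increasing")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "onsets", o)
        if self.orientations_deg is not None:
            ori = np.asarray(self.orientations_deg, dtype=float)
            if ori.shape != o.shape:
                raise ValueError("one orientation per onset required")
            object.__setattr__(self, "orientations_deg", ori)

    @property
    def n_trials(self) -> int:
        return self.onsets.size


@dataclass(frozen=True)
class EvokedResult:
    """Trial-averaged peri-stimulus response."""

    times: npt.NDArray[np.float64]
    mean: npt.NDArray[np.float64]
    n_trials: int
    n_dropped: int


@dataclass(frozen=True)
class BandPowerResult:
    """Trial-averaged spectrogram in dB re pre-stimulus baseline."""

    times: npt.NDArray[np.float64]
    frequencies: npt.NDArray[np.float64]
    power_db: npt.NDArray[np.float64]  # (freq, time)
    band: tuple[float, float]
    band_timecourse_db: npt.NDArray[np.float64]
    n_trials: int


def rms_noise(trace: RecordingTrace, window: tuple[float, float] | None = None) -> float:
    """RMS of the mean-subtracted samples over a time window (µV).

    ``window`` is (start, stop) in the trace's time base; the whole
    trace is used when omitted.  For a sine of amplitude A this returns
    A/√2, and the estimator is scale-equivariant.
    """
    x = trace.samples
    if window is not None:
        t0, t1 = window
        i0 = int(np.ceil((t0 - trace.start_time) * trace.rate))
        i1 = int(np.floor((t1 - trace.start_time) * trace.rate))
        i0 = max(i0, 0)
        x = x[i0:i1]
    if x.size == 0:
        raise ValueError("empty RMS window")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def _epochs(trace: RecordingTrace, protocol: StimulusProtocol, window: tuple[float, float]):
    """Extract complete epochs as a (trial, sample) matrix."""
    pre, post = window
    if not pre <= 0 <= post or pre == post:
        raise ValueError("window must straddle the stimulus: pre <= 0 <= post")
    n_pre = int(round(-pre * trace.rate))
    n_post = int(round(post * trace.rate))
    n = trace.samples.size
    rows, dropped = [], 0
    for onset in protocol.onsets:
        i = int(round((onset - trace.start_time) * trace.rate))
        if i - n_pre < 0 or i + n_post > n:
            dropped += 1
            continue
        rows.append(trace.samples[i - n_pre : i + n_post])
    if not rows:
        raise ValueError("no complete epochs within the trace")
    times = (np.arange(n_pre + n_post) - n_pre) / trace.rate
    return np.asarray(rows), times, n_pre, dropped


def epoch_and_average(
    trace: RecordingTrace,
    protocol: StimulusProtocol,
    window: tuple[float, float] = (-0.5, 1.0),
) -> EvokedResult:
    """Stimulus-locked trial average with per-epoch baseline subtraction.

    Each epoch's pre-stimulus mean is subtracted before averaging;
    epochs extending past the trace are dropped and counted.  The
    average is invariant to trial order and its noise SD shrinks as
    1/√n_trials.
    """
    rows, times, n_pre, dropped = _epochs(trace, protocol, window)
    if n_pre > 0:
        rows = rows - rows[:, :n_pre].mean(axis=1, keepdims=True)
    return EvokedResult(times=times, mean=rows.mean(axis=0), n_trials=rows.shape[0], n_dropped=dropped)


def onset_latency(
    evoked: EvokedResult,
    k: float = 3.0,
    sustained_ms: float = 20.0,
    rate: float | None = None,
) -> float | None:
    """Response onset latency (ms) after the stimulus, or None.

    The latency is the first post-stimulus time at which |response|
    exceeds ``k`` × SD of the pre-stimulus baseline and stays above it
    for ``sustained_ms``.  With a zero-variance baseline any nonzero
    excursion triggers; a flat trace yields None.
    """
    t, x = evoked.times, evoked.mean
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    base = x[t < 0]
    if base.size == 0:
        raise ValueError("no pre-stimulus baseline in the evoked window")
    sd = float(base.std(ddof=0))
    thresh = k * sd
    n_sustained = max(int(round(sustained_ms * 1e-3 * rate)), 1)
    post = t >= 0
    above = (np.abs(x) > thresh) & post
    idx = np.flatnonzero(above)
    for i in idx:
        j = min(i + n_sustained, above.size)
        if j - i < n_sustained:
            break
        if above[i:j].all():
            return float(t[i] * 1e3)
    return None


def band_power_spectrogram(
    trace: RecordingTrace,
    protocol: StimulusProtocol,
    band: tuple[float, float] = (140.0, 200.0),
    window: tuple[float, float] = (-1.0, 4.0),
    nperseg_s: float = 0.256,
    overlap: float = 0.75,
) -> BandPowerResult:
    """Trial-averaged short-time power in dB re pre-stimulus baseline.

    Per epoch a Hann spectrogram (``nperseg_s`` window, 75% overlap by
    default) is computed; power is averaged over trials, then each
    frequency row is referenced to its own mean over pre-stimulus time
    bins (dB).  The band time course averages the dB map over frequency
    bins whose centers lie inside the closed band.
    """
    lo, hi = band
    if hi <= lo or lo < 0:
        raise ValueError("band must be a positive-width interval")
    if trace.rate <= 2 * hi:
        raise ValueError("band extends beyond Nyquist: need rate > 2 × upper edge")
    rows, _, _, _ = _epochs(trace, protocol, window)
    nperseg = int(round(nperseg_s * trace.rate))
    noverlap = int(round(overlap * nperseg))
    f, t_spec, sxx = signal.spectrogram(
        rows, fs=trace.rate, window="hann", nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    sxx = sxx.mean(axis=0)  # (freq, time), trial-averaged
    t_spec = t_spec + window[0]

    # only windows lying fully before the stimulus: a straddling window
    # would leak stimulus power into the baseline
    baseline_bins = t_spec < -nperseg_s / 2.0
    if not baseline_bins.any():
        raise ValueError("no fully pre-stimulus spectrogram bins; widen the window")
    baseline = sxx[:, baseline_bins].mean(axis=1, keepdims=True)
    power_db = 10.0 * np.log10(np.maximum(sxx, 1e-300) / np.maximum(baseline, 1e-300))

    in_band = (f >= lo) & (f <= hi)
    if not in_band.any():
        raise ValueError("no spectrogram bins inside the band")
    # band time course: average linear power over the band first, then dB
    # (averaging dB per bin would be biased low for few trials)
    band_power = sxx[in_band].mean(axis=0)
    band_base = baseline[in_band].mean()
    band_db = 10.0 * np.log10(np.maximum(band_power, 1e-300) / max(band_base, 1e-300))
    return BandPowerResult(
        times=t_spec,
        frequencies=f,
        power_db=power_db,
        band=(lo, hi),
        band_timecourse_db=band_db,
        n_trials=rows.shape[0],
    )
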