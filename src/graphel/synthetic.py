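"""Seeded synthetic-data generators for every pipeline input.

No public dataset of graphene-electrode soak tests exists, so each
consumer module here has a generator that emulates the corresponding
measurement:

* impedance spectra from the equivalent circuit with multiplicative
  proportional noise,
* longitudinal 1 kHz impedance time courses with the characteristic
  initial drop to a plateau and injected irreversible open failures,
* microscope images with a permeation lobe growing from an
  electrode-opening boundary, and
* ECoG-like traces: 1/f (pink) background, a stimulus-locked
  on-response at a configurable latency, and a band-limited power
  increase during the stimulus.

Every generator is a pure function of its arguments: one top-level seed
is expanded into a fixed per-generator substream (``numpy``
``SeedSequence`` spawn keys), so adding a generator never perturbs the
output of an existing one.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import numpy.typing as npt
from scipy import signal

from graphel.eis_model import CircuitParameters, ImpedanceSpectrum, simulate_spectrum
from graphel.longitudinal import ChannelTimecourse
from graphel.permeation import MicroscopyImage
from graphel.recording_qc import RecordingTrace, StimulusProtocol

__all__ = [
    "rng_for",
    "gen_eis_spectrum",
    "gen_impedance_timecourse",
    "gen_permeation_image",
    "gen_bimodal_image",
    "gen_ecog",
]

#: Fixed substream ids; never renumber (fixture stability).
_STREAMS = {"eis": 1, "timecourse": 2, "image": 3, "ecog": 4, "bimodal": 5}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named substream of a top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


def gen_eis_spectrum(
    params: CircuitParameters,
    frequencies=None,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Noisy spectrum: Z(f) · (1 + ε_re + j·ε_im), ε ~ N(0, noise_frac).

    Noise is proportional and independent per frequency and per complex
    component; ``noise_frac = 0`` reproduces the deterministic forward
    simulation exactly.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    clean = simulate_spectrum(params, frequencies)
    if noise_frac == 0:
        return clean
    rng = rng_for(seed, "eis")
    eps = rng.normal(0.0, noise_frac, (2, len(clean)))
    return ImpedanceSpectrum(clean.frequencies, clean.z * (1.0 + eps[0] + 1j * eps[1]))


def gen_impedance_timecourse(
    n_channels: int = 16,
    days=None,
    z0: float = 9.0e5,
    z_plateau: float = 5.85e5,
    tau_days: float = 3.0,
    noise_sigma: float = 0.1,
    failures: Mapping[int, float] | None = None,
    seed: int = 0,
) -> list[ChannelTimecourse]:
    """Per-channel 1 kHz impedance over days.

    The noiseless profile is an initial drop to a plateau,
    ``z(d) = z_plateau + (z0 − z_plateau)·exp(−d/tau_days)`` (plateau
    default 585 kΩ, the typical end-of-soak average for a working
    array), multiplied by lognormal noise ``exp(σ·N)`` drawn
    independently per channel and day.  ``failures`` maps channel
    indices to the day from which that channel is an open circuit (NaN
    onward).
    """
    if z_plateau <= 0 or z0 < z_plateau:
        raise ValueError("need z0 >= z_plateau > 0")
    if days is None:
        days = np.arange(0.0, 31.0, 3.0)
    days = np.asarray(days, dtype=float)
    failures = dict(failures or {})
    rng = rng_for(seed, "timecourse")
    profile = z_plateau + (z0 - z_plateau) * np.exp(-days / tau_days)

    out = []
    for ch in range(n_channels):
        factor = np.exp(rng.normal(0.0, noise_sigma, days.size))
        z = profile * factor
        if ch in failures:
            z = np.where(days >= failures[ch], np.nan, z)
        out.append(ChannelTimecourse(channel_id=f"ch{ch:02d}", timepoints=days, z_1khz=z))
    return out


def gen_permeation_image(
    day_index: float,
    growth_um_per_day: float = 0.6,
    shape: tuple[int, int] = (192, 192),
    boundary_col: int = 48,
    pixel_size_um: float = 1.0,
    background: float = 60.0,
    contrast: float = 120.0,
    noise: float = 8.0,
    bump_width_frac: float = 0.1,
    seed: int = 0,
) -> tuple[MicroscopyImage, dict]:
    """Microscope image with a permeation lobe grown from a straight boundary.

    The electrode-opening boundary is the vertical pixel column
    ``boundary_col``; the permeated lobe extends rightward with a
    Gaussian envelope along the boundary whose peak extent is
    ``growth_um_per_day × day_index``.  Intensity is ``background`` plus
    ``contrast`` on the lobe plus Gaussian noise.  Day 0 has no lobe.

    Returns the image and a metadata dict with the boundary pixels, a
    rectangular ROI around the opening, the true maximum extent (µm)
    and the suggested fixed threshold (midway up the contrast step).
    """
    if growth_um_per_day < 0 or day_index < 0:
        raise ValueError("growth and day_index must be non-negative")
    n_rows, n_cols = shape
    rng = rng_for(seed, "image")
    px = background + rng.normal(0.0, noise, shape)

    extent_px = growth_um_per_day * day_index / pixel_size_um
    r0 = n_rows // 2
    w = bump_width_frac * n_rows
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    envelope = np.exp(-(((rows - r0) / w) ** 2))
    lobe = (cols >= boundary_col) & ((cols - boundary_col) <= extent_px * envelope)
    if extent_px < 1.0:
        lobe[:] = False
    px = px + contrast * lobe

    roi = np.zeros(shape, dtype=bool)
    roi[max(r0 - 40, 0) : r0 + 40, boundary_col : min(boundary_col + 48, n_cols)] = True
    meta = {
        "boundary": [(int(r), int(boundary_col)) for r in range(n_rows)],
        "roi": roi,
        "true_max_extent_um": float(math.floor(extent_px) * pixel_size_um if extent_px >= 1 else 0.0),
        "threshold": background + contrast / 2.0,
        "pixel_size_um": pixel_size_um,
    }
    return MicroscopyImage(px, pixel_size_um), meta


def gen_bimodal_image(
    shape: tuple[int, int] = (96, 96),
    levels: tuple[float, float] = (60.0, 180.0),
    sigmas: tuple[float, float] = (12.0, 12.0),
    foreground_frac: float = 0.4,
    seed: int = 0,
) -> MicroscopyImage:
    """Two-component Gaussian-mixture image (for threshold validation)."""
    rng = rng_for(seed, "bimodal")
    fg = rng.random(shape) < foreground_frac
    px = np.where(
        fg,
        rng.normal(levels[1], sigmas[1], shape),
        rng.normal(levels[0], sigmas[0], shape),
    )
    return MicroscopyImage(np.clip(px, 0.0, 255.0), 1.0)


def _pink_noise(n: int, rms: float, rng: np.random.Generator) -> npt.NDArray[np.float64]:
    """1/f-amplitude noise via spectral shaping of white Gaussian noise."""
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def gen_ecog(
    n_trials: int = 40,
    rate: float = 1000.0,
    latency_ms: float = 70.0,
    amplitude_uv: float = 50.0,
    response_tau_s: float = 0.15,
    band: tuple[float, float] = (140.0, 200.0),
    band_gain: float = 1.0,
    pink_rms_uv: float = 20.0,
    stim_duration_s: float = 4.0,
    isi_range: tuple[float, float] = (7.0, 9.0),
    seed: int = 0,
) -> tuple[RecordingTrace, StimulusProtocol]:
    """ECoG-like trace with a visual-stimulation protocol.

    Components, all seeded from one top-level seed:

    * pink (1/f) background at ``pink_rms_uv`` RMS;
    * per trial, an on-response starting exactly ``latency_ms`` after
      the onset: a step to ``amplitude_uv`` decaying with time constant
      ``response_tau_s`` (the sharp rise makes the injected latency
      recoverable to one sample on noiseless averages);
    * during each stimulus, extra band-limited noise scaled so the
      in-band power is ``band_gain`` × its baseline value
      (``band_gain = 1`` adds nothing);
    * onset-to-onset intervals uniform in ``isi_range`` and one of 12
      orientations (30° apart) per trial, in pseudorandom order.
    """
    lo, hi = band
    if rate <= 2 * hi:
        raise ValueError("band extends beyond Nyquist: need rate > 2 × upper edge")
    if band_gain < 1.0:
        raise ValueError("band_gain must be >= 1")
    rng = rng_for(seed, "ecog")

    lead_in = 2.0
    isis = rng.uniform(isi_range[0], isi_range[1], n_trials - 1) if n_trials > 1 else np.array([])
    onsets = lead_in + np.concatenate([[0.0], np.cumsum(isis)])
    duration = onsets[-1] + stim_duration_s + 2.0
    n = int(round(duration * rate))

    x = _pink_noise(n, pink_rms_uv, rng)

    # baseline in-band RMS, for calibrating the stimulus band-power gain
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    base_band_rms = float(signal.sosfiltfilt(sos, x).std())

    t_kernel = np.arange(0.0, stim_duration_s, 1.0 / rate)
    lat_s = latency_ms * 1e-3
    kernel = np.where(
        t_kernel >= lat_s, amplitude_uv * np.exp(-(t_kernel - lat_s) / response_tau_s), 0.0
    )

    extra_rms = base_band_rms * math.sqrt(band_gain - 1.0) if band_gain > 1.0 else 0.0
    n_stim = t_kernel.size
    for onset in onsets:
        i = int(round(onset * rate))
        x[i : i + n_stim] += kernel[: max(min(n_stim, n - i), 0)]
        if extra_rms > 0:
            burst = signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, n_stim))
            burst *= extra_rms / burst.std()
            x[i : i + n_stim] += burst[: max(min(n_stim, n - i), 0)]

    n_orient = 12
    orientations = np.empty(n_trials)
    for block in range(0, n_trials, n_orient):
        perm = rng.permutation(n_orient) * 30.0
        take = min(n_orient, n_trials - block)
        orientations[block : block + take] = perm[:take]

    trace = RecordingTrace(samples=x, rate=rate)
    protocol = StimulusProtocol(
        onsets=onsets,
        duration=stim_duration_s,
        isi_range=isi_range,
        orientations_deg=orientations,
    )
    return trace, protocol
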