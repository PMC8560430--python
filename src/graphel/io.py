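"""File interfaces for spectra, parameters and recording traces.

Formats are deliberately plain: CSV for spectra and time series, JSON
for parameter sets and sidecar metadata, raw little-endian float32 (or
two-column CSV) for recording traces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from graphel.eis_model import CircuitParameters, ImpedanceSpectrum
from graphel.recording_qc import RecordingTrace

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_parameters_json",
    "read_trace",
    "read_onsets_csv",
]

_SPECTRUM_COLS = ["frequency_hz", "z_real_ohm", "z_imag_ohm"]


def read_spectrum_csv(path) -> ImpedanceSpectrum:
    """Read a spectrum CSV (frequency_hz, z_real_ohm, z_imag_ohm)."""
    df = pd.read_csv(path)
    if not set(_SPECTRUM_COLS).issubset(df.columns):
        raise ValueError(f"spectrum CSV needs columns {_SPECTRUM_COLS}")
    df = df.sort_values("frequency_hz")
    return ImpedanceSpectrum(
        df["frequency_hz"].to_numpy(float),
        df["z_real_ohm"].to_numpy(float) + 1j * df["z_imag_ohm"].to_numpy(float),
    )


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path) -> None:
    pd.DataFrame(
        {
            "frequency_hz": spectrum.frequencies,
            "z_real_ohm": spectrum.z.real,
            "z_imag_ohm": spectrum.z.imag,
        }
    ).to_csv(path, index=False)


def write_parameters_json(params: CircuitParameters, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2), encoding="utf-8")


def read_trace(path, meta_path=None, rate_hz: float | None = None) -> RecordingTrace:
    """Read a trace from raw float32 (little-endian) or a time,value CSV.

    Raw traces need a sampling rate from ``rate_hz`` or a JSON sidecar
    with key ``rate_hz``; CSV traces infer it from the time column.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        x = df.iloc[:, 1].to_numpy(float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise ValueError("CSV trace needs an increasing time column")
        return RecordingTrace(samples=x, rate=1.0 / float(np.median(dt)), start_time=float(t[0]))
    if meta_path is not None:
        with open(meta_path, "r", encoding="utf-8") as fh:
            rate_hz = json.load(fh).get("rate_hz", rate_hz)
    if rate_hz is None:
        raise ValueError("raw traces need rate_hz (argument or sidecar JSON)")
    samples = np.fromfile(path, dtype="<f4").astype(float)
    return RecordingTrace(samples=samples, rate=float(rate_hz))


def read_onsets_csv(path) -> np.ndarray:
    """Read stimulus onset times (s) from a one-column CSV."""
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(float)
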