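"""Readers and writers for EEG series, spectra and feature tables.

Time series travel either as standard EDF (read through :mod:`mne`, an
optional dependency), as delimited multi-channel text (one column per
channel, optional header of channel names), or as flat binary float64 with
a JSON sidecar carrying sampling rate and channel names.  Spectra and
features are plain CSV with documented column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import PowerSpectrum

__all__ = [
    "read_edf",
    "read_delimited_timeseries",
    "write_delimited_timeseries",
    "read_binary_timeseries",
    "write_binary_timeseries",
    "write_spectra_csv",
    "read_spectra_csv",
]


def read_edf(path: str | Path, channels: list[str] | None = None):
    """Read an EDF file; returns (data (channels, samples), fs, channel names).

    Requires :mod:`mne`; raises ImportError with guidance if unavailable.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires mne; install the 'edf' extra or provide "
            "delimited/binary input instead"
        ) from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


def read_delimited_timeseries(
    path: str | Path, fs: float, sep: str = ","
) -> tuple[np.ndarray, float, list[str]]:
    """Read a (samples x channels) delimited text file; returns channels-first."""
    df = pd.read_csv(path, sep=sep)
    return df.to_numpy(dtype=float).T, fs, list(df.columns.astype(str))


def write_delimited_timeseries(
    path: str | Path, data: np.ndarray, channel_names: list[str], sep: str = ","
) -> None:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    pd.DataFrame(data.T, columns=channel_names).to_csv(path, sep=sep, index=False)


def write_binary_timeseries(
    path: str | Path, data: np.ndarray, fs: float, channel_names: list[str]
) -> None:
    """Flat float64 binary (channels x samples, C order) + JSON sidecar."""
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    data.tofile(path)
    sidecar = {
        "fs_hz": fs,
        "n_channels": data.shape[0],
        "n_samples": data.shape[1],
        "channel_names": list(channel_names),
        "dtype": "float64",
        "order": "C",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_binary_timeseries(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=np.float64).reshape(
        sidecar["n_channels"], sidecar["n_samples"]
    )
    return data, float(sidecar["fs_hz"]), list(sidecar["channel_names"])


def write_spectra_csv(path: str | Path, spectra: list[PowerSpectrum]) -> None:
    """Long-format spectra CSV with columns roi, frequency_hz, power."""
    frames = [
        pd.DataFrame(
            {"roi": s.label or "whole", "frequency_hz": s.freqs, "power": s.power}
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> list[PowerSpectrum]:
    df = pd.read_csv(path)
    out = []
    for roi, sub in df.groupby("roi", sort=False):
        out.append(
            PowerSpectrum(
                freqs=sub["frequency_hz"].to_numpy(dtype=float),
                power=sub["power"].to_numpy(dtype=float),
                label=str(roi),
            )
        )
    return out
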