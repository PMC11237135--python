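"""Multitaper power spectral density estimation for segmented infant EEG.

Cleaned EEG is cut into non-overlapping 2-second segments; each segment's
power spectral density (PSD) is estimated with discrete prolate spheroidal
(Slepian) tapers and averaged across tapers, then across segments, then
across the electrodes of a region of interest.  All averaging is done on the
linear power scale; the log transform happens only at parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

__all__ = [
    "PowerSpectrum",
    "RoiMap",
    "DEFAULT_ROI_MAP",
    "segment",
    "multitaper_psd",
    "psd_from_timeseries",
    "average_spectra",
]


@dataclass(frozen=True)
class PowerSpectrum:
    """A one-sided power spectral density on a uniform frequency grid.

    Attributes
    ----------
    freqs
        Frequencies in Hz, strictly increasing, uniformly spaced.
    power
        Linear-scale power density (signal-units^2 / Hz), same length as
        ``freqs``.
    n_epochs
        Number of 2-s segments averaged into this spectrum.
    label
        Channel or ROI name this spectrum belongs to.
    """

    freqs: np.ndarray
    power: np.ndarray
    n_epochs: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.ndim != 1 or power.shape != freqs.shape:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if freqs.size >= 2:
            df = np.diff(freqs)
            if np.any(df <= 0):
                raise ValueError("frequency grid must be strictly increasing")
            if not np.allclose(df, df[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frequency grid must be uniform")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)

    @property
    def df(self) -> float:
        """Grid spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    def log_power(self) -> np.ndarray:
        """log10 of the power values (fails loudly on non-positive power)."""
        if np.any(self.power <= 0):
            raise ValueError("log power undefined: spectrum has non-positive values")
        return np.log10(self.power)

    def with_label(self, label: str) -> "PowerSpectrum":
        return replace(self, label=label)


_ROI_NAMES = ("frontal", "central", "temporal", "posterior", "whole")


@dataclass(frozen=True)
class RoiMap:
    """Mapping from region-of-interest name to electrode labels.

    The four scalp ROIs (frontal, central, temporal, posterior) must be
    disjoint; ``whole`` is the union of every electrode and is derived
    automatically when not given.
    """

    rois: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rois = {name: tuple(chans) for name, chans in dict(self.rois).items()}
        unknown = set(rois) - set(_ROI_NAMES)
        if unknown:
            raise ValueError(f"unknown ROI names: {sorted(unknown)}")
        seen: dict[str, str] = {}
        for name, chans in rois.items():
            if name == "whole":
                continue
            for ch in chans:
                if ch in seen:
                    raise ValueError(
                        f"electrode {ch!r} assigned to both {seen[ch]!r} and {name!r}"
                    )
                seen[ch] = name
        if "whole" not in rois:
            rois["whole"] = tuple(seen)
        object.__setattr__(self, "rois", rois)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.rois[name]

    def names(self) -> tuple[str, ...]:
        return tuple(self.rois)


# 10-20-style default montage split into the four scalp regions.
DEFAULT_ROI_MAP = RoiMap(
    {
        "frontal": ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"),
        "central": ("C3", "C4", "Cz"),
        "temporal": ("T3", "T4", "T5", "T6"),
        "posterior": ("P3", "P4", "Pz", "O1", "O2", "Oz"),
    }
)


def segment(ts: np.ndarray, fs: float, epoch_len: float = 2.0) -> np.ndarray:
    """Cut a time series into non-overlapping epochs, dropping the remainder.

    Parameters
    ----------
    ts
        1-D signal (samples,) or 2-D (channels, samples).
    fs
        Sampling rate in Hz.
    epoch_len
        Epoch length in seconds (default 2 s).

    Returns
    -------
    Array of shape (n_epochs, n_samples) for 1-D input or
    (channels, n_epochs, n_samples) for 2-D input; ``n_epochs`` may be 0.
    """
    ts = np.asarray(ts, dtype=float)
    n_per = int(round(epoch_len * fs))
    if n_per <= 0:
        raise ValueError("epoch_len * fs must be positive")
    n_samples = ts.shape[-1]
    n_epochs = n_samples // n_per
    trimmed = ts[..., : n_epochs * n_per]
    new_shape = ts.shape[:-1] + (n_epochs, n_per)
    return trimmed.reshape(new_shape)


def multitaper_psd(
    epoch: np.ndarray,
    fs: float,
    n_tapers: int = 3,
    nw: float | None = None,
    label: str = "",
) -> PowerSpectrum:
    """Multitaper PSD of a single epoch using DPSS (Slepian) tapers.

    The eigenspectra of ``n_tapers`` orthogonal tapers are averaged with
    equal weights.  Density normalization: the integral of the one-sided PSD
    over [0, fs/2] equals the mean squared amplitude of the tapered signal
    (Parseval, up to taper bias).

    Parameters
    ----------
    epoch
        1-D signal of one segment.
    fs
        Sampling rate in Hz.
    n_tapers
        Number of tapers K (default 3 as in the analysis pipeline).
    nw
        Time-bandwidth product; defaults to (K + 1) / 2, the standard
        companion of K = 2NW - 1.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1:
        raise ValueError("epoch must be 1-D")
    if n_tapers < 1:
        raise ValueError("n_tapers must be >= 1")
    n = epoch.size
    if nw is None:
        nw = (n_tapers + 1) / 2.0
    tapers = dpss(n, NW=nw, Kmax=n_tapers)
    tapers = np.atleast_2d(tapers)
    # Each taper has unit energy (sum w^2 = 1); |FFT|^2 / fs is then a density.
    spectra = rfft(tapers * epoch[None, :], axis=-1)
    psd = (np.abs(spectra) ** 2) / fs
    # One-sided: double everything except DC and (if n even) Nyquist.
    if n % 2 == 0:
        psd[:, 1:-1] *= 2.0
    else:
        psd[:, 1:] *= 2.0
    freqs = rfftfreq(n, d=1.0 / fs)
    return PowerSpectrum(freqs=freqs, power=psd.mean(axis=0), n_epochs=1, label=label)


def psd_from_timeseries(
    ts: np.ndarray,
    fs: float,
    epoch_len: float = 2.0,
    n_tapers: int = 3,
    nw: float | None = None,
    label: str = "",
) -> PowerSpectrum:
    """Segment a series and average the per-epoch multitaper PSDs.

    Raises ``ValueError`` if the series is shorter than one epoch.
    """
    epochs = segment(ts, fs, epoch_len)
    if epochs.shape[0] == 0:
        raise ValueError("time series shorter than one epoch; no PSD computed")
    spectra = [multitaper_psd(ep, fs, n_tapers=n_tapers, nw=nw) for ep in epochs]
    out = average_spectra(spectra)
    return replace(out, label=label)


def average_spectra(
    spectra: Sequence[PowerSpectrum],
    weights: Iterable[float] | None = None,
    label: str = "",
) -> PowerSpectrum:
    """Pointwise (weighted) arithmetic mean of spectra in linear power.

    All inputs must share an identical frequency grid.  With the default
    equal weights, averaging epochs then electrodes equals pooled averaging.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != ref.shape or not np.allclose(s.freqs, ref):
            raise ValueError("cannot average spectra with mismatched frequency grids")
    stack = np.stack([s.power for s in spectra])
    if weights is None:
        mean = stack.mean(axis=0)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (len(spectra),):
            raise ValueError("weights length must match number of spectra")
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative and not all zero")
        mean = (stack * w[:, None]).sum(axis=0) / w.sum()
    n_epochs = int(sum(s.n_epochs for s in spectra))
    return PowerSpectrum(freqs=ref.copy(), power=mean, n_epochs=n_epochs, label=label)
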