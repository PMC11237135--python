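"""Frontal multitaper coherence under anesthesia and its group comparison.

Magnitude coherence between two channels (e.g. the frontal bipolar pairs
F7-Fp1 and F8-Fp2) is estimated as

    C_xy(f) = |S_xy(f)| / sqrt(S_xx(f) * S_yy(f))

where the cross- and auto-spectra are multitaper estimates averaged over
tapers and over non-overlapping windows *before* forming the ratio
(averaging per-window coherences is degenerate: a single-taper,
single-window coherence is identically 1).  Defaults follow the anesthesia
analysis convention: window T = 6 s, no overlap, time-bandwidth product
TW = 3, K = 5 tapers.

Epoch selection utilities implement (a) rejection of high-amplitude epochs
by their standard deviation relative to the median epoch sd and (b) a
stability mask over an anesthetic-concentration covariate (an epoch is
eligible only if the preceding two minutes of end-tidal concentration span
at most 0.2 %).

The group comparison is a one-way ANCOVA of median alpha coherence on
low-beta-peak presence with anesthetic level as covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

__all__ = [
    "CoherenceSpectrum",
    "EpochSelection",
    "reject_epochs_by_sd",
    "stable_covariate_mask",
    "multitaper_coherence",
    "median_band_coherence",
    "compare_groups_ancova",
]

ALPHA_BAND = (8.0, 12.0)


@dataclass(frozen=True)
class CoherenceSpectrum:
    """Per-frequency magnitude coherence with its estimator parameters."""

    freqs: np.ndarray
    coherence: np.ndarray
    window_s: float
    time_bandwidth: float
    n_tapers: int
    n_windows: int

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        coh = np.asarray(self.coherence, dtype=float)
        if freqs.shape != coh.shape:
            raise ValueError("freqs and coherence must have equal length")
        finite = np.isfinite(coh)
        if np.any(coh[finite] < 0) or np.any(coh[finite] > 1 + 1e-12):
            raise ValueError("coherence must lie in [0, 1]")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "coherence", coh)


@dataclass(frozen=True)
class EpochSelection:
    """Per-epoch sd, keep decision and optional covariate value."""

    epoch_sd: np.ndarray
    keep: np.ndarray
    threshold: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def reject_epochs_by_sd(epochs: np.ndarray, k: float = 3.0) -> EpochSelection:
    """Keep epochs whose sd is at most ``k`` times the median epoch sd.

    ``epochs`` has shape (n_epochs, n_samples).  With ``k=inf`` everything
    is kept.  If every epoch is rejected the selection is returned with an
    all-False mask; callers must treat that as an empty selection.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2 or epochs.shape[0] < 1:
        raise ValueError("epochs must be a non-empty (n_epochs, n_samples) array")
    sds = epochs.std(axis=1, ddof=0)
    threshold = k * float(np.median(sds))
    keep = sds <= threshold
    return EpochSelection(epoch_sd=sds, keep=keep, threshold=threshold)


def stable_covariate_mask(
    times_s: np.ndarray,
    covariate: np.ndarray,
    epoch_times_s: np.ndarray,
    window_s: float = 120.0,
    tolerance: float = 0.2,
) -> np.ndarray:
    """Eligibility mask: preceding ``window_s`` of covariate spans <= tolerance.

    ``times_s``/``covariate`` sample the anesthetic concentration;
    ``epoch_times_s`` are epoch start times.  Epochs whose preceding window
    extends before the first covariate sample are ineligible (insufficient
    history).
    """
    times_s = np.asarray(times_s, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    epoch_times_s = np.asarray(epoch_times_s, dtype=float)
    if times_s.shape != covariate.shape:
        raise ValueError("times_s and covariate must have equal length")
    keep = np.zeros(epoch_times_s.shape, dtype=bool)
    for i, t in enumerate(epoch_times_s):
        t0 = t - window_s
        if t0 < times_s[0] - 1e-9:
            continue
        mask = (times_s >= t0 - 1e-9) & (times_s <= t + 1e-9)
        if not np.any(mask):
            continue
        window = covariate[mask]
        keep[i] = (window.max() - window.min()) <= tolerance + 1e-12
    return keep


def multitaper_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 6.0,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
) -> CoherenceSpectrum:
    """Multitaper magnitude coherence with non-overlapping windows.

    Cross- and auto-spectra are averaged across all tapers and windows,
    then combined as |S_xy| / sqrt(S_xx S_yy); the Cauchy-Schwarz
    inequality bounds the result in [0, 1] by construction.  Frequencies
    where either averaged auto-spectrum is zero are reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if n_tapers > 2 * time_bandwidth - 1 + 1e-9:
        raise ValueError("n_tapers must satisfy K <= 2*TW - 1")
    n_per = int(round(window_s * fs))
    n_windows = x.size // n_per
    if n_windows < 2:
        raise ValueError("need at least 2 windows for a coherence estimate")
    tapers = dpss(n_per, NW=time_bandwidth, Kmax=n_tapers)
    tapers = np.atleast_2d(tapers)

    sxx = syy = sxy = None
    for w in range(n_windows):
        seg_x = x[w * n_per : (w + 1) * n_per]
        seg_y = y[w * n_per : (w + 1) * n_per]
        fx = rfft(tapers * seg_x[None, :], axis=-1)
        fy = rfft(tapers * seg_y[None, :], axis=-1)
        pxx = (np.abs(fx) ** 2).sum(axis=0)
        pyy = (np.abs(fy) ** 2).sum(axis=0)
        pxy = (fx * np.conj(fy)).sum(axis=0)
        sxx = pxx if sxx is None else sxx + pxx
        syy = pyy if syy is None else syy + pyy
        sxy = pxy if sxy is None else sxy + pxy

    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) / denom
    coh = np.where(denom > 0, coh, np.nan)
    freqs = rfftfreq(n_per, d=1.0 / fs)
    return CoherenceSpectrum(
        freqs=freqs, coherence=coh, window_s=window_s,
        time_bandwidth=time_bandwidth, n_tapers=n_tapers, n_windows=n_windows,
    )


def median_band_coherence(
    cs: CoherenceSpectrum, band: tuple[float, float] = ALPHA_BAND
) -> float:
    """Median coherence over in-band frequency bins (NaN bins excluded)."""
    lo, hi = band
    mask = (cs.freqs >= lo) & (cs.freqs <= hi)
    vals = cs.coherence[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no finite coherence bins in band {band}")
    return float(np.median(vals))


def compare_groups_ancova(
    values: np.ndarray,
    group: np.ndarray,
    covariate: np.ndarray,
) -> tuple[float, float]:
    """One-way ANCOVA: value ~ group + covariate; F test on the group term.

    ``group`` is binary (e.g. low-beta peak present/absent).  Returns
    (F, p) for the group effect.  A covariate collinear with group (or
    constant) raises a diagnostic error.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "group": np.asarray(group),
            "covariate": np.asarray(covariate, dtype=float),
        }
    )
    counts = df["group"].value_counts()
    if len(counts) != 2 or counts.min() < 2:
        raise ValueError("need two groups with at least 2 observations each")
    if np.std(df["covariate"]) == 0:
        raise ValueError("covariate is constant; ANCOVA adjustment undefined")
    r = np.corrcoef(pd.factorize(df["group"])[0], df["covariate"])[0, 1]
    if abs(r) > 0.999:
        raise ValueError("covariate is collinear with group; effect not identifiable")
    model = smf.ols("value ~ C(group) + covariate", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    row = anova.loc["C(group)"]
    return float(row["F"]), float(row["PR(>F)"])
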