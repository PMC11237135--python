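"""Synthetic EEG spectra, time series, coherent channel pairs and cohorts.

Every downstream stage (PSD estimation, spectral parameterization, band
features, coherence, trajectory modelling) is validated against data from
this module, where the ground truth is known by construction:

* spectra follow the aperiodic + periodic model
  ``log10 P(f) = b - chi * log10(f) + sum_k Gaussian(f; cf_k, h_k, sd_k)``
  with optional additive log-power noise;
* time series are Gaussian noise spectrally shaped in the frequency domain
  so their expected PSD equals the model spectrum;
* channel pairs share a band-limited common component, giving an analytic
  magnitude coherence ``sigma_s^2 / (sigma_s^2 + sigma_n^2)`` in band;
* longitudinal cohorts draw feature values from deterministic age curves
  plus subject and study random intercepts and residual noise.

No EEG artifacts (blinks, muscle), electrode geometry or volume conduction
are simulated; inputs to the pipeline are assumed clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq

from .spectral import PowerSpectrum

__all__ = [
    "SpectrumParams",
    "CohortSpec",
    "model_log_power",
    "generate_spectrum",
    "generate_timeseries",
    "generate_sinusoid",
    "generate_coherent_pair",
    "generate_cohort",
    "derive_seed",
]


def derive_seed(seed: int, *keys: int) -> int:
    """Deterministically derive a child seed (< 2**31) from a parent seed.

    Used so that per-subject draws in a cohort are reproducible under
    subsetting: subject ``i`` always sees the same stream regardless of how
    many other subjects are generated.
    """
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class SpectrumParams:
    """Ground-truth parameters of a model power spectrum.

    Attributes
    ----------
    offset
        Aperiodic offset ``b`` in log10(power) units (the model's value at
        1 Hz; the conventional reported offset is evaluated at 2.5 Hz).
    exponent
        Aperiodic exponent ``chi`` (>= 0); the log-log slope is ``-chi``.
    peaks
        Sequence of ``(center_freq_hz, height_log10, sd_hz)`` Gaussian
        peaks in log10-power space.
    noise_sd
        Standard deviation of i.i.d. additive noise in log10-power.
    freq_range
        (lo, hi) in Hz; peaks must lie strictly inside.
    """

    offset: float
    exponent: float
    peaks: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.0
    freq_range: tuple[float, float] = (2.0, 55.0)

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        if not (0 < lo < hi):
            raise ValueError("freq_range must satisfy 0 < lo < hi")
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        peaks = tuple((float(c), float(h), float(s)) for c, h, s in self.peaks)
        for cf, h, sd in peaks:
            if not (lo < cf < hi):
                raise ValueError(f"peak center {cf} Hz not strictly inside {self.freq_range}")
            if sd <= 0:
                raise ValueError("peak sd must be > 0")
            if h < 0:
                raise ValueError("peak height must be >= 0")
        object.__setattr__(self, "peaks", peaks)


def model_log_power(params: SpectrumParams, freqs: np.ndarray) -> np.ndarray:
    """Noise-free model log10 power on an arbitrary positive grid."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("model undefined at f <= 0")
    log_p = params.offset - params.exponent * np.log10(freqs)
    for cf, h, sd in params.peaks:
        log_p = log_p + h * np.exp(-((freqs - cf) ** 2) / (2.0 * sd**2))
    return log_p


def generate_spectrum(
    params: SpectrumParams, grid: np.ndarray, seed: int | None = None
) -> PowerSpectrum:
    """Evaluate the model (plus log-power noise) on a grid; linear scale out.

    The grid must be strictly increasing, uniform, and inside
    ``params.freq_range``.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = params.freq_range
    if grid.size and (grid[0] < lo or grid[-1] > hi):
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] Hz outside params.freq_range {params.freq_range}"
        )
    log_p = model_log_power(params, grid)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        log_p = log_p + rng.normal(0.0, params.noise_sd, size=grid.shape)
    return PowerSpectrum(freqs=grid, power=10.0**log_p, n_epochs=1, label="synthetic")


def _shaped_noise(
    target_psd: Callable[[np.ndarray], np.ndarray],
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with expected one-sided PSD ``target_psd(f)``.

    White Gaussian noise is transformed to the frequency domain and each
    rfft coefficient scaled by sqrt of the target density, which gives the
    exact expected periodogram (the DC bin is zeroed: the model is
    undefined at 0 Hz and EEG is detrended anyway).
    """
    white = rng.standard_normal(n_samples)
    coef = rfft(white)
    freqs = rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    pos = freqs > 0
    # E|X_k|^2 = n*fs*S(f)/2 for interior one-sided bins; rfft of unit white
    # noise already carries E|W_k|^2 = n, leaving sqrt(fs*S/2) to apply.
    psd_vals = np.asarray(target_psd(freqs[pos]), dtype=float)
    scale[pos] = np.sqrt(psd_vals * fs / 2.0)
    if n_samples % 2 == 0:
        scale[-1] *= np.sqrt(2.0)  # Nyquist bin is real-valued, not doubled
    return irfft(coef * scale, n=n_samples)


def generate_timeseries(
    params: SpectrumParams,
    duration: float,
    fs: float,
    seed: int | None = None,
    epoch_len: float = 2.0,
) -> np.ndarray:
    """Simulate a stationary series whose expected PSD is the model spectrum.

    Each ``epoch_len`` segment is generated independently with the exact
    expected multitaper PSD, then concatenated, so segmenting downstream at
    the same epoch length recovers independent epochs.

    ``fs`` must satisfy Nyquist for the upper frequency bound; ``duration``
    must be a whole number of epochs.
    """
    lo, hi = params.freq_range
    if fs < 2.0 * hi:
        raise ValueError(f"fs={fs} violates Nyquist for upper bound {hi} Hz")
    n_epochs = duration / epoch_len
    if abs(n_epochs - round(n_epochs)) > 1e-9 or round(n_epochs) < 1:
        raise ValueError("duration must be a positive multiple of epoch_len")
    n_epochs = int(round(n_epochs))
    n_per = int(round(epoch_len * fs))
    rng = np.random.default_rng(seed)

    def target(freqs: np.ndarray) -> np.ndarray:
        # Clip evaluation to the model's domain; roll off outside it.
        f = np.clip(freqs, lo, hi)
        psd = 10.0 ** model_log_power(
            SpectrumParams(params.offset, params.exponent, params.peaks, 0.0, params.freq_range),
            f,
        )
        return np.where((freqs >= lo) & (freqs <= hi), psd, psd * 1e-6)

    out = np.concatenate([_shaped_noise(target, n_per, fs, rng) for _ in range(n_epochs)])
    return out


def generate_sinusoid(
    freq: float, amplitude: float, duration: float, fs: float, phase: float = 0.0
) -> np.ndarray:
    """Pure sinusoid A*sin(2*pi*f*t + phase); band power around f is A^2/2."""
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.sin(2.0 * np.pi * freq * t + phase)


def generate_coherent_pair(
    shared_var: float,
    independent_var: float,
    band: tuple[float, float],
    duration: float,
    fs: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two series sharing a band-limited component with known coherence.

    ``y1 = s + n1`` and ``y2 = s + n2`` where s, n1, n2 are independent
    Gaussian noises band-limited to ``band``; in-band magnitude coherence
    has expectation ``shared_var / (shared_var + independent_var)``.
    """
    if shared_var < 0 or independent_var < 0:
        raise ValueError("variances must be >= 0")
    if shared_var == 0 and independent_var == 0:
        raise ValueError("shared_var and independent_var cannot both be 0")
    lo, hi = band
    if not (0 < lo < hi <= fs / 2):
        raise ValueError("band must satisfy 0 < lo < hi <= fs/2")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    s = _band_noise(shared_var, lo, hi, n, fs, rng)
    n1 = _band_noise(independent_var, lo, hi, n, fs, rng)
    n2 = _band_noise(independent_var, lo, hi, n, fs, rng)
    return s + n1, s + n2


def _band_noise(
    var: float, lo: float, hi: float, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian noise with total variance ``var``."""
    if var == 0:
        return np.zeros(n)
    width = hi - lo

    def density(f: np.ndarray) -> np.ndarray:
        return np.where((f >= lo) & (f <= hi), var / width, 0.0)

    return _shaped_noise(density, n, fs, rng)


def infant_archetype_params(rng: np.random.Generator, noise_sd: float = 0.01) -> SpectrumParams:
    """Archetypal 2-7-month spectrum: alpha + broad high-beta, no low beta.

    The two peaks pull a global power-law fit upward, so the 10-20 Hz
    stretch of the spectrum falls below the initial aperiodic estimate (the
    "trough" regime that motivates the infant modification).  Peak
    locations follow the printed infant values (alpha 9.5 +/- 0.45 Hz;
    high-beta centered in the 24-30 Hz range).
    """
    return SpectrumParams(
        offset=rng.uniform(1.2, 1.8),
        exponent=rng.uniform(0.8, 1.2),
        peaks=(
            (float(rng.normal(9.5, 0.45)), float(rng.uniform(0.6, 1.0)), float(rng.uniform(1.0, 1.5))),
            (float(rng.uniform(24.0, 30.0)), float(rng.uniform(0.3, 0.6)), float(rng.uniform(3.0, 4.0))),
        ),
        noise_sd=noise_sd,
    )


def toddler_archetype_params(rng: np.random.Generator, noise_sd: float = 0.0) -> SpectrumParams:
    """Archetypal trough-free ~36-month spectrum: one dominant sharp alpha peak.

    Used to check that the infant modification is conservative where no
    trough exists.  Spectra with additional broad beta peaks leave the two
    code paths agreeing only at the few-1e-3 level because their robust
    selections weight Gaussian tails differently.
    """
    return SpectrumParams(
        offset=rng.uniform(1.5, 2.0),
        exponent=rng.uniform(1.2, 1.6),
        peaks=(
            (float(rng.normal(8.5, 0.3)), float(rng.uniform(0.3, 0.5)), float(rng.uniform(0.9, 1.1))),
        ),
        noise_sd=noise_sd,
    )


def spline_peak_curve(
    age_range: tuple[float, float],
    peak_day: float,
    k: int = 4,
    amplitude: float = 0.8,
    baseline: float = 1.0,
    width_days: float = 180.0,
) -> "Callable[[np.ndarray], np.ndarray]":
    """Age curve inside the k-dim spline family with its maximum at ``peak_day``.

    Trajectory models fit fixed-df regression splines, so a recovery study
    needs ground-truth curves the model class can represent exactly;
    otherwise the extremum of the best spline approximation — not of the
    generating curve — is the estimand.  A Gaussian bump is projected onto
    a natural cubic spline basis (dimension ``k``, built on a daily grid)
    and its center adjusted by bisection until the projected curve's
    interior maximum lies within half a day of ``peak_day``.
    """
    import patsy

    lo, hi = age_range
    grid = np.arange(lo, hi + 1.0)
    df_grid = pd.DataFrame({"age": grid})
    X = patsy.dmatrix(f"cr(age, df={k}) - 1", df_grid, return_type="dataframe")
    design_info = X.design_info
    B = X.to_numpy()
    means = B.mean(axis=0)
    Bc = (B - means)[:, : k - 1]
    design = np.column_stack([np.ones(grid.size), Bc])

    def projected(center: float) -> tuple[np.ndarray, np.ndarray]:
        bump = baseline + amplitude * np.exp(-((grid - center) ** 2) / (2 * width_days**2))
        coef, *_ = np.linalg.lstsq(design, bump, rcond=None)
        return coef, design @ coef

    c_lo, c_hi = lo, hi
    coef = None
    for _ in range(60):
        c_mid = 0.5 * (c_lo + c_hi)
        coef, curve = projected(c_mid)
        peak = grid[np.argmax(curve)]
        if abs(peak - peak_day) <= 0.5:
            break
        if peak < peak_day:
            c_lo = c_mid
        else:
            c_hi = c_mid

    def curve_fn(ages: np.ndarray) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        (Xn,) = patsy.build_design_matrices([design_info], pd.DataFrame({"age": ages}))
        Bn = (np.asarray(Xn) - means)[:, : k - 1]
        return np.column_stack([np.ones(ages.size), Bn]) @ coef

    return curve_fn


AgeCurve = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class CohortSpec:
    """Design of a longitudinal synthetic cohort.

    ``parameter_curves`` maps each feature name to a deterministic function
    of age in days (vectorized).  Random intercepts are Gaussian per subject
    and per study with the given sds; residual noise is added per visit.
    """

    n_subjects: int
    visits_per_subject: int
    age_range: tuple[float, float] = (60.0, 1340.0)
    sex_assignment: float = 0.5
    study_labels: tuple[str, ...] = ("study1", "study2")
    parameter_curves: Mapping[str, AgeCurve] = field(default_factory=dict)
    random_effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    residual_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.visits_per_subject < 1:
            raise ValueError("n_subjects and visits_per_subject must be >= 1")
        lo, hi = self.age_range
        if not (0 <= lo < hi):
            raise ValueError("invalid age_range")
        if not (0.0 <= self.sex_assignment <= 1.0):
            raise ValueError("sex_assignment must be a probability")
        if not self.study_labels:
            raise ValueError("need at least one study label")
        for feat, (ssd, stsd) in self.random_effects.items():
            if ssd < 0 or stsd < 0:
                raise ValueError(f"negative random-effect sd for {feat!r}")
        for feat, rsd in self.residual_sd.items():
            if rsd < 0:
                raise ValueError(f"negative residual sd for {feat!r}")


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw a longitudinal cohort table with known feature-generating curves.

    Returns one row per (subject, visit) with columns ``subject_id``,
    ``study``, ``sex`` ('F'/'M'), ``age_days`` and one column per feature.
    Visit ages are uniform over ``age_range`` and sorted within subject.
    Study random intercepts are drawn once per study from the study sd.
    """
    rng = np.random.default_rng(derive_seed(seed, 0))
    features = list(spec.parameter_curves)
    study_effects = {
        feat: {
            lab: rng.normal(0.0, spec.random_effects.get(feat, (0.0, 0.0))[1])
            for lab in spec.study_labels
        }
        for feat in features
    }
    rows: list[dict] = []
    lo, hi = spec.age_range
    for i in range(spec.n_subjects):
        srng = np.random.default_rng(derive_seed(seed, 1, i))
        study = spec.study_labels[i % len(spec.study_labels)]
        sex = "F" if srng.random() < spec.sex_assignment else "M"
        ages = np.sort(srng.uniform(lo, hi, size=spec.visits_per_subject))
        subj_eff = {
            feat: srng.normal(0.0, spec.random_effects.get(feat, (0.0, 0.0))[0])
            for feat in features
        }
        for v, age in enumerate(ages):
            row = {
                "subject_id": f"S{i:04d}",
                "study": study,
                "sex": sex,
                "visit": v,
                "age_days": float(age),
            }
            for feat in features:
                curve = spec.parameter_curves[feat]
                val = float(np.asarray(curve(np.asarray([age])))[0])
                val += subj_eff[feat]
                val += study_effects[feat][study]
                rsd = spec.residual_sd.get(feat, 0.0)
                if rsd > 0:
                    val += srng.normal(0.0, rsd)
                row[feat] = val
            rows.append(row)
    return pd.DataFrame(rows)
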