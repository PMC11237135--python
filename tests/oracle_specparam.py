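"""Independent re-implementation of the published parameterization loop.

Used as a cross-check oracle for the package's unmodified code path.  It is
deliberately written through a different numerical route (``np.polyfit`` for
the linear-in-parameters power-law fits, ``scipy.optimize.least_squares``
for the joint Gaussian stage) and shares no code with the package.
"""

import numpy as np
from scipy.optimize import least_squares


def power_law_fit(freqs, log_power):
    """Least-squares b - chi*log10(f) via polyfit in log-log coordinates."""
    slope, intercept = np.polyfit(np.log10(freqs), log_power, 1)
    return intercept, -slope


def robust_aperiodic_fit(freqs, log_power, percentile=2.5):
    """Published robust fit: clip negatives, percentile-select, refit."""
    b0, chi0 = power_law_fit(freqs, log_power)
    flat = log_power - (b0 - chi0 * np.log10(freqs))
    flat[flat < 0] = 0.0
    thresh = np.percentile(flat, percentile)
    mask = flat <= thresh
    return power_law_fit(freqs[mask], log_power[mask])


def iterative_peak_guesses(freqs, flat, max_n_peaks=7, peak_threshold=2.0,
                           width_limits=(0.5, 18.0)):
    res = freqs[1] - freqs[0]
    lo, hi = width_limits[0] / 2, width_limits[1] / 2
    work = flat.copy()
    guesses = []
    while len(guesses) < max_n_peaks:
        i = int(np.argmax(work))
        h = work[i]
        if h <= peak_threshold * np.std(work) or h <= 1e-6:
            break
        half = h / 2
        left = next((j for j in range(i - 1, -1, -1) if work[j] <= half), None)
        right = next((j for j in range(i + 1, len(work)) if work[j] <= half), None)
        sides = [abs(j - i) for j in (left, right) if j is not None]
        sd = (min(sides) * 2 * res) / 2.355 if sides else np.mean(width_limits)
        sd = float(np.clip(sd, lo, hi))
        work = work - h * np.exp(-((freqs - freqs[i]) ** 2) / (2 * sd**2))
        guesses.append([float(freqs[i]), float(h), sd])
    # published overlap rule: where two guesses' +/- 0.75 sd intervals
    # overlap, only the taller survives
    guesses.sort(key=lambda g: g[0])
    merged = []
    for g in guesses:
        if merged and g[0] - 0.75 * g[2] <= merged[-1][0] + 0.75 * merged[-1][2]:
            if g[1] > merged[-1][1]:
                merged[-1] = g
            continue
        merged.append(g)
    return merged


def joint_gaussian_fit(freqs, flat, guesses, width_limits=(0.5, 18.0), cf_bound=1.5):
    if not guesses:
        return []
    lo_w, hi_w = width_limits[0] / 2, width_limits[1] / 2

    def model(params):
        out = np.zeros_like(freqs)
        for j in range(0, len(params), 3):
            c, h, s = params[j : j + 3]
            out = out + h * np.exp(-((freqs - c) ** 2) / (2 * s**2))
        return out

    p0, lo, hi = [], [], []
    for c, h, s in guesses:
        p0 += [c, h, s]
        lo += [max(freqs[0], c - cf_bound * s), 0.0, lo_w]
        hi += [min(freqs[-1], c + cf_bound * s), np.inf, hi_w]
    p0 = np.clip(p0, lo, hi)
    sol = least_squares(lambda p: model(p) - flat, p0, bounds=(lo, hi))
    return [tuple(sol.x[j : j + 3]) for j in range(0, len(sol.x), 3)]


def full_fit_unmodified(freqs, log_power):
    """Whole published pipeline without any infant modification."""
    b, chi = robust_aperiodic_fit(freqs, log_power)
    flat = log_power - (b - chi * np.log10(freqs))
    guesses = iterative_peak_guesses(freqs, flat)
    peaks = joint_gaussian_fit(freqs, flat, guesses)
    peak_curve = np.zeros_like(freqs)
    for c, h, s in peaks:
        peak_curve += h * np.exp(-((freqs - c) ** 2) / (2 * s**2))
    b_final, chi_final = power_law_fit(freqs, log_power - peak_curve)
    return (b_final, chi_final), peaks
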