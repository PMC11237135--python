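"""Multitaper coherence, epoch selection and ANCOVA group comparison."""

import numpy as np
import pytest

from infantspec.coherence import (
    compare_groups_ancova,
    median_band_coherence,
    multitaper_coherence,
    reject_epochs_by_sd,
    stable_covariate_mask,
    CoherenceSpectrum,
)
from infantspec.synthetic import generate_coherent_pair


class TestRejectEpochsBySd:
    def test_identical_epochs_all_kept(self):
        epochs = np.tile(np.sin(np.linspace(0, 10, 500)), (10, 1))
        sel = reject_epochs_by_sd(epochs)
        assert sel.keep.all()

    def test_large_amplitude_epoch_rejected(self):
        rng = np.random.default_rng(0)
        epochs = rng.standard_normal((10, 500))
        epochs[4] *= 100.0
        sel = reject_epochs_by_sd(epochs, k=3.0)
        assert not sel.keep[4]
        assert sel.keep.sum() == 9

    def test_infinite_threshold_keeps_all(self):
        rng = np.random.default_rng(1)
        epochs = rng.standard_normal((5, 100)) * np.array([[1], [2], [5], [50], [500]])
        sel = reject_epochs_by_sd(epochs, k=np.inf)
        assert sel.keep.all()


class TestStableCovariateMask:
    def test_constant_covariate_eligible_after_history(self):
        t = np.arange(0, 600.0, 5.0)
        cov = np.full(t.shape, 2.0)
        epochs = np.array([60.0, 119.0, 120.0, 300.0])
        keep = stable_covariate_mask(t, cov, epochs)
        assert list(keep) == [False, False, True, True]

    def test_step_change_blocks_following_window(self):
        t = np.arange(0, 600.0, 5.0)
        cov = np.where(t < 300, 2.0, 2.5)
        epochs = np.array([250.0, 310.0, 415.0, 421.0])
        keep = stable_covariate_mask(t, cov, epochs)
        assert list(keep) == [True, False, False, True]

    def test_slow_ramp_within_tolerance(self):
        t = np.arange(0, 600.0, 5.0)
        cov = 2.0 + (0.1 / 120.0) * t  # 0.1 per 2 minutes
        keep = stable_covariate_mask(t, cov, np.array([150.0, 400.0]))
        assert keep.all()


class TestMultitaperCoherence:
    def test_identical_signals_coherence_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(250 * 30)
        cs = multitaper_coherence(x, x, 250.0)
        finite = np.isfinite(cs.coherence)
        assert np.allclose(cs.coherence[finite], 1.0, atol=1e-9)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(250 * 30)
        cs = multitaper_coherence(x, -x, 250.0)
        finite = np.isfinite(cs.coherence)
        assert np.allclose(cs.coherence[finite], 1.0, atol=1e-9)

    def test_scale_invariance(self):
        x, y = generate_coherent_pair(1.0, 1.0, (8, 12), 60, 250, seed=4)
        a = multitaper_coherence(x, y, 250.0)
        b = multitaper_coherence(5.0 * x, y, 250.0)
        finite = np.isfinite(a.coherence)
        assert np.allclose(a.coherence[finite], b.coherence[finite], atol=1e-12)

    def test_bounded_by_one(self):
        x, y = generate_coherent_pair(1.0, 0.5, (8, 12), 60, 250, seed=5)
        cs = multitaper_coherence(x, y, 250.0)
        finite = np.isfinite(cs.coherence)
        assert np.all(cs.coherence[finite] <= 1.0 + 1e-12)

    def test_taper_count_constraint(self):
        x = np.zeros(250 * 12)
        with pytest.raises(ValueError, match="K <= 2"):
            multitaper_coherence(x, x, 250.0, time_bandwidth=3.0, n_tapers=6)

    def test_closed_form_half_coherence(self):
        # sigma_s^2 = sigma_n^2 gives expected in-band coherence 0.5
        x, y = generate_coherent_pair(1.0, 1.0, (8.0, 12.0), 600, 250, seed=6)
        cs = multitaper_coherence(x, y, 250.0)
        med = median_band_coherence(cs, (8.0, 12.0))
        assert med == pytest.approx(0.5, abs=0.05)

    def test_independent_signals_low_coherence(self):
        x, _ = generate_coherent_pair(0.0, 1.0, (8, 12), 300, 250, seed=7)
        _, y = generate_coherent_pair(0.0, 1.0, (8, 12), 300, 250, seed=8)
        cs = multitaper_coherence(x, y, 250.0)
        assert median_band_coherence(cs, (8.0, 12.0)) < 0.2


class TestMedianBandCoherence:
    def _cs(self, freqs, coh):
        return CoherenceSpectrum(
            freqs=np.asarray(freqs, dtype=float), coherence=np.asarray(coh, dtype=float),
            window_s=6.0, time_bandwidth=3.0, n_tapers=5, n_windows=10,
        )

    def test_constant(self):
        cs = self._cs(np.arange(1.0, 20.0), np.full(19, 0.7))
        assert median_band_coherence(cs, (8, 12)) == 0.7

    def test_median_of_values(self):
        cs = self._cs([8.0, 10.0, 12.0], [0.1, 0.2, 0.9])
        assert median_band_coherence(cs, (8, 12)) == 0.2

    def test_empty_band_rejected(self):
        cs = self._cs([8.0, 10.0, 12.0], [0.1, 0.2, 0.9])
        with pytest.raises(ValueError, match="band"):
            median_band_coherence(cs, (30, 40))


def _brute_force_ancova(values, group, covariate):
    """F test for the group term via explicit residual sums of squares."""
    g = (np.asarray(group) == np.asarray(group)[0]).astype(float)
    X_full = np.column_stack([np.ones_like(values), g, covariate])
    X_red = np.column_stack([np.ones_like(values), covariate])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        r = values - X @ beta
        return float(r @ r)

    rss_full, rss_red = rss(X_full), rss(X_red)
    df_den = len(values) - X_full.shape[1]
    F = (rss_red - rss_full) / (rss_full / df_den)
    from scipy.stats import f as fdist

    return F, float(fdist.sf(F, 1, df_den))


class TestCompareGroupsAncova:
    def test_matches_brute_force_on_toy_data(self):
        values = np.array([0.30, 0.35, 0.42, 0.55, 0.60, 0.52])
        group = np.array(["absent", "absent", "absent", "present", "present", "present"])
        cov = np.array([1.8, 2.0, 2.2, 1.9, 2.1, 2.0])
        F, p = compare_groups_ancova(values, group, cov)
        F_o, p_o = _brute_force_ancova(values, group, cov)
        assert F == pytest.approx(F_o, rel=1e-9)
        assert p == pytest.approx(p_o, rel=1e-9)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(9)
        n = 20
        group = np.repeat(["absent", "present"], n)
        cov = rng.uniform(1.5, 2.5, 2 * n)
        values = np.where(group == "present", 0.62, 0.50) + 0.001 * rng.standard_normal(2 * n)
        _, p = compare_groups_ancova(values, group, cov)
        assert p < 1e-10

    def test_type_one_error_calibrated(self):
        # identical group distributions: p < 0.05 in ~5% of replicates
        rng = np.random.default_rng(10)
        hits = 0
        reps = 400
        for _ in range(reps):
            group = np.repeat(["a", "b"], 15)
            cov = rng.uniform(1.5, 2.5, 30)
            values = 0.5 + 0.1 * rng.standard_normal(30) + 0.05 * cov
            _, p = compare_groups_ancova(values, group, cov)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compare_groups_ancova(
                np.arange(6.0), np.repeat(["a", "b"], 3), np.full(6, 2.0)
            )

    def test_collinear_covariate_rejected(self):
        group = np.repeat(["a", "b"], 3)
        cov = np.where(group == "a", 1.0, 2.0)
        with pytest.raises(ValueError, match="collinear"):
            compare_groups_ancova(np.arange(6.0), group, cov)
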