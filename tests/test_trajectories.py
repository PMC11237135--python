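"""Spline mixed-model trajectories, FDR, inflection ages and rates."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from infantspec.synthetic import CohortSpec, generate_cohort, spline_peak_curve
from infantspec.trajectories import (
    TrajectoryModelSpec,
    adjust_fdr,
    fit_roi_contrast,
    fit_trajectory,
    inflection_points,
    standardized_rate,
    two_peak_age_model,
)


def _cubic(age):
    a = np.asarray(age, dtype=float) / 1000.0
    return 1.0 + 0.9 * a - 0.5 * a**2 + 0.08 * a**3


def _cohort(curve, n=120, subject_sd=0.0, study_sd=0.0, resid_sd=0.0, seed=1,
            sex_curves=None):
    spec = CohortSpec(
        n_subjects=n, visits_per_subject=3, age_range=(60.0, 1340.0),
        study_labels=("s1", "s2", "s3"),
        parameter_curves={"y": curve},
        random_effects={"y": (subject_sd, study_sd)},
        residual_sd={"y": resid_sd},
    )
    cohort = generate_cohort(spec, seed=seed)
    if sex_curves is not None:
        male = cohort["sex"] == "M"
        extra = sex_curves(cohort.loc[male, "age_days"].to_numpy())
        cohort.loc[male, "y"] += extra
    return cohort


class TestFitTrajectory:
    def test_low_noise_cohort_recovers_curve(self):
        cohort = _cohort(_cubic, subject_sd=0.02, resid_sd=0.02)
        fit = fit_trajectory(cohort, TrajectoryModelSpec(response="y"))
        truth = _cubic(fit.age_grid)
        rel = np.abs(fit.predicted - truth) / np.abs(truth)
        assert np.median(rel) < 0.02
        assert fit.chosen == "additive"

    def test_sex_specific_bump_selects_interaction(self):
        bump = lambda a: 0.35 * np.exp(-((np.asarray(a) - 600.0) ** 2) / (2 * 150.0**2))
        cohort = _cohort(_cubic, n=200, subject_sd=0.05, resid_sd=0.05,
                         sex_curves=bump, seed=7)
        fit = fit_trajectory(cohort, TrajectoryModelSpec(response="y"))
        assert fit.chosen == "interaction"
        assert fit.interaction_p < 0.05
        # male and female curves genuinely differ
        gap = np.max(np.abs(fit.predicted_by_sex["M"] - fit.predicted_by_sex["F"]))
        assert gap > 0.1

    def test_additive_nests_interaction_in_likelihood(self):
        cohort = _cohort(_cubic, subject_sd=0.05, resid_sd=0.05, seed=3)
        fit = fit_trajectory(cohort, TrajectoryModelSpec(response="y"))
        assert fit.loglike_interaction >= fit.loglike_additive - 1e-6

    def test_single_study_drops_study_effect_with_warning(self):
        spec = CohortSpec(
            n_subjects=40, visits_per_subject=3, age_range=(60.0, 1340.0),
            study_labels=("only",),
            parameter_curves={"y": _cubic},
            random_effects={"y": (0.05, 0.0)}, residual_sd={"y": 0.05},
        )
        cohort = generate_cohort(spec, seed=4)
        fit = fit_trajectory(cohort, TrajectoryModelSpec(response="y"))
        assert any("study" in w for w in fit.warnings_)

    def test_too_few_subjects_rejected(self):
        cohort = _cohort(_cubic, n=120).iloc[:3]
        with pytest.raises(ValueError, match="subjects"):
            fit_trajectory(cohort, TrajectoryModelSpec(response="y"))

    def test_prediction_grid_is_daily(self):
        cohort = _cohort(_cubic, subject_sd=0.02, resid_sd=0.02)
        fit = fit_trajectory(cohort, TrajectoryModelSpec(response="y"))
        assert np.allclose(np.diff(fit.age_grid), 1.0)
        assert fit.age_grid[0] <= cohort["age_days"].min()
        assert fit.age_grid[-1] >= cohort["age_days"].max()


class TestRoiContrast:
    def _roi_cohort(self, delta, seed=5):
        base = _cohort(_cubic, n=60, subject_sd=0.03, resid_sd=0.03, seed=seed)
        rows = []
        for roi in ("frontal", "central", "temporal", "posterior"):
            sub = base.copy()
            sub["roi"] = roi
            if roi == "central":
                sub["y"] += delta
            rows.append(sub)
        return pd.concat(rows, ignore_index=True)

    def test_identical_rois_near_zero_contrasts(self):
        out = fit_roi_contrast(self._roi_cohort(0.0), TrajectoryModelSpec(response="y"))
        assert np.max(np.abs(out["contrast"])) < 0.02

    def test_shifted_roi_recovers_delta(self):
        out = fit_roi_contrast(self._roi_cohort(0.25), TrajectoryModelSpec(response="y"))
        central = out.set_index("roi").loc["central", "contrast"]
        assert central == pytest.approx(0.25, abs=0.03)

    def test_reference_swap_flips_sign(self):
        cohort = self._roi_cohort(0.25)
        spec = TrajectoryModelSpec(response="y")
        vs_post = fit_roi_contrast(cohort, spec, reference="posterior").set_index("roi")
        vs_cent = fit_roi_contrast(cohort, spec, reference="central").set_index("roi")
        assert vs_post.loc["central", "contrast"] == pytest.approx(
            -vs_cent.loc["posterior", "contrast"], abs=0.02
        )

    def test_missing_reference_rejected(self):
        cohort = self._roi_cohort(0.0)
        with pytest.raises(ValueError, match="reference"):
            fit_roi_contrast(cohort, TrajectoryModelSpec(response="y"), reference="occipital")


class TestTwoPeakAgeModel:
    def _sim(self, B_true, seed=0, n=300):
        rng = np.random.default_rng(seed)
        subj = np.repeat([f"S{i}" for i in range(n // 2)], 2)
        age = rng.uniform(60, 180, n)
        u = np.repeat(rng.normal(0, 0.4, n // 2), 2)
        pr = 1.0 / (1.0 + np.exp(-(B_true * (age - age.mean()) + u)))
        y = (rng.random(n) < pr).astype(int)
        return y, age, subj

    def test_null_odds_ratio_near_one(self):
        y, age, subj = self._sim(0.0, seed=1)
        res = two_peak_age_model(y, age, subj)
        assert res["odds_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_recovers_negative_age_effect(self):
        # true decline of -0.018 per day, as in the 2-6-month window
        y, age, subj = self._sim(-0.018, seed=2)
        res = two_peak_age_model(y, age, subj)
        assert res["ci_lo"] - 0.005 <= -0.018 <= res["ci_hi"] + 0.005
        assert res["B"] < 0

    def test_or_exp_identity(self):
        y, age, subj = self._sim(-0.01, seed=3)
        res = two_peak_age_model(y, age, subj)
        assert res["odds_ratio"] == pytest.approx(np.exp(res["B"]), rel=1e-12)

    def test_complete_separation_rejected(self):
        age = np.array([60.0, 70.0, 80.0, 150.0, 160.0, 170.0])
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="separation"):
            two_peak_age_model(y, age, [f"S{i}" for i in range(6)])


def _bh_oracle(p):
    """Step-up BH by its textbook definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestAdjustFdr:
    def test_textbook_example(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            assert np.allclose(adjust_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_groupwise_adjustment_independent(self):
        p = np.array([0.01, 0.5, 0.01, 0.5])
        groups = ["roiA", "roiA", "roiB", "roiB"]
        q = adjust_fdr(p, groups)
        assert np.allclose(q[:2], adjust_fdr(p[:2]))
        assert np.allclose(q[2:], adjust_fdr(p[2:]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])


class TestInflectionPoints:
    def test_unimodal_peak_found(self):
        curve = spline_peak_curve((60.0, 1340.0), 372.0)
        grid = np.arange(60.0, 1341.0)
        infl = inflection_points(grid, curve(grid), order=100)
        maxima = [a for a in infl]
        assert any(abs(a - 372.0) <= 1.0 for a in maxima)

    def test_monotone_curve_no_extrema(self):
        grid = np.arange(0.0, 1000.0)
        assert inflection_points(grid, 0.001 * grid, order=100) == []

    def test_order_window_semantics(self):
        grid = np.arange(0.0, 1000.0)
        curve = 1.0 * np.exp(-((grid - 300) ** 2) / (2 * 60.0**2)) + 0.6 * np.exp(
            -((grid - 600) ** 2) / (2 * 60.0**2)
        )
        both = inflection_points(grid, curve, order=100)
        assert any(abs(a - 300) <= 2 for a in both)
        assert any(abs(a - 600) <= 2 for a in both)
        wide = inflection_points(grid, curve, order=400)
        assert any(abs(a - 300) <= 2 for a in wide)
        assert not any(abs(a - 600) <= 2 for a in wide)


class TestStandardizedRate:
    def test_linear_curve_constant_rate(self):
        vals = 2.0 + 0.01 * np.arange(500.0)
        rate = standardized_rate(vals)
        expected = 0.01 / np.std(vals)
        assert np.allclose(rate, expected)

    def test_constant_curve_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            rate = standardized_rate(np.full(100, 3.0))
        assert np.allclose(rate, 0.0)

    def test_symmetric_bump_antisymmetric_rate(self):
        grid = np.arange(-250.0, 251.0)
        vals = np.exp(-(grid**2) / (2 * 80.0**2))
        rate = standardized_rate(vals)
        assert np.allclose(rate, -rate[::-1], atol=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            standardized_rate(np.array([1.0]))


class TestAgainstMgcv:
    def test_predictions_match_mgcv_gamm(self, tmp_path):
        """Cross-check the spline mixed model against mgcv on one cohort."""
        cohort = _cohort(_cubic, n=80, subject_sd=0.08, study_sd=0.03,
                         resid_sd=0.08, seed=21)
        fit = fit_trajectory(cohort, TrajectoryModelSpec(response="y"))
        csv = tmp_path / "cohort.csv"
        out = tmp_path / "pred.csv"
        cohort.to_csv(csv, index=False)
        r_code = f"""
        library(mgcv)
        d <- read.csv("{csv}")
        d$oSex <- factor(d$sex, ordered = TRUE)
        d$New_ID <- factor(d$subject_id)
        d$Study <- factor(d$study)
        m <- gam(y ~ oSex + s(age_days, k = 4, fx = TRUE) +
                     s(New_ID, bs = "re") + s(Study, bs = "re"),
                 data = d, method = "ML")
        grid <- data.frame(age_days = seq(floor(min(d$age_days)), ceiling(max(d$age_days)), by = 1),
                           oSex = factor("F", levels = levels(d$oSex), ordered = TRUE),
                           New_ID = d$New_ID[1], Study = d$Study[1])
        p <- predict(m, newdata = grid, exclude = c("s(New_ID)", "s(Study)"), newdata.guaranteed = TRUE)
        write.csv(data.frame(age_days = grid$age_days, pred = p), "{out}", row.names = FALSE)
        """
        script = tmp_path / "fit.R"
        script.write_text(r_code)
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        rpred = pd.read_csv(out)
        n = min(len(rpred), len(fit.predicted))
        mine = fit.predicted[:n]
        theirs = rpred["pred"].to_numpy()[:n]
        # same smooth family, different basis parameterizations: allow a
        # small fraction of the curve's dynamic range, after aligning means
        rng_span = np.ptp(theirs)
        diff = (mine - mine.mean()) - (theirs - theirs.mean())
        assert np.max(np.abs(diff)) < 0.1 * rng_span
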