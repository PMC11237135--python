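"""Developmental trajectories of spectral features via spline mixed models.

Each feature is modelled over age in days with a fixed-degrees-of-freedom
smooth (a natural cubic regression spline with basis dimension k = 4,
i.e. 3 estimable spline columns, matching an unpenalized smooth term) plus
a sex main effect, with random intercepts for subject nested within study.
Two model forms are compared:

  additive:     value ~ sex + s(age)            + (1|subject) + (1|study)
  interaction:  value ~ sex + s(age) + s(age):sex + (1|subject) + (1|study)

Both are fit by maximum likelihood (statsmodels MixedLM); the interaction
model is chosen when a likelihood-ratio test between the nested forms is
significant at alpha = 0.05.  Predictions are made on a 1-day grid across
the observed age range with pointwise 95% intervals from the fixed-effect
covariance.

Post-processing: relative extrema of the predicted curve within a +/-100
day comparison window ("inflection ages"), the standardized daily rate of
change (day-to-day difference divided by the sd of the modelled values
over the full range), and Benjamini-Hochberg FDR adjustment of term
p-values grouped by region of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.signal import argrelextrema
from scipy.stats import chi2, norm

__all__ = [
    "TrajectoryModelSpec",
    "TrajectoryFit",
    "fit_trajectory",
    "fit_roi_contrast",
    "two_peak_age_model",
    "adjust_fdr",
    "inflection_points",
    "standardized_rate",
]

class _AgeSmooth:
    """Fixed-df natural cubic spline basis for age with centering constraint.

    A k-dimensional cubic regression spline is built on the training ages,
    its columns centered (projecting out the constant, as a sum-to-zero
    constraint does) and one dropped, leaving k - 1 estimable columns to
    accompany a separate intercept — the unpenalized analogue of a basis-
    dimension-k smooth term.
    """

    def __init__(self, ages: np.ndarray, k: int):
        self.k = k
        df_train = pd.DataFrame({"age_days": np.asarray(ages, dtype=float)})
        X = patsy.dmatrix(f"cr(age_days, df={k}) - 1", df_train, return_type="dataframe")
        self.design_info = X.design_info
        self.col_means = X.to_numpy().mean(axis=0)

    def transform(self, ages: np.ndarray) -> np.ndarray:
        new = pd.DataFrame({"age_days": np.asarray(ages, dtype=float)})
        (X,) = patsy.build_design_matrices([self.design_info], new)
        X = np.asarray(X) - self.col_means
        return X[:, : self.k - 1]


@dataclass(frozen=True)
class TrajectoryModelSpec:
    """Model form for one feature's age trajectory.

    ``k`` is the basis dimension of the smooth (k - 1 spline columns are
    estimated, the analogue of an unpenalized k = 4 smooth).  The
    interaction model nests the additive model by construction.
    """

    response: str
    k: int = 4
    alpha: float = 0.05
    subject_col: str = "subject_id"
    study_col: str = "study"
    sex_col: str = "sex"
    age_col: str = "age_days"


@dataclass(frozen=True)
class TrajectoryFit:
    """Fitted trajectory: daily predictions, term tests, chosen model."""

    spec: TrajectoryModelSpec
    age_grid: np.ndarray
    predicted: np.ndarray          # reference-sex (female) curve
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    predicted_by_sex: Mapping[str, np.ndarray]
    chosen: str                    # "additive" or "interaction"
    interaction_p: float
    term_pvalues: Mapping[str, float]
    loglike_additive: float
    loglike_interaction: float
    n_obs: int
    warnings_: tuple[str, ...] = field(default_factory=tuple)


def _fit_mixedlm(
    endog: np.ndarray,
    exog: pd.DataFrame,
    data: pd.DataFrame,
    spec: TrajectoryModelSpec,
    drop_study: bool,
):
    """ML fit of a mixed model with subject (and study) random intercepts."""
    df = data.copy()
    df["_y"] = endog
    for c in exog.columns:
        df[f"_x_{hash(c) & 0xFFFFFF:x}"] = exog[c].to_numpy()
    xcols = [c for c in df.columns if c.startswith("_x_")]
    if drop_study:
        groups = df[spec.subject_col]
        md = sm.MixedLM(df["_y"], df[xcols], groups=groups)
    else:
        vcf = {"subject": f"0 + C({spec.subject_col})"}
        md = sm.MixedLM.from_formula(
            "_y ~ 0 + " + " + ".join(xcols),
            groups=spec.study_col,
            vc_formula=vcf,
            re_formula="1",
            data=df,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=False, method="lbfgs", maxiter=200)
    return res


def _fixed_design(
    smooth: _AgeSmooth, ages: np.ndarray, sex_m: np.ndarray, interaction: bool
) -> pd.DataFrame:
    B = smooth.transform(ages)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(ages)), "sex_m": sex_m}
    for j in range(B.shape[1]):
        cols[f"s_age_{j}"] = B[:, j]
    if interaction:
        for j in range(B.shape[1]):
            cols[f"s_age_{j}:sex_m"] = B[:, j] * sex_m
    return pd.DataFrame(cols)


def fit_trajectory(
    cohort: pd.DataFrame, spec: TrajectoryModelSpec
) -> TrajectoryFit:
    """Fit additive and interaction spline mixed models and select one.

    Requires >= 2 subjects; with fewer than 2 studies the study random
    intercept is dropped with a warning.  Raises on rank deficiency with
    the offending term named.
    """
    data = cohort.dropna(subset=[spec.response, spec.age_col]).copy()
    if data[spec.subject_col].nunique() < 2:
        raise ValueError("need at least 2 subjects to fit subject random effects")
    warns: list[str] = []
    drop_study = data[spec.study_col].nunique() < 2
    if drop_study:
        warns.append("single study: study random intercept dropped")
    # Sex as an ordered two-level factor reduces to a single contrast column.
    data["_sex_m"] = (data[spec.sex_col].astype(str).str.upper().str[0] == "M").astype(float)

    y = data[spec.response].to_numpy(dtype=float)
    ages_arr = data[spec.age_col].to_numpy(dtype=float)
    sex_arr = data["_sex_m"].to_numpy(dtype=float)
    smooth = _AgeSmooth(ages_arr, spec.k)
    X_add = _fixed_design(smooth, ages_arr, sex_arr, interaction=False)
    X_int = _fixed_design(smooth, ages_arr, sex_arr, interaction=True)
    for name, X in (("additive", X_add), ("interaction", X_int)):
        sv = np.linalg.svd(X.to_numpy(), compute_uv=False)
        if sv[-1] < 1e-8 * sv[0]:
            raise ValueError(
                f"rank-deficient {name} design "
                f"(near-singular direction involves {X.columns[-1]!r} or sex term)"
            )

    res_add = _fit_mixedlm(y, X_add, data, spec, drop_study)
    res_int = _fit_mixedlm(y, X_int, data, spec, drop_study)

    # LRT between nested ML fits; df = number of interaction columns.
    df_diff = X_int.shape[1] - X_add.shape[1]
    lr = 2.0 * (res_int.llf - res_add.llf)
    interaction_p = float(chi2.sf(max(lr, 0.0), df_diff))
    chosen = "interaction" if interaction_p < spec.alpha else "additive"
    res, X_train = (res_int, X_int) if chosen == "interaction" else (res_add, X_add)

    # Wald tests per term on the chosen model.
    fe = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
    colnames = list(X_train.columns)

    def wald(cols: list[int]) -> float:
        if not cols:
            return float("nan")
        b = fe[cols]
        V = cov[np.ix_(cols, cols)]
        stat = float(b @ np.linalg.solve(V, b))
        return float(chi2.sf(stat, len(cols)))

    sex_cols = [i for i, c in enumerate(colnames) if c == "sex_m"]
    smooth_cols = [i for i, c in enumerate(colnames) if c.startswith("s_age_") and ":" not in c]
    inter_cols = [i for i, c in enumerate(colnames) if c.startswith("s_age_") and ":" in c]
    term_pvalues = {
        "sex": wald(sex_cols),
        "s(age_days)": wald(smooth_cols),
        "s(age_days):sex": wald(inter_cols) if inter_cols else float("nan"),
    }

    # Daily prediction grid over the observed age range, per sex.
    grid = np.arange(np.floor(ages_arr.min()), np.ceil(ages_arr.max()) + 1.0)
    preds: dict[str, np.ndarray] = {}
    ci: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sex_label, sex_val in (("F", 0.0), ("M", 1.0)):
        Xg = _fixed_design(
            smooth, grid, np.full(grid.shape, sex_val), interaction=(chosen == "interaction")
        ).to_numpy()
        mu = Xg @ fe
        var = np.einsum("ij,jk,ik->i", Xg, cov, Xg)
        se = np.sqrt(np.clip(var, 0.0, None))
        preds[sex_label] = mu
        ci[sex_label] = (mu - 1.96 * se, mu + 1.96 * se)

    return TrajectoryFit(
        spec=spec,
        age_grid=grid,
        predicted=preds["F"],
        ci_lo=ci["F"][0],
        ci_hi=ci["F"][1],
        predicted_by_sex=preds,
        chosen=chosen,
        interaction_p=interaction_p,
        term_pvalues=term_pvalues,
        loglike_additive=float(res_add.llf),
        loglike_interaction=float(res_int.llf),
        n_obs=len(data),
        warnings_=tuple(warns),
    )


def fit_roi_contrast(
    cohort: pd.DataFrame,
    spec: TrajectoryModelSpec,
    roi_col: str = "roi",
    reference: str = "posterior",
) -> pd.DataFrame:
    """Additive model with ROI main effects contrasted against a reference.

    Returns one row per non-reference ROI with the estimated contrast, its
    standard error and p-value.  The reference level must be present.
    """
    data = cohort.dropna(subset=[spec.response, spec.age_col]).copy()
    levels = set(data[roi_col].astype(str))
    if reference not in levels:
        raise ValueError(f"reference ROI {reference!r} missing from {sorted(levels)}")
    if len(levels) < 2:
        raise ValueError("need at least 2 ROI levels")
    data["_sex_m"] = (data[spec.sex_col].astype(str).str.upper().str[0] == "M").astype(float)
    ages_arr = data[spec.age_col].to_numpy(dtype=float)
    smooth = _AgeSmooth(ages_arr, spec.k)
    X = _fixed_design(
        smooth, ages_arr, data["_sex_m"].to_numpy(dtype=float), interaction=False
    )
    roi_dummies = pd.get_dummies(data[roi_col].astype(str), prefix=roi_col, dtype=float)
    roi_dummies = roi_dummies.drop(columns=f"{roi_col}_{reference}")
    X = pd.concat([X.reset_index(drop=True), roi_dummies.reset_index(drop=True)], axis=1)
    drop_study = data[spec.study_col].nunique() < 2
    res = _fit_mixedlm(data[spec.response].to_numpy(dtype=float), X, data, spec, drop_study)
    fe = res.fe_params.to_numpy()
    se = np.sqrt(np.diag(res.cov_params().to_numpy()))[: len(fe)]
    rows = []
    for i, c in enumerate(X.columns):
        if not c.startswith(f"{roi_col}_"):
            continue
        level = c[len(roi_col) + 1 :]
        z = float(fe[i] / se[i])
        rows.append(
            {
                "roi": level,
                "contrast": float(fe[i]),
                "se": float(se[i]),
                "z": z,
                "p": float(2.0 * norm.sf(abs(z))),
            }
        )
    return pd.DataFrame(rows)


def two_peak_age_model(
    present: Sequence[int] | np.ndarray,
    age_days: Sequence[float] | np.ndarray,
    subject: Sequence[str] | np.ndarray,
) -> dict[str, float]:
    """Logistic mixed model of two-peak presence on age (per-day effect).

    A variational-Bayes logistic mixed model with a subject random
    intercept; reports the age slope B (log-odds per day), OR = exp(B) and
    a 95% interval from the posterior sd.  Complete separation raises a
    diagnostic error.
    """
    present = np.asarray(present, dtype=float)
    age_days = np.asarray(age_days, dtype=float)
    if set(np.unique(present)) - {0.0, 1.0}:
        raise ValueError("present must be binary")
    if present.min() == present.max():
        raise ValueError("response is constant; model not identifiable")
    thr_lo = age_days[present == 1].max()
    thr_hi = age_days[present == 0].min()
    if thr_lo < thr_hi or age_days[present == 0].max() < age_days[present == 1].min():
        raise ValueError("complete separation of presence by age; GLMM not identifiable")
    df = pd.DataFrame(
        {
            "present": present,
            # Centered age keeps the VB optimization well scaled.
            "age_c": age_days - age_days.mean(),
            "subject": np.asarray(subject).astype(str),
        }
    )
    model = sm.BinomialBayesMixedGLM.from_formula(
        "present ~ age_c", {"subject": "0 + C(subject)"}, df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit_vb()
    idx = list(fit.model.exog_names).index("age_c")
    b = float(fit.fe_mean[idx])
    sd = float(fit.fe_sd[idx])
    return {
        "B": b,
        "odds_ratio": float(np.exp(b)),
        "ci_lo": b - 1.96 * sd,
        "ci_hi": b + 1.96 * sd,
        "sd": sd,
    }


def adjust_fdr(
    pvalues: Sequence[float] | np.ndarray,
    groups: Sequence | np.ndarray | None = None,
) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, computed within each group.

    The grouping reflects the correction unit of the analysis: each model
    term within each region of interest across the measure types.  With
    ``groups=None`` a single family is assumed.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.empty_like(p)
    if groups is None:
        group_ids = np.zeros(p.shape, dtype=int)
    else:
        group_ids = pd.factorize(np.asarray(groups))[0]
        if group_ids.shape != p.shape:
            raise ValueError("groups must match pvalues in length")
    for g in np.unique(group_ids):
        mask = group_ids == g
        q[mask] = sm.stats.multipletests(p[mask], method="fdr_bh")[1]
    return q


def inflection_points(
    age_grid: np.ndarray,
    predicted: np.ndarray,
    order: int = 100,
    mode: str = "curve",
) -> list[float]:
    """Ages of relative extrema of the modelled curve (+/- ``order`` days).

    ``mode="curve"`` finds strict maxima/minima of the prediction itself
    (the operational definition used for trajectory milestones);
    ``mode="derivative"`` applies the same search to the first difference.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    values = np.asarray(predicted, dtype=float)
    if mode == "derivative":
        values = np.diff(values)
        age_grid = age_grid[:-1]
    elif mode != "curve":
        raise ValueError("mode must be 'curve' or 'derivative'")
    if values.size < 3:
        return []
    maxima = argrelextrema(values, np.greater, order=order)[0]
    minima = argrelextrema(values, np.less, order=order)[0]
    idx = sorted(np.concatenate([maxima, minima]))
    return [float(age_grid[i]) for i in idx]


def standardized_rate(predicted: np.ndarray) -> np.ndarray:
    """Standardized change per day: diff(curve) / sd(curve over full range).

    A constant curve yields all zeros with a degenerate-sd warning.
    """
    values = np.asarray(predicted, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 daily predictions")
    sd = float(np.std(values))
    if sd == 0:
        warnings.warn("constant trajectory: standardized rate is identically 0")
        return np.zeros(values.size - 1)
    return np.diff(values) / sd
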