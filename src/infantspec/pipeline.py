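"""Pipeline orchestration: simulate -> psd -> fit -> features -> trajectories.

Runs the stages on a synthetic cohort (or on user-provided spectra CSVs),
applies the EEG-level rejection rules, and writes CSV artifacts plus a QC
report and the resolved configuration next to every run's outputs.  All
randomness flows from the single config seed, so a rerun with the same
config produces byte-identical feature tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .parameterization import FitConfig, fit_full_model, restrict_range
from .periodic import (
    PeriodicSpectrum,
    band_power_table,
    count_theta_alpha_peaks,
    find_band_peak,
    smooth_periodic,
)
from .spectral import psd_from_timeseries
from .synthetic import (
    CohortSpec,
    SpectrumParams,
    derive_seed,
    generate_cohort,
    generate_timeseries,
)

logger = logging.getLogger("infantspec.pipeline")

__all__ = ["QcRecord", "QcReport", "apply_rejection_rules", "run_pipeline", "default_cohort_spec"]


@dataclass
class QcRecord:
    """Per-EEG quality metrics; optional HAPPE-style fields may be None."""

    eeg_id: str
    n_segments: int
    n_grid_points: int = 0
    r_squared: float = float("nan")
    fit_error: float = float("nan")
    pct_good_channels: float | None = None
    pct_ics_rejected: float | None = None
    mean_artifact_probability: float | None = None
    pct_variance_retained: float | None = None
    keep: bool = True
    reasons: tuple[str, ...] = ()


@dataclass
class QcReport:
    records: list[QcRecord] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "records": [dataclasses.asdict(r) for r in self.records],
                "stage_seconds": self.stage_seconds,
                "warnings": self.warnings,
            },
            indent=2,
        )


def apply_rejection_rules(record: QcRecord, config: RunConfig = RunConfig()) -> QcRecord:
    """Reject an EEG failing the data-quality rules.

    Always applied: fewer than ``min_segments`` 2-s segments (i.e. < 40 s
    of usable EEG).  Applied only when the metric was supplied: percent
    good channels < 80, percent ICs rejected > 80, mean artifact
    probability > 0.3, percent variance retained < 25.
    """
    reasons = []
    if record.n_segments < config.min_segments:
        reasons.append(f"segments {record.n_segments} < {config.min_segments}")
    if (
        record.pct_good_channels is not None
        and record.pct_good_channels < config.min_pct_good_channels
    ):
        reasons.append(f"good channels {record.pct_good_channels}% < {config.min_pct_good_channels}%")
    if (
        record.pct_ics_rejected is not None
        and record.pct_ics_rejected > config.max_pct_ics_rejected
    ):
        reasons.append(f"ICs rejected {record.pct_ics_rejected}% > {config.max_pct_ics_rejected}%")
    if (
        record.mean_artifact_probability is not None
        and record.mean_artifact_probability > config.max_artifact_probability
    ):
        reasons.append(
            f"artifact probability {record.mean_artifact_probability} > {config.max_artifact_probability}"
        )
    if (
        record.pct_variance_retained is not None
        and record.pct_variance_retained < config.min_pct_variance_retained
    ):
        reasons.append(
            f"variance retained {record.pct_variance_retained}% < {config.min_pct_variance_retained}%"
        )
    return dataclasses.replace(record, keep=not reasons, reasons=tuple(reasons))


def _alpha_height_curve(age: np.ndarray) -> np.ndarray:
    # Transient 9.5 Hz alpha expression wanes between 2 and 6 months.
    return 0.35 * np.exp(-np.clip(age - 60.0, 0, None) / 90.0) + 0.25


def default_cohort_spec(n_subjects: int = 20, visits: int = 3) -> CohortSpec:
    """Cohort whose spectral parameters follow infant-like age curves.

    Aperiodic offset rises steeply over the first year then plateaus;
    exponent rises gradually; high-beta peak amplitude rises then falls
    with a maximum near the end of the first year.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        visits_per_subject=visits,
        age_range=(60.0, 1340.0),
        parameter_curves={
            "offset": lambda a: 1.0 + 0.8 * (1.0 - np.exp(-a / 250.0)),
            "exponent": lambda a: 0.8 + 0.4 * (1.0 - np.exp(-a / 400.0)),
            "alpha_height": _alpha_height_curve,
            "high_beta_height": lambda a: 0.25
            + 0.2 * np.exp(-((a - 372.0) ** 2) / (2 * 200.0**2)),
        },
        random_effects={
            "offset": (0.1, 0.05),
            "exponent": (0.05, 0.02),
            "alpha_height": (0.03, 0.0),
            "high_beta_height": (0.03, 0.0),
        },
        residual_sd={
            "offset": 0.05,
            "exponent": 0.03,
            "alpha_height": 0.02,
            "high_beta_height": 0.02,
        },
    )


def _params_from_row(row: pd.Series) -> SpectrumParams:
    peaks = []
    alpha_h = max(float(row.get("alpha_height", 0.0)), 0.0)
    if alpha_h > 0:
        peaks.append((9.5, alpha_h, 1.2))
    hb_h = max(float(row.get("high_beta_height", 0.0)), 0.0)
    if hb_h > 0:
        peaks.append((27.0, hb_h, 3.0))
    return SpectrumParams(
        offset=float(row["offset"]),
        exponent=max(float(row["exponent"]), 0.0),
        peaks=tuple(peaks),
        noise_sd=0.0,
        freq_range=(2.0, 55.0),
    )


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> QcReport:
    """Execute the configured stages and write artifacts under output_dir.

    Outputs: cohort.csv, features.csv, qc_report.json, resolved_config.yaml
    and (when the trajectories stage runs) trajectory.csv, inflections.csv
    and rates.csv.  Raises FileNotFoundError for missing inputs.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = QcReport()
    fit_cfg = FitConfig(
        peak_width_limits=config.peak_width_limits,
        max_n_peaks=config.max_n_peaks,
        peak_threshold=config.peak_threshold,
        fit_range=(config.fit_lo_hz, config.fit_hi_hz),
    )

    if "simulate" not in config.stages:
        cohort_path = Path(config.input_dir) / "cohort.csv"
        if not cohort_path.exists():
            raise FileNotFoundError(f"input cohort table not found: {cohort_path}")
        cohort = pd.read_csv(cohort_path)
    else:
        t0 = time.time()
        cohort = generate_cohort(
            default_cohort_spec(config.n_subjects, config.visits_per_subject),
            seed=config.seed,
        )
        report.stage_seconds["simulate"] = time.time() - t0
        logger.info("simulated cohort: %d rows", len(cohort))
        cohort.to_csv(out / "cohort.csv", index=False)

    feature_rows = []
    t0 = time.time()
    duration = config.epoch_len_s * max(config.min_segments, 25)
    for i, row in cohort.iterrows():
        eeg_id = f"{row['subject_id']}_v{int(row['visit'])}"
        params = _params_from_row(row)
        ts = generate_timeseries(
            params,
            duration=duration,
            fs=config.fs_hz,
            seed=derive_seed(config.seed, 2, int(i)),
            epoch_len=config.epoch_len_s,
        )
        spectrum = psd_from_timeseries(
            ts, config.fs_hz, epoch_len=config.epoch_len_s, n_tapers=config.n_tapers,
            label="whole",
        )
        n_segments = int(round(duration / config.epoch_len_s))
        rec = QcRecord(eeg_id=eeg_id, n_segments=n_segments, n_grid_points=len(spectrum.freqs))
        rec = apply_rejection_rules(rec, config)
        if not rec.keep:
            report.records.append(rec)
            report.warnings.append(f"{eeg_id}: rejected ({'; '.join(rec.reasons)})")
            continue

        fit = fit_full_model(
            restrict_range(spectrum, config.fit_lo_hz, config.fit_hi_hz),
            fit_cfg,
            modified=config.modified,
            restrict=False,
        )
        rec = dataclasses.replace(rec, r_squared=fit.r_squared, fit_error=fit.mean_abs_error)
        report.records.append(rec)
        if not fit.converged:
            report.warnings.append(f"{eeg_id}: {fit.diagnostics}")

        ps = PeriodicSpectrum(freqs=fit.freqs, residual=fit.periodic_residual())
        smoothed = smooth_periodic(
            ps, config.savgol_window, config.savgol_polyorder, config.smooth_grid_step_hz
        )
        n_ta, _ = count_theta_alpha_peaks(
            smoothed, min_separation=config.two_peak_min_separation_hz
        )
        feats = {
            "eeg_id": eeg_id,
            "subject_id": row["subject_id"],
            "study": row["study"],
            "sex": row["sex"],
            "age_days": row["age_days"],
            "roi": "whole",
            "aperiodic_offset_2p5": fit.offset_at_2p5,
            "aperiodic_exponent": fit.aperiodic.exponent,
            "r_squared": fit.r_squared,
            "mean_abs_error": fit.mean_abs_error,
            "n_theta_alpha_peaks": n_ta,
        }
        for band in ("theta", "theta_alpha", "low_beta", "high_beta"):
            pk = find_band_peak(smoothed, band)
            feats[f"{band}_present"] = int(pk.present)
            feats[f"{band}_peak_freq"] = pk.peak_freq
            feats[f"{band}_amplitude"] = pk.amplitude
        aper_curve = fit.aperiodic_curve()
        per_curve = fit.periodic_residual()
        feats.update(band_power_table(fit.freqs, aper_curve, per_curve))
        feature_rows.append(feats)
    report.stage_seconds["psd_fit_features"] = time.time() - t0

    features = pd.DataFrame(feature_rows)
    features.to_csv(out / "features.csv", index=False)

    if "trajectories" in config.stages and len(features) >= 10:
        from .trajectories import (
            TrajectoryModelSpec,
            fit_trajectory,
            inflection_points,
            standardized_rate,
        )

        t0 = time.time()
        spec = TrajectoryModelSpec(
            response="aperiodic_offset_2p5", k=config.basis_dim_k,
            alpha=config.selection_alpha,
        )
        try:
            fit = fit_trajectory(features, spec)
            pd.DataFrame(
                {
                    "age_days": fit.age_grid,
                    "predicted": fit.predicted,
                    "ci_lo": fit.ci_lo,
                    "ci_hi": fit.ci_hi,
                }
            ).to_csv(out / "trajectory.csv", index=False)
            infl = inflection_points(
                fit.age_grid, fit.predicted, order=config.inflection_order_days
            )
            pd.DataFrame({"inflection_age_days": infl}).to_csv(
                out / "inflections.csv", index=False
            )
            rate = standardized_rate(fit.predicted)
            pd.DataFrame(
                {"age_days": fit.age_grid[:-1], "standardized_rate": rate}
            ).to_csv(out / "rates.csv", index=False)
        except ValueError as err:
            report.warnings.append(f"trajectories stage skipped: {err}")
        report.stage_seconds["trajectories"] = time.time() - t0

    resolved = dataclasses.replace(config)
    save_config(resolved, out / "resolved_config.yaml")
    (out / "qc_report.json").write_text(report.to_json())
    (out / "VERSION").write_text(__version__ + "\n")
    return report
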