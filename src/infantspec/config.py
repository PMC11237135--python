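"""Run configuration for the pipeline: every tunable in one serializable place.

Defaults mirror the analysis conventions: 2-s segments, 3 tapers, fit range
2.5-50 Hz, peak_width_limits [0.5, 18], max 7 peaks, peak threshold 2,
Savitzky-Golay window 101 / polyorder 8 on a 0.1 Hz resampled grid,
coherence windows T = 6 s with TW = 3 and K = 5, alpha band 8-12 Hz,
smooth basis dimension k = 4.  Configs round-trip through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 0
    # spectral
    epoch_len_s: float = 2.0
    n_tapers: int = 3
    fs_hz: float = 250.0
    # parameterization
    fit_lo_hz: float = 2.5
    fit_hi_hz: float = 50.0
    peak_width_limits: tuple[float, float] = (0.5, 18.0)
    max_n_peaks: int = 7
    peak_threshold: float = 2.0
    modified: bool = True
    # periodic features
    savgol_window: int = 101
    savgol_polyorder: int = 8
    smooth_grid_step_hz: float = 0.1
    two_peak_min_separation_hz: float = 1.0
    # coherence
    coherence_window_s: float = 6.0
    coherence_tw: float = 3.0
    coherence_n_tapers: int = 5
    alpha_band: tuple[float, float] = (8.0, 12.0)
    epoch_sd_factor: float = 3.0
    covariate_window_s: float = 120.0
    covariate_tolerance: float = 0.2
    # trajectories
    basis_dim_k: int = 4
    selection_alpha: float = 0.05
    inflection_order_days: int = 100
    # rejection rules
    min_segments: int = 20
    min_pct_good_channels: float = 80.0
    max_pct_ics_rejected: float = 80.0
    max_artifact_probability: float = 0.3
    min_pct_variance_retained: float = 25.0
    # stages / paths
    stages: tuple[str, ...] = ("simulate", "psd", "fit", "features", "trajectories")
    input_dir: str = ""
    output_dir: str = "outputs"
    # simulate stage
    n_subjects: int = 20
    visits_per_subject: int = 3

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("peak_width_limits", "alpha_band", "stages"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("peak_width_limits", "alpha_band", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
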