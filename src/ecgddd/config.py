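"""YAML run configuration: validated, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import CohortConfig, DrunkDeltas, NoiseConfig


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(50, ge=1)
    sessions_per_subject: int = Field(1, ge=1)
    record_minutes: float = Field(2.0, gt=0)
    mean_hr_bpm: float = Field(71.0, gt=0)
    hr_sd_bpm: float = Field(8.0, ge=0)
    rr_sd_ms: float = Field(30.0, ge=0)
    subject_amp_cv: float = Field(0.25, ge=0)
    subject_pwidth_sd_ms: float = Field(2.5, ge=0)
    sampling_rate: float = Field(360.0, ge=250)
    dispersion_window: int = Field(10, ge=2)
    baseline_amp_mV: float = Field(0.05, ge=0)
    baseline_freq_hz: float = Field(0.3, gt=0)
    powerline_amp_mV: float = Field(0.0, ge=0)
    white_sd_mV: float = Field(0.02, ge=0)

    def to_cohort_config(self, seed: int) -> CohortConfig:
        return CohortConfig(
            n_subjects=self.n_subjects,
            sessions_per_subject=self.sessions_per_subject,
            record_minutes=self.record_minutes,
            mean_hr_bpm=self.mean_hr_bpm,
            hr_sd_bpm=self.hr_sd_bpm,
            rr_sd_ms=self.rr_sd_ms,
            subject_amp_cv=self.subject_amp_cv,
            subject_pwidth_sd_ms=self.subject_pwidth_sd_ms,
            drunk_deltas=DrunkDeltas(),
            noise=NoiseConfig(
                baseline_amp_mV=self.baseline_amp_mV,
                baseline_freq_hz=self.baseline_freq_hz,
                powerline_amp_mV=self.powerline_amp_mV,
                white_sd_mV=self.white_sd_mV,
            ),
            sampling_rate=self.sampling_rate,
            dispersion_window=self.dispersion_window,
            seed=seed,
        )


class RunConfig(BaseModel):
    """Top-level pipeline configuration (YAML-loadable)."""

    model_config = ConfigDict(extra="forbid")

    cohort: CohortSettings = Field(default_factory=CohortSettings)
    window_beats: int = Field(10, ge=3)
    stride: int = Field(1, ge=1)
    kernels: list[str] = Field(default_factory=lambda: ["all"])
    C: float = Field(10.0, gt=0)
    gamma: float = Field(0.5, gt=0)
    k_folds: int = Field(10, ge=2)
    seed: int = 0
    discard_seconds: float = Field(30.0, ge=0)
    out_dir: str = "ecgddd_out"
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
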