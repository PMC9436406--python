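"""Configuration models for synthetic cohorts and pipeline runs.

All tunables are validated pydantic models so a YAML config round-trips
losslessly into the run manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class ConditionSpec(BaseModel):
    """One treatment condition: a label, a dose in µM and a drug family flag.

    ``selenite=False`` marks a non-selenite arm (e.g. gemcitabine) so that
    pooled-selenite summaries and the responder model can tell them apart.
    """

    label: str
    dose_um: float = Field(ge=0)
    selenite: bool = True


#: The study design: untreated 72 h control, three sodium selenite doses
#: (5/15/30 µM) and gemcitabine 1 µM.
CONDITIONS_DEFAULT: tuple[ConditionSpec, ...] = (
    ConditionSpec(label="control_72h", dose_um=0.0),
    ConditionSpec(label="se5", dose_um=5.0),
    ConditionSpec(label="se15", dose_um=15.0),
    ConditionSpec(label="se30", dose_um=30.0),
    ConditionSpec(label="gem1", dose_um=1.0, selenite=False),
)


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic annotation-measurement cohort.

    Defaults emulate the study design: 8 patient cultures, 5 conditions in
    duplicate slices, ~14 slices per tumor (range 9-18), six outgrowth
    morphology classes, an Emax/Hill dose-dependent loss of the viable
    fraction (minimal at 5 µM, >90% damage at 15-30 µM), gemcitabine
    effective in ~1 of 8 patients, and 2 of 8 patients quantified by
    within-slice area instead of outgrowth.
    """

    n_patients: int = Field(default=8, ge=1)
    conditions: tuple[ConditionSpec, ...] = CONDITIONS_DEFAULT
    duplicates_per_condition: int = Field(default=2, ge=1)
    slices_per_tumor_mean: int = Field(default=14, ge=1)
    perimeter_mean_um: float = Field(default=20000.0, gt=0)
    # Baseline viable fraction ~ Beta(8, 2): mean 0.8, matching a control
    # viability around 80%.
    v0_alpha: float = Field(default=8.0, gt=0)
    v0_beta: float = Field(default=2.0, gt=0)
    # Emax/Hill dose response of the viable fraction.
    emax: float = Field(default=0.99, ge=0, le=1)
    ec50_um: float = Field(default=7.0, gt=0)
    hill: float = Field(default=4.0, gt=0)
    # Outgrowth fraction of the perimeter and its dose-dependent decline.
    outgrowth0: float = Field(default=0.55, ge=0, le=1)
    outgrowth_decline: float = Field(default=0.7, ge=0, le=1)
    # Logit-scale normal noise between duplicate slices.
    noise_sd: float = Field(default=0.3, ge=0)
    area_mode_patients: int = Field(default=2, ge=0)
    gem_responder_prob: float = Field(default=1.0 / 8.0, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_counts(self) -> "SyntheticConfig":
        if self.area_mode_patients > self.n_patients:
            raise ValueError("area_mode_patients cannot exceed n_patients")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        return self

    @property
    def condition_labels(self) -> list[str]:
        return [c.label for c in self.conditions]


class RunConfig(BaseModel):
    """End-to-end pipeline run configuration.

    Either ``annotation_table`` points at an existing measurement table or
    ``synthetic`` describes a cohort to simulate.  ``de_table`` is an
    optional differential-expression results table for the filtering stage.
    """

    synthetic: Optional[SyntheticConfig] = None
    annotation_table: Optional[Path] = None
    de_table: Optional[Path] = None
    control_condition: str = "control_72h"
    # BH family: treatment columns tested against control; None = all
    # non-control conditions.
    bh_family: Optional[list[str]] = None
    readouts_to_test: list[str] = Field(
        default_factory=lambda: ["viability_pct", "outgrowth_pct", "tvi"]
    )
    viable_weight: float = Field(default=3.0, gt=0)
    damaged_weight: float = Field(default=1.0, gt=0)
    evans_thresholds: tuple[float, float, float] = (10.0, 50.0, 90.0)
    out_dir: Path = Path("results/run")
    seed: int = 0
    verbosity: str = "INFO"

    @field_validator("evans_thresholds")
    @classmethod
    def _sorted_thresholds(cls, v: tuple[float, float, float]):
        if not (0 < v[0] < v[1] < v[2] < 100):
            raise ValueError("Evans thresholds must be strictly increasing in (0, 100)")
        return v

    @model_validator(mode="after")
    def _need_input(self) -> "RunConfig":
        if self.synthetic is None and self.annotation_table is None:
            raise ValueError("either synthetic config or annotation_table is required")
        return self
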