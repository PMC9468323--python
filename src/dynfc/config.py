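"""Validated pipeline configuration loaded from YAML.

Defaults mirror the analysis protocol the package implements: 20 group ICA
components with 10 ICASSO runs, sliding windows of width 50 TR and step
1 TR, a 0.01-0.08 Hz band-pass, and 10-fold stratified cross-validation.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pipeline import ExperimentConfig


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    data_dir: Optional[str] = None
    atlas: Optional[str] = None
    output: str = "dynfc_out"


class ICAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_components: int = 20
    icasso_runs: int = 10
    variance_threshold: float = Field(0.95, gt=0, le=1)
    subject_pca_max: int = 30
    keep_list: Optional[list] = None


class WindowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width: int = Field(50, ge=2)
    step: int = Field(1, ge=1)


class ClassifierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    type: str = "lstm"
    hidden_size: int = 30
    fc_size: int = 16
    learning_rate: float = 1e-3
    max_epochs: int = 200
    batch_size: int = 16
    patience: int = 20


class CVConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = Field(10, ge=2)
    seed: int = 0


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    paths: PathsConfig = PathsConfig()
    ica: ICAConfig = ICAConfig()
    windows: WindowConfig = WindowConfig()
    band: tuple = (0.01, 0.08)
    tr: float = 3.0
    postprocess: bool = False
    classifier: ClassifierConfig = ClassifierConfig()
    cv: CVConfig = CVConfig()
    level: str = "ica"
    mode: str = "dynamic"
    positive_class: Optional[str] = None

    @model_validator(mode="after")
    def _check_enums(self):
        if self.level not in ("ica", "roi", "timecourse"):
            raise ValueError(f"level must be ica/roi/timecourse, got {self.level}")
        if self.mode not in ("dynamic", "static"):
            raise ValueError(f"mode must be dynamic/static, got {self.mode}")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"invalid band {self.band}")
        return self

    def to_experiment_config(self):
        return ExperimentConfig(
            level=self.level, mode=self.mode,
            classifier=self.classifier.type,
            n_components=self.ica.n_components,
            variance_threshold=self.ica.variance_threshold,
            subject_pca_max=self.ica.subject_pca_max,
            icasso_runs=self.ica.icasso_runs,
            keep_list=self.ica.keep_list,
            width=self.windows.width, step=self.windows.step,
            band=tuple(self.band), tr=self.tr, postprocess=self.postprocess,
            k=self.cv.k, seed=self.cv.seed,
            positive_class=self.positive_class,
            hidden_size=self.classifier.hidden_size,
            fc_size=self.classifier.fc_size,
            learning_rate=self.classifier.learning_rate,
            max_epochs=self.classifier.max_epochs,
            batch_size=self.classifier.batch_size,
            patience=self.classifier.patience)


def parse_config(path):
    """Load and validate a YAML pipeline configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    return PipelineConfig(**raw)
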