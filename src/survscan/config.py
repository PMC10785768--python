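"""Run configuration: a strict, typed YAML schema for the full pipeline."""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["SimBlock", "ModelSpec", "RunConfig", "validate_config"]


class SimBlock(BaseModel):
    """Simulation parameters (mirrors :class:`survscan.simulate.SimConfig`)."""

    model_config = ConfigDict(extra="forbid")

    n_per_cohort: dict = Field(default={"Black/AA": 61, "White": 272})
    n_genes: int = 1000
    effect_table: dict = Field(default_factory=dict)
    baseline_hazard: float = 0.01
    censor_rate: float = 0.03
    admin_cutoff: float = 120.0
    nb_mean_range: tuple = (20.0, 2000.0)
    nb_dispersion: float = 0.4
    libsize_sigma: float = 0.25
    de_table: dict = Field(default_factory=dict)


class ModelSpec(BaseModel):
    """One multivariable Cox model: term lists as in models.DesignSpec."""

    model_config = ConfigDict(extra="forbid")

    name: str
    continuous: list = Field(default_factory=list)
    categorical: dict = Field(default_factory=dict)
    interactions: list = Field(default_factory=list)
    cohort: Optional[str] = None   # restrict to one cohort (stratified fit)


class RunConfig(BaseModel):
    """Everything the end-to-end run needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # exactly one of: input paths | simulation block
    clinical_path: Optional[str] = None
    expression_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    weights_path: Optional[str] = None
    simulation: Optional[SimBlock] = None

    endpoint_col: str = "os_months"
    event_col: str = "event"
    cohort_col: str = "cohort"
    cohort_labels: Optional[tuple] = None

    scan_bounds: tuple = (0.10, 0.90)
    alpha: float = 0.05
    fdr_method: str = "smoother"
    ties: str = "breslow"
    de_lfc_thresh: float = 0.1
    de_p_thresh: float = 0.05
    top_k: int = 100
    model_gene: Optional[str] = None
    models: list = Field(default_factory=list)

    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self):
        has_paths = self.clinical_path is not None or self.expression_path is not None
        if has_paths and self.simulation is not None:
            raise ValueError("provide input paths or a simulation block, not both")
        if not has_paths and self.simulation is None:
            raise ValueError("one of input paths or a simulation block is required")
        if has_paths and (self.clinical_path is None or self.expression_path is None):
            raise ValueError("both clinical_path and expression_path are required")
        if has_paths and self.cohort_labels is None:
            raise ValueError("cohort_labels are required with external input paths")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        lo, hi = self.scan_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("scan_bounds must satisfy 0 < low < high < 1")
        if self.fdr_method not in ("smoother", "fixed"):
            raise ValueError("fdr_method must be 'smoother' or 'fixed'")
        if self.ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        if self.cohort_labels is not None:
            if len(self.cohort_labels) != 2 or self.cohort_labels[0] == self.cohort_labels[1]:
                raise ValueError("cohort_labels must be two distinct labels")
        if min(self.de_lfc_thresh, self.de_p_thresh) < 0:
            raise ValueError("DE thresholds must be non-negative")
        return self


def validate_config(path) -> RunConfig:
    """Parse + validate a YAML run configuration.

    Raises :class:`pydantic.ValidationError` carrying every failure at once.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
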