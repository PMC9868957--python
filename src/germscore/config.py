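"""YAML run configuration with schema validation.

A flat namespace per stage; every robustness toggle of the analysis is
exposed here (age numeric vs. categorical, TSM as total count vs. equal-
weight mean rate, all vs. protein-changing mutations, optional driver
covariate).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_genes: int = 2_000
    n_terms: int = 80
    dag_branching: int = 2
    neoplasm_subtree_fraction: float = 0.15
    or_tsm_per_sd: float = 1.9
    age_effect_per_level: float = 0.1
    intercept: float = -1.4
    n_tumor_types: int = 33
    tsm_mean_per_tumor: float = 0.3
    tsm_dispersion: float = 0.5
    n_patients_per_tumor: int = 300
    feature_correlation: float = 0.3
    length_coupling: float = 0.2
    max_annotations_per_gene: int = 5
    neoplasm_annotation_fraction: float = 0.1
    n_diseases: int = 200
    phenotypes_per_disease: int = 5
    causal_gene_sharpness: float = 3.0


class FeaturesConfig(_Strict):
    mutation_mode: str = "all"          # all | protein_changing
    tsm_variant: str = "total"          # total | mean_rate


class TrainConfig(_Strict):
    min_genes: int = 100
    paradigm: str = "random_forest"
    grid: dict[str, list] | None = None
    outer_folds: int = 10
    inner_folds: int = 3
    age_categorical: bool = False
    driver_covariate: bool = False


class ScoreConfig(_Strict):
    n_randomizations: int = 100
    n_bins: int = 20
    alpha: float = 0.01
    low_score_threshold: float = 0.15


class RunConfig(_Strict):
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    features: FeaturesConfig = FeaturesConfig()
    train: TrainConfig = TrainConfig()
    score: ScoreConfig = ScoreConfig()


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
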