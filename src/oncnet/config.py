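"""Configuration objects for the simulation and analysis pipeline.

All study constants live here as named fields so that a deviation from the
default analysis is a visible diff in a config file: the 3-month lookback is
91 days, the 12-month follow-up is 365 days, the sharing threshold is 3
patients, the node floor is 5 patients, the linchpin cutoff is the top 15%,
and treatment delay means an interval greater than 60 days (90 in the
sensitivity analysis).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is structurally invalid."""


def _default_exclusion_fractions() -> dict[str, float]:
    # One planted violation class per cohort exclusion rule; disjoint by
    # construction so filter tallies can be compared against planted counts.
    return {
        "prior_cancer_dx": 0.01,
        "age_out_of_range": 0.01,
        "enrollment_gap": 0.01,
        "multiple_cancers": 0.01,
        "bad_zip": 0.01,
        "metastatic_90d": 0.01,
        "neoadjuvant": 0.01,
        "same_day_reconstruction": 0.01,
        "no_surgery": 0.02,
    }


@dataclass
class GeneratorConfig:
    """Settings for the synthetic claims generator.

    Defaults emulate the margins of a US fee-for-service Medicare
    breast-cancer cohort: women 66-99, ~20% rural residence, roughly one
    operating surgeon per ten patients, and an adjuvant-therapy rate of 52%.
    """

    n_patients: int = 2000
    patients_per_surgeon: float = 10.0
    patients_per_med_onc: float = 20.0
    patients_per_rad_onc: float = 30.0
    patients_per_other: float = 6.0
    n_hrrs: int = 8
    hsas_per_hrr: int = 3
    zips_per_hsa: int = 3
    rural_patient_fraction: float = 0.204
    rural_hsa_fraction: float = 0.34
    #: 0 disables rural surgeon scarcity; 1 removes nearly all rural surgeons.
    rural_scarcity: float = 0.7
    adjuvant_fraction: float = 0.522
    two_surgery_fraction: float = 0.15
    #: fraction of patients whose preoperative team is the surgeon alone
    pre_sole_fraction: float = 0.10
    exclusion_fractions: dict[str, float] = field(
        default_factory=_default_exclusion_fractions
    )

    def validate(self) -> None:
        for name in (
            "n_patients",
            "patients_per_surgeon",
            "patients_per_med_onc",
            "patients_per_rad_onc",
            "patients_per_other",
            "n_hrrs",
            "hsas_per_hrr",
            "zips_per_hsa",
        ):
            if getattr(self, name) <= 0 and not (name == "n_patients" and self.n_patients == 0):
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not 0.0 <= self.rural_patient_fraction <= 1.0:
            raise ConfigError("rural_patient_fraction must lie in [0, 1]")
        if not 0.0 <= self.rural_scarcity <= 1.0:
            raise ConfigError("rural_scarcity must lie in [0, 1]")
        total = sum(self.exclusion_fractions.values())
        if min(self.exclusion_fractions.values(), default=0.0) < 0 or total >= 1.0:
            raise ConfigError(
                "exclusion_fractions must be non-negative and sum to < 1, "
                f"got total {total:.3f}"
            )


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; every methods constant is a named key."""

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    days_before_biopsy: int = 91
    days_after_biopsy: int = 365
    min_shared_patients: int = 3
    min_patients_per_physician: int = 5
    linchpin_top_fraction: float = 0.15
    delay_cutoff_days: int = 60
    sensitivity_cutoff_days: int = 90
    glmm_backend: str = "laplace"
    output_dir: str = "oncnet_run"

    def validate(self) -> None:
        self.generator.validate()
        for name in (
            "days_before_biopsy",
            "days_after_biopsy",
            "min_shared_patients",
            "min_patients_per_physician",
            "delay_cutoff_days",
            "sensitivity_cutoff_days",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0.0 < self.linchpin_top_fraction < 1.0:
            raise ConfigError("linchpin_top_fraction must lie in (0, 1)")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        gen = data.pop("generator", {})
        known = {f.name for f in dataclasses.fields(GeneratorConfig)}
        unknown = set(gen) - known
        if unknown:
            raise ConfigError(f"unknown generator keys: {sorted(unknown)}")
        cfg = cls(generator=GeneratorConfig(**gen))
        known = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            setattr(cfg, key, value)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
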