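"""Pipeline configuration.

Every numeric screening threshold used anywhere in the pipeline lives in
:class:`PipelineConfig`, so a run is fully described by one config object
plus a seed.  Defaults are the assay's standard operating values: compounds
pass at oral bioavailability >= 30% and drug-likeness >= 0.18, target
predictions at probability > 0.1, the key-target screen uses twice the
median degree, metabolite calls require p < 0.05 and VIP > 1, QC features
are dropped above 30% RSD, and the dose series is a four-level 1:0.5
dilution anchored to a 1000 U/ug reference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """All tunable thresholds and design constants of the pipeline."""

    # network-pharmacology screens
    ob_min: float = 30.0            # oral bioavailability, percent, inclusive
    dl_min: float = 0.18            # drug-likeness, inclusive
    prob_min: float = 0.1           # target-prediction probability, strict >
    degree_median_multiplier: float = 2.0

    # metabolomics screens
    p_threshold: float = 0.05       # strict <
    vip_threshold: float = 1.0      # strict >
    qc_rsd_max: float = 30.0        # percent, strict >
    loess_span: float = 0.75
    n_orthogonal: int = 1
    n_permutations: int = 200
    cv_folds: int = 7
    log_transform_ttest: bool = True

    # enrichment
    enrich_p_max: float = 0.05      # on BH-adjusted p

    # biopotency
    dilution_ratio: float = 0.5
    n_dilutions: int = 4
    reference_potency: float = 1000.0   # U/ug for the safflower S1 reference
    reference_potency_units: str = "U/ug"
    confidence_level: float = 0.95

    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "ob_min": self.ob_min,
            "dl_min": self.dl_min,
            "prob_min": self.prob_min,
            "degree_median_multiplier": self.degree_median_multiplier,
            "vip_threshold": self.vip_threshold,
            "qc_rsd_max": self.qc_rsd_max,
            "loess_span": self.loess_span,
            "reference_potency": self.reference_potency,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValidationError(f"{name} must be strictly positive, got {value}")
        for name, value in (
            ("p_threshold", self.p_threshold),
            ("confidence_level", self.confidence_level),
        ):
            if not 0 < value < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {value}")
        if not 0 < self.dilution_ratio < 1:
            raise ValidationError(
                f"dilution_ratio must lie in (0, 1), got {self.dilution_ratio}"
            )
        if self.n_dilutions < 3:
            raise ValidationError(
                f"a probit line needs >= 3 doses, got n_dilutions={self.n_dilutions}"
            )
        for name, value in (
            ("n_orthogonal", self.n_orthogonal),
            ("n_permutations", self.n_permutations),
            ("cv_folds", self.cv_folds),
        ):
            if value < 1:
                raise ValidationError(f"{name} must be >= 1, got {value}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _replace(config: PipelineConfig, **kwargs: Any) -> PipelineConfig:
    return dataclasses.replace(config, **kwargs)
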