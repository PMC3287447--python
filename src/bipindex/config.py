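"""Pipeline configuration: thresholds, dimension weights and optimizer settings.

Defaults follow the published methodology: Spearman screening cut at
|rho| >= 0.5, collinearity flagged at VIF > 4, dimension importance weights
e = (DAT 0.1, GRF 0.2, HOST 0.4, SPCS 0.3), and a 75% reliability (RRS)
threshold for a country to be eligible for ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

#: The nine thematic predictor groups ("drivers").
DRIVERS = ("GEO", "POP", "BIO", "ENV", "ICT", "DVE", "DVH", "PWR", "PWF")

#: The four response axes ("dimensions") of the composite index.
DIMENSIONS = ("DAT", "GRF", "HOST", "SPCS")

#: Variable categories.
CATEGORIES = ("human", "environmental", "intrinsic")

#: Category each driver belongs to.
DRIVER_CATEGORY = {
    "DVH": "human", "DVE": "human", "ICT": "human", "PWR": "human", "PWF": "human",
    "BIO": "environmental", "ENV": "environmental",
    "GEO": "intrinsic", "POP": "intrinsic",
}


@dataclass
class McParams:
    """Random-walk hill-climb settings for driver-weight optimization.

    One weight is perturbed per iteration by a Gaussian step with standard
    deviation ``step_scale * (weight + step_floor)``; proposals are clamped
    at zero. The walk stops after ``patience`` consecutive non-improving
    proposals or ``max_iterations`` total proposals.
    """

    step_scale: float = 0.05
    step_floor: float = 0.1
    patience: int = 500
    max_iterations: int = 50_000

    def validate(self) -> None:
        if self.step_scale <= 0:
            raise ValueError("mc.step_scale must be > 0")
        if self.patience < 1 or self.max_iterations < 1:
            raise ValueError("mc.patience and mc.max_iterations must be >= 1")


@dataclass
class BipConfig:
    """All tunable thresholds of the index-construction pipeline."""

    #: Expert-judgment importance weight of each dimension in the final score.
    e_weights: dict[str, float] = field(
        default_factory=lambda: {"DAT": 0.1, "GRF": 0.2, "HOST": 0.4, "SPCS": 0.3}
    )
    #: Two-sided significance level for the screening correlations.
    alpha: float = 0.05
    #: Minimum Spearman coefficient for a predictor to survive screening.
    rho_min: float = 0.5
    #: "absolute" applies rho_min to |rho|; "signed" to rho itself.
    rho_mode: str = "absolute"
    #: Minimum complete (predictor, response) pairs for a screen to be evaluated.
    min_pairs: int = 10
    #: Stepwise entry / removal significance levels.
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    #: Variance inflation factor above which terms are sent to PCA substitution.
    vif_max: float = 4.0
    #: |pairwise r| linking high-VIF terms into one collinear set.
    collinear_r: float = 0.7
    #: Reliability-score threshold (percent) for ranking eligibility.
    rrs_min: float = 75.0
    #: Monte-Carlo optimizer settings.
    mc: McParams = field(default_factory=McParams)
    #: Accepted calendar-year span for ingested records.
    year_min: int = 1990
    year_max: int = 2009
    #: Tokens treated as missing values on ingestion (empty string always is).
    missing_sentinels: tuple[str, ...] = ("NA", "NaN", "..", "-")

    def validate(self) -> None:
        if not self.e_weights or any(v < 0 for v in self.e_weights.values()):
            raise ValueError("e_weights must be nonnegative")
        if all(v == 0 for v in self.e_weights.values()):
            raise ValueError("at least one e_weight must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rho_mode not in ("absolute", "signed"):
            raise ValueError("rho_mode must be 'absolute' or 'signed'")
        if self.vif_max <= 1:
            raise ValueError("vif_max must exceed 1")
        if not 0 <= self.rrs_min <= 100:
            raise ValueError("rrs_min is a percentage")
        self.mc.validate()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "BipConfig":
        data = dict(data)
        if "mc" in data and isinstance(data["mc"], Mapping):
            data["mc"] = McParams(**data["mc"])
        if "missing_sentinels" in data:
            data["missing_sentinels"] = tuple(data["missing_sentinels"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BipConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
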