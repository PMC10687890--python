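"""Run configuration: YAML-backed parameters with the method defaults.

Defaults follow the workflow constants: 5-min interpolation, 10-m contact
buffer, 1:30 used:available ratio, 95%/50% isopleths, |r| >= 0.6
collinearity screen, 0.5 core-overlap threshold, >10-contact pair filter,
fivefold cross-validation with 10 score bins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from contactrsf.errors import InvalidArgumentError

DEFAULT_CANDIDATE_FORMULAS = [
    ["wetland", "water", "road", "food", "ndvi", "tree_canopy"],
    ["wetland", "water", "food", "ndvi"],
    ["wetland", "water", "food"],
    ["food", "ndvi"],
]


@dataclass
class SimulateConfig:
    """Synthetic-population parameters (used when no tracks are supplied)."""

    extent_m: float = 3000.0
    cell_size_m: float = 30.0
    n_days: int = 4
    n_food_sites: int = 25
    n_groups: int = 2
    animals_per_group: int = 2
    tau_p_min: float = 60.0
    sigma_m2: float = 90000.0
    fix_interval_min: float = 10.0
    gps_error_sd: float = 0.0
    meetings_per_day: float = 6.0
    attraction_coeffs: dict = field(default_factory=lambda: {"food": 1.0986122886681098})
    site_mode: str = "candidates"


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    out_dir: str = "out"
    tracks_csv: str | None = None  # external input; None -> simulate
    env_manifest: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    interval_min: float = 5.0
    buffer_m: float = 10.0
    ratio: int = 30
    isopleths: tuple[float, float] = (0.95, 0.50)
    collinearity_threshold: float = 0.6
    overlap_threshold: float = 0.5
    min_contacts: int = 10
    min_consecutive_weeks: int = 12
    cv_folds: int = 5
    cv_bins: int = 10
    candidate_formulas: list = field(default_factory=lambda: [list(f) for f in DEFAULT_CANDIDATE_FORMULAS])
    weights_mode: str = "murtaugh_product"  # or "sum", "inverse_variance"
    compare_date: str | None = None
    sexes: dict = field(default_factory=dict)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def validate(self) -> None:
        if self.interval_min <= 0:
            raise InvalidArgumentError("interval_min must be positive")
        if self.buffer_m <= 0:
            raise InvalidArgumentError("buffer_m must be positive")
        if self.ratio < 1:
            raise InvalidArgumentError("ratio must be >= 1")
        for level in self.isopleths:
            if not 0 < level < 1:
                raise InvalidArgumentError("isopleth levels must lie in (0, 1)")
        if not 0 < self.collinearity_threshold <= 1:
            raise InvalidArgumentError("collinearity_threshold must lie in (0, 1]")
        if not 0 <= self.overlap_threshold <= 1:
            raise InvalidArgumentError("overlap_threshold must lie in [0, 1]")
        if self.min_contacts < 0:
            raise InvalidArgumentError("min_contacts must be >= 0")
        if self.cv_folds < 2 or self.cv_bins < 2:
            raise InvalidArgumentError("cv_folds and cv_bins must be >= 2")
        if not self.candidate_formulas:
            raise InvalidArgumentError("need at least one candidate formula")
        if self.weights_mode not in ("murtaugh_product", "sum", "inverse_variance"):
            raise InvalidArgumentError(f"unknown weights_mode {self.weights_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["isopleths"] = list(self.isopleths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulate" in d and isinstance(d["simulate"], dict):
            d["simulate"] = SimulateConfig(**d["simulate"])
        if "isopleths" in d:
            d["isopleths"] = tuple(d["isopleths"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
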