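"""Analysis configuration: every tunable threshold in one place.

All distances are micrometres; all areas are square micrometres.  Defaults
follow the documented analysis conventions (see ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A threshold is outside its documented legal range."""


@dataclass
class AnalysisConfig:
    # -- steatosis detection -------------------------------------------------
    #: "otsu" picks the dark class of a bimodal TPEF histogram; "fixed"
    #: thresholds at dark_fixed_fraction * median(tissue).
    dark_threshold_mode: str = "otsu"
    dark_fixed_fraction: float = 0.35
    #: minimum vacuole candidate area after hole filling.
    min_vacuole_area_um2: float = 3.0
    #: bright pockets smaller than this are treated as holes and filled.
    fill_hole_max_um2: float = 0.8
    # -- vacuole classification ----------------------------------------------
    macro_min_diameter_um: float = 10.0
    micro_min_diameter_um: float = 2.0
    min_circularity: float = 0.4
    min_solidity: float = 0.7
    #: dilation radius defining the steatosis region (one hepatocyte radius).
    dilation_radius_um: float = 10.0
    # -- collagen segmentation / strings -------------------------------------
    min_collagen_area_um2: float = 2.0
    long_min_um: float = 40.0
    thin_max_um: float = 1.5
    agg_radius_um: float = 20.0
    agg_min_neighbors: int = 2
    # -- co-localization -----------------------------------------------------
    coloc_distance_um: float = 10.0
    #: "whole": a string counts if >= 50% of its pixels fall in the
    #: neighborhood; "clip": string pixels are clipped to the neighborhood.
    coloc_attribution: str = "whole"
    # -- feature selection ---------------------------------------------------
    top_k: int = 10
    top_k_step: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dark_threshold_mode not in ("otsu", "fixed"):
            raise ConfigError(f"dark_threshold_mode must be otsu|fixed, got {self.dark_threshold_mode!r}")
        if not 0 < self.dark_fixed_fraction < 1:
            raise ConfigError("dark_fixed_fraction must be in (0, 1)")
        positive = (
            "min_vacuole_area_um2", "macro_min_diameter_um", "micro_min_diameter_um",
            "min_collagen_area_um2", "long_min_um", "thin_max_um", "agg_radius_um",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("fill_hole_max_um2", "dilation_radius_um", "coloc_distance_um"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0 <= self.min_circularity <= 1.05:
            raise ConfigError("min_circularity must be in [0, 1.05]")
        if not 0 <= self.min_solidity <= 1:
            raise ConfigError("min_solidity must be in [0, 1]")
        if self.micro_min_diameter_um >= self.macro_min_diameter_um:
            raise ConfigError("micro_min_diameter_um must be below macro_min_diameter_um")
        if self.agg_min_neighbors < 1:
            raise ConfigError("agg_min_neighbors must be >= 1")
        if self.coloc_attribution not in ("whole", "clip"):
            raise ConfigError("coloc_attribution must be whole|clip")
        if self.top_k < 1 or self.top_k_step < 1:
            raise ConfigError("top_k and top_k_step must be >= 1")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
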