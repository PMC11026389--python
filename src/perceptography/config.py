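"""Campaign configuration: the procedural constants of the closed loop.

Defaults encode the original closed-loop procedure at desk scale: 5 image seeds with a
pool of ~100 random perturbations each (full-scale pools are 400-1000 and
remain reachable), at least 5 presentations per image per stimulation
condition, image-selection thresholds of FA > 50% with Miss < 5%, family
survival above a 50% cumulative FA rate, a stopping rule of >= 60% FA over at
least 12 non-stimulated presentations, 2-6 mutated children per surviving
image, and 50-80% dilution with non-optimized images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ValidationError

__all__ = ["CampaignConfig", "load_config"]


@dataclass
class CampaignConfig:
    master_seed: int = 0
    n_seeds: int = 5
    pool_size: int = 100
    min_presentations: int = 5
    iteration_budget: int = 5
    dilution_fraction: float = 0.5
    fa_select: float = 0.5
    miss_select: float = 0.05
    family_survival: float = 0.5
    stop_fa: float = 0.6
    stop_min_presentations: int = 12
    children_per_parent: int = 4
    intensity_mw: float = 3.0
    # image space
    image_size: int = 64
    n_classes: int = 16
    latent_dim: int = 12
    truncation: float = 2.0
    # optimizer internals
    mutation_spread: float = 0.35
    spray_multiplier: int = 10
    max_families: int = 12
    # observer overrides (field name -> value of ObserverConfig), and site shape
    observer: dict = field(default_factory=dict)
    site_seed: int | None = None

    def validate(self) -> None:
        problems: list[str] = []
        if self.master_seed < 0:
            problems.append("master_seed: must be non-negative")
        for name in ("n_seeds", "pool_size", "min_presentations"):
            if getattr(self, name) < 1:
                problems.append(f"{name}: must be >= 1")
        if self.iteration_budget < 0:
            problems.append("iteration_budget: must be >= 0")
        for name in ("fa_select", "miss_select", "family_survival", "stop_fa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}: {v} outside [0, 1]")
        if self.stop_min_presentations < 1:
            problems.append("stop_min_presentations: must be >= 1")
        if not 2 <= self.children_per_parent <= 6:
            problems.append(
                f"children_per_parent: {self.children_per_parent} outside the "
                "fixed family range [2, 6]"
            )
        if self.dilution_fraction != 0.0 and not 0.5 <= self.dilution_fraction <= 0.8:
            problems.append(
                f"dilution_fraction: {self.dilution_fraction} outside the "
                "documented dilution range [0.5, 0.8] (use 0 to disable dilution)"
            )
        if self.intensity_mw <= 0:
            problems.append("intensity_mw: must be positive")
        if self.mutation_spread <= 0:
            problems.append("mutation_spread: must be positive")
        if self.spray_multiplier < 1:
            problems.append("spray_multiplier: must be >= 1")
        if self.max_families < 1:
            problems.append("max_families: must be >= 1")
        if not isinstance(self.observer, dict):
            problems.append("observer: must be a mapping of override fields")
        if problems:
            raise ValidationError("; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(
                "unknown configuration keys: " + ", ".join(sorted(unknown))
            )
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path) -> CampaignConfig:
    """Load and fully validate a YAML campaign config.

    Unknown keys are rejected; an empty file yields all documented defaults;
    every invariant violation is listed in the error message.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a YAML mapping")
    return CampaignConfig.from_dict(data)
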