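"""Run configuration: defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .survstats import ALPHA
from .screen import DEFAULT_FRACTIONS
from .trialsim import BiomarkerEffect, SimConfig

__all__ = ["RunConfig", "load_run_config", "sim_config_from_dict"]


@dataclass
class CohortSpec:
    n_treated: int
    n_control: int = 0


@dataclass
class RunConfig:
    """Pipeline-wide knobs; see docs/methods.md for units and rationale."""

    seed: int = 0
    significance: float = ALPHA
    fractions: tuple = DEFAULT_FRACTIONS
    share: float = 0.8                 # share of significant fractions to retain
    min_events: int = 10
    fraction_range: tuple = (0.25, 0.50)
    combination_rule: str = "any_high"
    count_threshold: int | None = None
    horizon: float = 12.0              # AUC horizon, months
    landmark: bool = True
    max_biomarkers: int = 3            # score size cap after the cascade
    biomarkers: list | None = None     # None -> the default screened universe
    time_unit: str = "months"          # "days" accepted and converted
    cohorts: dict = field(default_factory=lambda: {
        "training": CohortSpec(600, 400),
        "validation1": CohortSpec(400, 0),
        "validation2": CohortSpec(300, 200),
    })
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance threshold must be in (0, 1)")
        if any(not 0.0 < f < 1.0 for f in self.fractions):
            raise ValueError("fractions must be in (0, 1)")
        if not 0.0 < self.share <= 1.0:
            raise ValueError("share must be in (0, 1]")
        if not 0.0 < self.fraction_range[0] < self.fraction_range[1] < 1.0:
            raise ValueError("fraction_range must be an increasing pair in (0, 1)")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")
        if self.time_unit not in ("months", "days"):
            raise ValueError("time_unit must be 'months' or 'days'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohorts"] = {k: asdict(v) if isinstance(v, CohortSpec) else v
                        for k, v in self.cohorts.items()}
        return d


def sim_config_from_dict(d: dict, **overrides) -> SimConfig:
    """Build a SimConfig from a plain mapping (e.g. parsed YAML)."""
    d = dict(d)
    for key in ("prognostic_effects", "predictive_effects"):
        effs = []
        for e in d.get(key, []):
            effs.append(e if isinstance(e, BiomarkerEffect) else BiomarkerEffect(**e))
        d[key] = effs
    d.update(overrides)
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg


def load_run_config(path) -> RunConfig:
    """Read a YAML key-value run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohorts = {
        name: CohortSpec(**spec) for name, spec in raw.pop("cohorts", {}).items()
    }
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "cohorts"})
    if cohorts:
        cfg.cohorts = cohorts
    if isinstance(cfg.fractions, list):
        cfg.fractions = tuple(cfg.fractions)
    if isinstance(cfg.fraction_range, list):
        cfg.fraction_range = tuple(cfg.fraction_range)
    cfg.validate()
    return cfg
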