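"""Run configuration: which designs, scenarios and settings to simulate.

A run is fully reproducible from its configuration plus seed.  Designs
are named by token: ``fixed`` for the 5+5+5+5 benchmark, ``adaptive:X``
for the adaptive design with TIL X (a probability, e.g. ``adaptive:0.05``).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .designs import DesignSpec
from .dose_model import ModelSpec

__all__ = ["RunConfig", "parse_design_token"]

DEFAULT_DESIGNS = ["fixed", "adaptive:0.05", "adaptive:0.10", "adaptive:0.20"]
DEFAULT_SCENARIOS = [f"scenario{i}" for i in range(1, 8)]


def parse_design_token(token: str, config: "RunConfig") -> DesignSpec:
    if token == "fixed":
        return DesignSpec.fixed()
    if token.startswith("adaptive:"):
        til = float(token.split(":", 1)[1])
        return DesignSpec.adaptive(
            til,
            decision_rule=config.decision_rule,
            period3_enabled=config.period3_enabled,
            selection_criteria=config.selection,
        )
    raise ValueError(f"unknown design token {token!r}")


@dataclass
class RunConfig:
    designs: list[str] = field(default_factory=lambda: list(DEFAULT_DESIGNS))
    scenarios: list[str] = field(default_factory=lambda: list(DEFAULT_SCENARIOS))
    n_realisations: int = 1000
    seed: int = 0
    prior_name: str = "uniform"
    prior_params: list[float] = field(default_factory=lambda: [0.0, 10.0])
    point_convention: str = "plugin_median"
    decision_rule: str = "closest"
    selection: str = "both"
    period3_enabled: bool = False
    out_dir: str = "results"
    make_plots: bool = True

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            prior_name=self.prior_name,
            prior_params=tuple(self.prior_params),
            point_convention=self.point_convention,
        )

    def design_specs(self) -> dict[str, DesignSpec]:
        return {token: parse_design_token(token, self) for token in self.designs}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
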