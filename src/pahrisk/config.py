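"""Run configuration: a single YAML file driving every pipeline stage.

Top-level sections (all optional; defaults are the study parameters):

``paths``      samples / participants / output locations
``tef``        TEF overrides, abbreviation -> float (complete table unless
               ``tef_merge_defaults`` is true)
``scenario``   per-season Monte Carlo parameter blocks
``thresholds`` acceptable_risk and diagnostic-ratio cutoffs
``seed``, ``iterations``, ``verbosity``

Unknown keys are rejected rather than ignored, and every successful CLI run
echoes the effective configuration into the output directory so a run can
be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .montecarlo import ParameterSpec, ScenarioSpec, heating_scenario, nonheating_scenario

__all__ = ["RunConfig", "ConfigError"]

_TOP_KEYS = {"paths", "tef", "tef_merge_defaults", "scenario", "thresholds",
             "seed", "iterations", "verbosity", "generator"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    paths: dict = field(default_factory=dict)
    tef: dict | None = None
    tef_merge_defaults: bool = False
    scenario_overrides: dict = field(default_factory=dict)
    acceptable_risk: float = 1e-6
    seed: int = 0
    iterations: int = 10_000
    verbosity: str = "info"
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw, source=str(path))

    @classmethod
    def from_mapping(cls, raw: dict, source: str = "<mapping>") -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"{source}: unknown config key(s): {sorted(unknown)}")
        thresholds = raw.get("thresholds", {})
        bad = set(thresholds) - {"acceptable_risk"}
        if bad:
            raise ConfigError(f"{source}: unknown thresholds key(s): {sorted(bad)}")
        return cls(
            paths=dict(raw.get("paths", {})),
            tef=dict(raw["tef"]) if "tef" in raw else None,
            tef_merge_defaults=bool(raw.get("tef_merge_defaults", False)),
            scenario_overrides=dict(raw.get("scenario", {})),
            acceptable_risk=float(thresholds.get("acceptable_risk", 1e-6)),
            seed=int(raw.get("seed", 0)),
            iterations=int(raw.get("iterations", 10_000)),
            verbosity=str(raw.get("verbosity", "info")),
            generator=dict(raw.get("generator", {})),
        )

    def registry_config(self) -> dict | None:
        return {"tef": self.tef} if self.tef is not None else None

    def scenario(self, season: str, seed: int | None = None) -> ScenarioSpec:
        """Build a season scenario, applying any config overrides."""
        factory = {"heating": heating_scenario,
                   "non-heating": nonheating_scenario}.get(season)
        if factory is None:
            raise ConfigError(f"unknown season {season!r}")
        spec = factory(seed=self.seed if seed is None else seed)
        spec = spec.with_seed(spec.seed if spec.seed is not None else 0)
        overrides = dict(self.scenario_overrides.get(season, {}))
        unknown = set(overrides) - {"bapeq", "ir", "bw", "ef", "ed", "at",
                                    "cf", "sf", "n_iterations"}
        if unknown:
            raise ConfigError(f"unknown scenario key(s) for {season}: {sorted(unknown)}")
        kwargs = {}
        for name in ("bapeq", "ir", "bw"):
            if name in overrides:
                block = overrides.pop(name)
                kwargs[name] = ParameterSpec(
                    kind=block["kind"], p1=float(block["p1"]),
                    p2=float(block.get("p2", 0.0)),
                    lower_bound=float(block.get("lower_bound", 0.0)),
                )
        kwargs.update({k: v for k, v in overrides.items()})
        kwargs["n_iterations"] = int(kwargs.get("n_iterations", self.iterations))
        from dataclasses import replace
        return replace(spec, **kwargs)

    def effective_mapping(self) -> dict:
        out: dict = {
            "seed": self.seed,
            "iterations": self.iterations,
            "verbosity": self.verbosity,
            "thresholds": {"acceptable_risk": self.acceptable_risk},
        }
        if self.paths:
            out["paths"] = dict(self.paths)
        if self.tef is not None:
            out["tef"] = dict(self.tef)
            out["tef_merge_defaults"] = self.tef_merge_defaults
        if self.scenario_overrides:
            out["scenario"] = dict(self.scenario_overrides)
        if self.generator:
            out["generator"] = dict(self.generator)
        return out

    def echo(self, directory) -> Path:
        """Write the effective config into ``directory`` for reproducibility."""
        path = Path(directory) / "effective_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.effective_mapping(), fh, sort_keys=True)
        return path
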