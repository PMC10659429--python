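"""Run configuration: one YAML/JSON schema binding all pipeline stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .federation import FederationConfig
from .learners import LearnerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Declarative definition of a full experiment run.

    The federated grid is the cross product of ``learners`` x
    ``mu_grid`` x ``n_clients_grid`` (mu > 0 entries pair only with
    gradient learners).
    """

    seed: int = 0
    output_dir: str = "results"
    internal_cohort: dict = field(default_factory=lambda: {"n_cases": 171, "n_controls": 427})
    external_cohort: dict | None = field(
        default_factory=lambda: {
            "n_cases": 404,
            "n_controls": 712,
            "shift_effect_scale": 0.7,
            "shift_mean": 0.25,
        }
    )
    K: int = 6
    rounds: int = 5
    train_ratio: float = 0.8
    learners: list[str] = field(default_factory=lambda: ["logreg"])
    learner_overrides: dict = field(default_factory=dict)
    mu_grid: list[float] = field(default_factory=lambda: [0.0])
    n_clients_grid: list[int] = field(default_factory=lambda: [2])
    strategies: list[str] = field(default_factory=lambda: ["uniform_stratified"])
    preprocessing: dict = field(default_factory=dict)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def internal_spec(self) -> CohortSpec:
        return CohortSpec(**{"seed": self.seed, **self.internal_cohort})

    def external_spec(self) -> CohortSpec | None:
        if self.external_cohort is None:
            return None
        return CohortSpec(**{"seed": self.seed + 1, **self.external_cohort})

    def learner_config(self, kind: str) -> LearnerConfig:
        return LearnerConfig(
            kind=kind, seed=self.seed, **self.learner_overrides.get(kind, {})
        )

    def federation_grid(self) -> dict[str, FederationConfig]:
        grid: dict[str, FederationConfig] = {}
        for kind in self.learners:
            for mu in self.mu_grid:
                if mu > 0 and kind == "tree_ensemble":
                    continue  # fedprox undefined for trees
                for n in self.n_clients_grid:
                    strat = "fedprox" if mu > 0 else "fedavg"
                    name = f"{strat}_{kind}" + (f"_mu{mu:g}" if mu > 0 else "")
                    if len(self.n_clients_grid) > 1:
                        name += f"_n{n}"
                    grid[name] = FederationConfig(
                        n_clients=n,
                        strategy=strat,
                        mu=mu,
                        rounds=self.rounds,
                        learner=self.learner_config(kind),
                        seed=self.seed,
                    )
        if not grid:
            raise ValueError("empty federation grid")
        return grid

    # -- provenance --------------------------------------------------------
    def as_dict(self) -> dict:
        return {
            name: getattr(self, name) for name in self.__dataclass_fields__
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def write_manifest(self, path) -> None:
        manifest = {
            "config": self.as_dict(),
            "config_hash": self.config_hash(),
            "master_seed": self.seed,
        }
        Path(path).write_text(json.dumps(manifest, indent=2, default=str))
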