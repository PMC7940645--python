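"""Serialisable run configuration for the CLI workflow.

A run is fully determined by its config (including the seed): rerunning
``simulate -> analyze -> compare`` from a saved config reproduces every
output byte.  Precedence is flags > config file > defaults, resolved by
the CLI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import SyntheticSpec, default_spec

__all__ = ["RunConfig", "DEFAULT_LAMBDAS"]

#: default filtration snapshot values
DEFAULT_LAMBDAS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class RunConfig:
    #: synthetic cohort spec as a dict (None when analysing real tables)
    synthetic: dict | None = None
    #: group label -> subject-table path (real-data mode)
    group_tables: dict[str, str] | None = None
    #: pathway config YAML; None = synthetic layout when simulating,
    #: shipped atlas otherwise
    pathway_config: str | None = None
    edge_threshold: float = 0.5
    retain_rule: str = "threshold"
    density: float | None = None
    snapshot_lambdas: tuple[float, ...] = DEFAULT_LAMBDAS
    statistics: tuple[str, ...] = ("sip_auc", "cpl", "nd", "ec_mean")
    n_permutations: int = 10_000
    alpha: float = 0.001
    seed: int = 0
    out_dir: str = "phnet_out"

    def __post_init__(self) -> None:
        self.snapshot_lambdas = tuple(float(x) for x in self.snapshot_lambdas)
        self.statistics = tuple(self.statistics)
        if self.synthetic is None and self.group_tables is None:
            self.synthetic = default_spec(seed=self.seed).to_dict()

    @property
    def synthetic_spec(self) -> SyntheticSpec | None:
        if self.synthetic is None:
            return None
        return SyntheticSpec.from_dict(self.synthetic)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: expected a mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = self.to_dict()
        # YAML-friendly containers
        doc["snapshot_lambdas"] = list(doc["snapshot_lambdas"])
        doc["statistics"] = list(doc["statistics"])
        if doc["synthetic"] is not None:
            doc["synthetic"]["group_names"] = list(doc["synthetic"]["group_names"])
            doc["synthetic"]["group_sizes"] = list(doc["synthetic"]["group_sizes"])
            doc["synthetic"]["within_strength"] = list(doc["synthetic"]["within_strength"])
            doc["synthetic"]["pathway_layout"] = [
                list(pair) for pair in doc["synthetic"]["pathway_layout"]
            ]
        path.write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")
        return path
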