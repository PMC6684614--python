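"""Run configuration: a single hierarchical YAML file, overridable per-flag.

A run writes the resolved configuration it actually used back into its
output directory, so every result can be regenerated from that snapshot
plus the seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .pre import K_PRINTED, PREPhysics


@dataclasses.dataclass
class SANSDatasetConfig:
    name: str
    path: str
    f_d2o: float
    deuteration: dict[str, float]


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out: str = "presans_out"
    # structures
    complex_path: str = "complex.pdb"
    manifest_path: str = "manifest.csv"
    deuteration: dict[str, float] = dataclasses.field(default_factory=dict)
    # physics
    tau_hmqc_s: float = 7.7e-3
    tau_c_ns: float = 81.0
    field_mhz: float = 850.0
    k_const: float = K_PRINTED
    # PRE inputs
    peaks_path: str = "pre_peaks.csv"
    relaxation_path: str = "relaxation.csv"
    tag_chain: str = "A"
    tag_resid: int = 15
    tag_cloud_points: int = 1
    restraints_path: str = "restraints.txt"
    # SANS
    q_units: str = "A"
    sans_datasets: list[SANSDatasetConfig] = dataclasses.field(default_factory=list)
    exchange_efficiency: float = 0.9
    # selection
    cluster_cutoff: float = 5.0
    cluster_mode: str = "reference"
    reference_chains: list[str] = dataclasses.field(default_factory=list)
    mobile_chains: list[str] = dataclasses.field(default_factory=list)
    # base directory the relative paths resolve against
    base_dir: str = "."

    def physics(self) -> PREPhysics:
        return PREPhysics(
            tau_hmqc=self.tau_hmqc_s,
            tau_c=self.tau_c_ns * 1e-9,
            omega=2.0 * np.pi * self.field_mhz * 1e6,
            K=self.k_const,
        )

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sans_datasets"] = [dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s
                              for s in self.sans_datasets]
        return d

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.setdefault("base_dir", str(path.parent))
        cfg = cls.from_dict(raw)
        for key, value in overrides.items():
            if value is not None:
                if not hasattr(cfg, key):
                    raise ValueError(f"unknown configuration key {key!r}")
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        datasets = [
            SANSDatasetConfig(**d) if isinstance(d, dict) else d
            for d in raw.get("sans_datasets", [])
        ]
        raw = dict(raw)
        raw["sans_datasets"] = datasets
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
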