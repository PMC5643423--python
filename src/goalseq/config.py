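"""Run configuration, deterministic seeding and file round-tripping.

A run is described by a flat, human-editable YAML mapping. Network
parameters are overridden with dotted keys relative to the defaults, e.g.
``ca3_rec.weight_max: 0.02`` or ``dg.V_theta: -50.4``. Every stochastic
component derives its generator from the master seed and a component name,
so that runs are reproducible end-to-end and components can be re-executed
in isolation.
"""
from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .network import NetworkParams
from .params import LatticeSpec, NeuronParams, PlaceFieldSpec, SynapseSpec

__all__ = ["RunConfig", "component_rng", "network_params"]

#: lattice side used by the "reduced" scale (full = 80)
REDUCED_GRID_SIDE = 40


def component_rng(master_seed: int, name: str) -> np.random.Generator:
    """Generator for one named component, derived from the master seed."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(key,)))


@dataclass
class RunConfig:
    """Everything needed to reproduce a behavioral simulation or sweep."""

    seed: int = 0
    scale: str = "reduced"              # "full" | "reduced"
    n_networks: int = 10
    n_pairs: int = 8                    # Home/Away pairs per network
    home_wells: Optional[list] = None   # default: counterbalanced cycling
    search_mode: str = "uniform"        # random-search ordering
    output_dir: str = "runs"
    network: dict = field(default_factory=dict)  # dotted-key overrides
    # sweep settings
    sweep_factors: tuple = (0.5, 0.75, 1.0)
    sweep_events: int = 50
    sweep_weight_scaling: str = "area"
    decode_subsets: int = 4
    decode_subset_size: int = 160
    decode_bin: float = 5.25

    def grid_side(self) -> int:
        if self.scale == "full":
            return 80
        if self.scale == "reduced":
            return REDUCED_GRID_SIDE
        raise ValueError(f"unknown scale {self.scale!r}")

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sweep_factors"] = list(self.sweep_factors)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "sweep_factors" in d:
            d["sweep_factors"] = tuple(d["sweep_factors"])
        return cls(**d)


def _apply_override(params: NetworkParams, key: str, value) -> NetworkParams:
    parts = key.split(".")
    if len(parts) == 1:
        return replace(params, **{key: value})
    if len(parts) == 2:
        head, leaf = parts
        sub = getattr(params, head)
        if not isinstance(sub, (SynapseSpec, NeuronParams, LatticeSpec,
                                PlaceFieldSpec)):
            raise ValueError(f"{head!r} is not an overridable group")
        return replace(params, **{head: replace(sub, **{leaf: value})})
    raise ValueError(f"bad override key {key!r}")


def network_params(config: RunConfig) -> NetworkParams:
    """NetworkParams for the configured scale with overrides applied."""
    params = NetworkParams(lattice=LatticeSpec(grid_side=config.grid_side()))
    for key, value in config.network.items():
        params = _apply_override(params, key, value)
    return params
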