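"""YAML configuration for the colony growth/competition simulator.

A config file has up to three blocks, each overriding the shipped defaults::

    domain:
      R_max: 25.0
      n_r: 251
      D_N: 0.01
      N0: 1.0
    genotypes:
      - id: wt
        D_b: 0.01
        mu_max: 0.3
        sigma_max: 0.03
      - id: mutant
        sigma_max: 0.0
    protocol:
      cycle_hours: 168
      edge_width: 1.5
      n_cycles: 5

All default parameter values are choices of this package, not measurements.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Tuple

import yaml

from colonyevo.surface_model import Domain, GenotypeParams, PassageProtocol

__all__ = ["SimulationConfig", "load_config"]


@dataclasses.dataclass
class SimulationConfig:
    domain: Domain
    genotypes: List[GenotypeParams]
    protocol: PassageProtocol


def _build(cls, block: dict, **extra):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{**block, **extra})


def load_config(path) -> SimulationConfig:
    """Load a simulation config, filling unspecified values with defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    domain = _build(Domain, raw.get("domain", {}) or {})
    protocol = _build(PassageProtocol, raw.get("protocol", {}) or {})
    gts = raw.get("genotypes") or [{"id": "wt"}]
    genotypes = []
    for i, block in enumerate(gts):
        block = dict(block)
        block.setdefault("id", f"genotype{i}")
        genotypes.append(_build(GenotypeParams, block))
    return SimulationConfig(domain=domain, genotypes=genotypes, protocol=protocol)
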