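"""YAML configuration for the classifier stack.

A config file has up to three blocks, all optional (missing keys take the
package defaults)::

    architecture:
      n_feature_groups: 2
      nodes_per_group: 5
      n_enhancement: 20
      feature_activation: tanh
      enhancement_activation: sigmoid
    graph:
      k1: 5
      k2: 5
      zeta: 1.0e-5
      lambda1: 1.0e-4
      lambda2: 0.1
    sae:
      population_size: 20
      learning_period: 5
      max_generations: 50
      rmse_threshold: 0.0
      epsilon_success: 0.01
      epsilon_select: 0.001
      bounds: [-1.0, 1.0]
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .bls import BLSArchitecture
from .errors import ParameterError
from .graphs import NeighborGraphSpec
from .sae import SaEConfig


def _build(cls, block: dict | None):
    block = dict(block or {})
    valid = {f.name for f in fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ParameterError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; valid: {sorted(valid)}"
        )
    if "bounds" in block:
        block["bounds"] = tuple(block["bounds"])
    return cls(**block)


def load_config(
    path: str | Path | None,
) -> tuple[BLSArchitecture, NeighborGraphSpec, SaEConfig]:
    """Parse a YAML config into the three configuration dataclasses."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    arch = _build(BLSArchitecture, raw.get("architecture"))
    graph = _build(NeighborGraphSpec, raw.get("graph"))
    sae = _build(SaEConfig, raw.get("sae"))
    return arch, graph, sae
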