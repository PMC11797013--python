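"""Flat YAML run configuration.

A config file is a single flat mapping whose keys mirror the scenario
fields plus the batch settings of the Monte Carlo driver.  Unknown keys are
rejected so typos fail loudly.  Files round-trip byte-identically through
:func:`load_config` / :func:`save_config` (keys are written sorted).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .errors import ParameterError

__all__ = ["KNOWN_KEYS", "load_config", "save_config"]

#: every key a config file may contain
KNOWN_KEYS = frozenset(
    {
        # scenario parameters
        "conversion",
        "resistance_level",
        "resistance_frequency",
        "fitness_cost",
        "exposure",
        "dominance",
        "inbreeding",
        "population_size",
        "generations",
        "initial_drive_frequency",
        "timing",
        "mode",
        "seed",
        "drift_method",
        # batch settings
        "n_sims",
        "n_per_outcome",
        "chunk_size",
        "max_attempts",
        "gradient_method",
        # output paths
        "out",
        "summary_out",
        "table_out",
        "preset",
    }
)


def load_config(path: Union[str, Path]) -> dict:
    """Read and validate a flat YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} must contain a flat mapping")
    unknown = sorted(set(data) - KNOWN_KEYS)
    if unknown:
        raise ParameterError(f"unknown config keys in {path}: {unknown}")
    return data


def save_config(config: dict, path: Union[str, Path]) -> None:
    """Write a config mapping to YAML (sorted keys, stable layout)."""
    unknown = sorted(set(config) - KNOWN_KEYS)
    if unknown:
        raise ParameterError(f"refusing to write unknown config keys: {unknown}")
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True, default_flow_style=False)
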