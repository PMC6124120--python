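"""Run configuration: per-stage parameter blocks with replication defaults.

The defaults reproduce the study's parameter set: fourfold expression
threshold (log2 >= 2), strict E < 0.001 homology cut-off, two-tailed tests
and Bonferroni significance at alpha = 0.0025.  Unknown keys anywhere in a
config file are rejected rather than silently ignored.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

#: The replication parameter set.  ``replication_defaults()`` returns a
#: deep copy; every stage's block mirrors the corresponding module options.
_REPLICATION_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "segscan_run",
    "log_level": "INFO",
    "stages": ["simulate", "scan", "regions"],
    "simulate": {
        "n_chromosomes": 17,
        "markers_per_chromosome": 20,
        "chromosome_length_bp": 1_000_000,
        "chromosome_length_morgans": 1.0,
        "causal_loci": [],
        "phenotype_model": "ALL",
        "misclassification_rate": 0.05,
        "pool_depth": [155.0, 128.0],
        "seq_error_rate": 0.001,
        "n_f2": 2000,
        "n_f1": 200,
    },
    "scan": {
        "min_depth": 10,
        "sided": "two",
        "counts": None,  # path; defaults to the simulate stage's output
    },
    "regions": {
        "threshold": 2.0,
        "max_gap": 500_000,
    },
    "de": {
        "fpkm": None,
        "fold": 4.0,
        "pseudocount": 0.1,
        "mask": None,
        "qc_floor": 0.98,
    },
    "strata": {
        "hits": None,
        "taxa": None,
        "universe": None,
        "e_max": 0.001,
    },
    "enrich": {
        "set": None,
        "annot": None,
        "universe": None,
        "alpha": 0.0025,
        "method": "min-likelihood",
        "m": None,
    },
}


def replication_defaults() -> dict[str, Any]:
    """The full default configuration (study-replication settings)."""
    return copy.deepcopy(_REPLICATION_DEFAULTS)


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {where!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Replication defaults merged with a YAML file and/or a dict.

    Raises on unknown keys at any nesting level.
    """
    config = replication_defaults()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        config = _merge(config, data)
    if overrides:
        config = _merge(config, overrides)
    return config
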