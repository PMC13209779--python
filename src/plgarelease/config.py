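"""Versioned default configuration (stage-1/stage-2 hyperparameters)."""

from __future__ import annotations

import copy
from importlib import resources

import yaml


def load_defaults() -> dict:
    """The packaged default configuration as a fresh, mutable dict."""
    text = resources.files("plgarelease").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS = load_defaults()


def default_hyperparams(algorithm: str) -> dict:
    """Default stage-2 hyperparameters for one algorithm name."""
    algos = _DEFAULTS["stage2"]["algorithms"]
    if algorithm not in algos:
        raise KeyError(algorithm)
    return copy.deepcopy(algos[algorithm]) or {}


def stage1_defaults() -> dict:
    return copy.deepcopy(_DEFAULTS["stage1"])


def stage2_defaults() -> dict:
    return copy.deepcopy(_DEFAULTS["stage2"])


def validation_defaults() -> dict:
    return copy.deepcopy(_DEFAULTS["validation"])
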