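"""Loading and merging of model parameter files.

Parameters ship as a structured YAML file (see ``data/default_params.yaml``)
holding channel gating constants, Markov rate constants, transporter
kinetics, synapse densities and initial concentrations.  User files may
override any subset; mappings are merged recursively.
"""

from __future__ import annotations

import copy
from importlib import resources

import yaml


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_params() -> dict:
    """The packaged default parameter set as a nested dict."""
    text = resources.files("ionshift.data").joinpath("default_params.yaml").read_text()
    return yaml.safe_load(text)


def load_params(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally merged with a YAML file and/or a dict."""
    params = default_params()
    if path is not None:
        with open(path) as fh:
            params = _deep_merge(params, yaml.safe_load(fh) or {})
    if overrides:
        params = _deep_merge(params, overrides)
    return params


def save_params(params: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)
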