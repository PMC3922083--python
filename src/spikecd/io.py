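"""Flat key-value configuration handling.

The configuration file is TOML with one flat table per concern; defaults
are exactly the reference simulation constants (see ``params``).
"""

from __future__ import annotations

import tomllib

from .params import NeuronParams

DEFAULT_CONFIG = {
    "neuron": {
        "C": 1e-12, "g_L": 1e-9, "theta": 0.1, "u_rst": 0.0,
        "tau_r": 4e-3, "sigma": 3e-11,
    },
    "synapse": {"tau_syn": 4e-3, "nu_bias": 1000.0},
    "simulation": {"dt": 1e-4},
    "learning": {"T": 50e-3, "tau_br": 10e-3, "A": 0.02, "tau_stdp": 4e-3},
}


def load_config(path=None) -> dict:
    """Load a TOML config, filling unspecified keys with the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for section, table in user.items():
            if section not in cfg:
                raise KeyError(f"unknown config section '{section}'")
            for key, val in table.items():
                if key not in cfg[section]:
                    raise KeyError(f"unknown config key '{section}.{key}'")
                cfg[section][key] = float(val)
    return cfg


def neuron_from_config(cfg: dict) -> NeuronParams:
    return NeuronParams(**cfg["neuron"])


def dump_config(cfg: dict) -> str:
    """Render a config dict as TOML text."""
    lines = []
    for section, table in cfg.items():
        lines.append(f"[{section}]")
        for key, val in table.items():
            lines.append(f"{key} = {val!r}")
        lines.append("")
    return "\n".join(lines)
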