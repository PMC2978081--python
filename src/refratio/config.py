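"""Run configuration: TOML file with sections
[sequence], [local_model], [target], [mcmc], [reference], [iterate],
[hbond], [geometry], [toy]; any omitted key takes the documented default.
Command-line flags override file values.
"""

from __future__ import annotations

import copy
import tomllib

DEFAULTS: dict = {
    "sequence": {
        "name": "ubiquitin",      # or "protein_g", or letters = "ACDE..."
        "letters": "",
    },
    "local_model": {
        "params": "default",      # or a path to a YAML parameter file
    },
    "target": {
        "kind": "rg_gaussian",    # or "hbond_multinomial"
        "mean": 24.0,             # Angstrom (Rg target)
        "sd": 1.0,                # Angstrom
        "counts": [],             # 8 integers (H-bond target); [] = built-in fixture
        "pseudocount": 0.5,
    },
    "mcmc": {
        "steps": 200_000,
        "window_min": 1,
        "window_max": 20,
        "thinning": 10,
        "burn_in_fraction": 0.1,
        "seed": 1,
    },
    "reference": {
        "bin_width": 0.08,        # Angstrom
        "rg_min": 19.0,
        "rg_max": 31.0,
        "wl_stages": 10,
        "wl_steps_per_stage": 20_000,
        "final_steps": 400_000,
    },
    "iterate": {
        "n_iterations": 6,
        "samples_per_iteration": 2000,
        "steps_per_iteration": 150_000,
        "n_chains": 25,
        "update_clip": 1.2,
        "window_min": 1,
        "window_max": 10,
    },
    "hbond": {
        "cutoff": 3.5,            # Angstrom, N..O
        "min_angle": 100.0,       # degrees
        "min_sep": 2,             # minimum |i - j|
    },
    "geometry": {},               # GeometryParams field overrides
    "toy": {
        "L": 8,
        "K": 3,
        "self_prob": 0.6,         # diagonal of the toy transition matrix
        "steps": 200_000,
    },
}


def merge_config(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown configuration field: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration field {where} must be a table")
            out[key] = merge_config(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolved configuration: defaults <- file <- overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, "rb") as fh:
            cfg = merge_config(cfg, tomllib.load(fh))
    if overrides:
        cfg = merge_config(cfg, overrides)
    return cfg
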