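"""Reference configuration for the closed-loop oculomotor model.

The published architecture fixes the population set, component types and
projection topology; the scalar weights, time constants, offsets and
noise amplitudes below are free parameters of the model, chosen by the
tuning harnesses in :mod:`sacsim.experiments` so that the closed loop
makes single, accurate saccades with the documented latency behaviour,
and then frozen here as the reference configuration.

Projection ``weight`` semantics: for ``one_to_one`` / ``decaying`` /
``diffuse`` kernels the weight is the per-edge (or per-edge-sum for
diffuse) strength; for ``gaussian`` kernels it is the *total* kernel
mass (the builder's peak weight is weight / sum-of-kernel), which keeps
loop gains independent of the kernel width.
"""

from __future__ import annotations

import copy
import json
from typing import Any

import yaml

__all__ = ["default_config", "load_config", "merge_config", "config_hash"]


_DEFAULT: dict[str, Any] = {
    "mapping": {"W_nfs": 50, "W_fov": 61.0, "E2": 2.5},
    "world": {"blur_sigma": 1.0, "fovea_mask_deg": 1.5, "combine": "max"},
    "dopamine": 0.7,
    "dt": 0.001,
    "dt_plant": 0.025,
    "flags": {
        "widening": True,
        "tecto_tectal": True,
        "ibn_feedback": True,
        "tn_reset": True,
    },
    "populations": {
        "Retina_1": {"component": "LINret", "tau": 0.008},
        "Retina_2": {"component": "LINret", "tau": 0.060},
        "FEF": {"component": "LINlinear", "tau": 0.020, "c": 0.0, "alpha": 0.003},
        "Thalamus": {"component": "LINlinear", "tau": 0.015, "c": 0.02, "alpha": 0.003},
        "Str_D1": {"component": "D1MSN", "tau": 0.020, "c": 0.10},
        "Str_D2": {"component": "D2MSN", "tau": 0.020, "c": 0.10},
        "STN": {"component": "LINexp", "tau": 0.010, "V_r_minus": -0.5},
        "GPe": {"component": "LINlinear", "tau": 0.020, "c": -0.2, "alpha": 0.005},
        "SNr": {"component": "LINlinear", "tau": 0.020, "c": -0.2, "alpha": 0.005},
        "SC_sup": {"component": "LINlinear", "tau": 0.010, "c": 0.0, "alpha": 0.003},
        "SC_deep": {"component": "LINlinear", "tau": 0.012, "c": 0.08, "alpha": 0.003},
        "SC_deep2": {"component": "LINlinear", "tau": 0.010, "c": 0.02, "alpha": 0.0},
        "SC_avg": {"component": "LINlinear", "tau": 0.005, "c": 0.1, "alpha": 0.0},
    },
    "fef_add_noise_alpha": 0.01,
    "projections": [
        {"source": "World", "target": "Retina_1", "kernel": "one_to_one", "weight": 1.0},
        {"source": "World", "target": "Retina_2", "kernel": "one_to_one", "weight": 1.0},
        {"source": "Retina_2", "target": "Retina_1", "kernel": "one_to_one", "weight": 1.0,
         "sign": -1},
        {"source": "Retina_1", "target": "SC_sup", "kernel": "gaussian", "sigma": 1.0,
         "weight": 1.0},
        {"source": "FEF_add_noise", "target": "FEF", "kernel": "gaussian", "sigma": 1.0,
         "weight": 1.0, "delay": 0.030},
        {"source": "Thalamus", "target": "FEF", "kernel": "one_to_one", "weight": 0.9},
        {"source": "FEF", "target": "Thalamus", "kernel": "one_to_one", "weight": 0.9},
        {"source": "SC_deep", "target": "Thalamus", "kernel": "gaussian", "sigma": 1.0,
         "weight": 0.4},
        {"source": "SNr", "target": "Thalamus", "kernel": "one_to_one", "weight": 3.5,
         "sign": -1, "port": "shunting"},
        {"source": "FEF", "target": "Str_D1", "kernel": "decaying", "weight": 0.6},
        {"source": "FEF", "target": "Str_D2", "kernel": "decaying", "weight": 0.6},
        {"source": "Thalamus", "target": "Str_D1", "kernel": "decaying", "weight": 0.6},
        {"source": "Thalamus", "target": "Str_D2", "kernel": "decaying", "weight": 0.6},
        {"source": "FEF", "target": "STN", "kernel": "one_to_one", "weight": 1.0},
        {"source": "STN", "target": "SNr", "kernel": "diffuse", "weight": 1.6},
        {"source": "STN", "target": "GPe", "kernel": "diffuse", "weight": 0.9},
        {"source": "Str_D1", "target": "SNr", "kernel": "gaussian", "sigma": 1.0,
         "weight": 1.0, "sign": -1},
        {"source": "Str_D2", "target": "GPe", "kernel": "gaussian", "sigma": 1.0,
         "weight": 1.0, "sign": -1},
        {"source": "GPe", "target": "STN", "kernel": "one_to_one", "weight": 0.9, "sign": -1},
        {"source": "GPe", "target": "SNr", "kernel": "one_to_one", "weight": 0.3, "sign": -1},
        {"source": "SNr", "target": "SC_deep", "kernel": "one_to_one", "weight": 1.5,
         "sign": -1},
        {"source": "SC_sup", "target": "SC_deep", "kernel": "gaussian", "sigma": 1.0,
         "weight": 0.5},
        {"source": "FEF", "target": "SC_deep", "kernel": "gaussian", "sigma": 1.0,
         "weight": 0.8},
        {"source": "SC_deep", "target": "SC_deep", "kernel": "gaussian", "sigma": 1.5,
         "weight": 0.55},
        {"source": "SC_deep", "target": "SC_deep", "kernel": "tecto_tectal", "gain": 0.3,
         "sigma": 2.0, "sign": -1},
        {"source": "SC_deep", "target": "SC_deep2", "kernel": "widening", "weight": 0.15},
        {"source": "SC_deep2", "target": "SC_avg", "kernel": "one_to_one", "weight": 3.0},
    ],
    # Widening projection field; m_sigma is calibrated by the
    # invariant-integral harness (see docs/methods.md).
    "widening": {"m_sigma": 3.5, "sigma_0": 0.3, "M_0": 12.43, "r_0": 20.0,
                 "threshold": 0.02, "use_eccentricity": True},
    "decaying": {"midpoint": 10.0, "steepness": 0.5},
    "feedback": {"weight": 4.0, "targets": ["SC_deep", "Thalamus", "FEF"],
                 "port": "shunting", "delay": 0.1},
    "sbg": {
        "tau_llbn": 0.008, "tau_ebn": 0.008, "tau_ibn": 0.020, "tau_tn": 0.050,
        "tau_mn": 0.005, "tau_opn": 0.005,
        "b_llbn": 0.0, "b_ebn": 0.05, "b_ibn": 0.0, "b_tn": 0.0, "b_mn": 0.02,
        "b_opn": -3.0,
        "w_sc": 0.45, "w_ibn_llbn": 0.5, "w_llbn_opn": 10.0, "w_llbn_ebn": 1.0,
        "w_opn_ebn": 2.0, "w_ebn_opn": 8.0, "w_ebn_ibn": 1.0, "g_tn": 1.0, "g_reset": 2.5,
        "w_ebn_mn": 0.2, "w_tn_mn": 0.1175, "ibn_delay": 0.008, "w_fb": 2.0,
        "weight_maps": {
            "left": {"i": 0.0016, "j": 0.087},
            "right": {"i": 0.0016, "j": 0.087},
            "up": {"i": 0.0013, "j": 0.095},
            "down": {"i": 0.0013, "j": 0.095},
        },
    },
    "plant": {"mass": 7.5e-3, "diameter": 24e-3, "K": 1.0e-3, "C": 5.0e-5,
              "F_max": 0.1},
}


def default_config() -> dict[str, Any]:
    """A deep copy of the reference configuration."""
    return copy.deepcopy(_DEFAULT)


def merge_config(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict[str, Any]:
    """Reference config, optionally overridden by a YAML/JSON file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, override)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration (for run manifests)."""
    import hashlib

    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
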