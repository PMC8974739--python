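"""YAML configuration: one file governs phantom, protocol, and analysis.

Schema (all keys optional; defaults shown)::

    seed: 0
    variant: pre_fess            # pre_fess | post_fess
    protocol: {...}              # explicit phase block, overrides `variant`
    phantom:
      grid_shape: [64, 64, 48]
      voxel_mm: [3.0, 3.0, 3.0]
      nasal_tau_s: 2.5
      noise_sigma_hu: 5.0
      compartments:              # per-sinus overrides of the preset table
        maxillary_L: {k_laminar: 0.0, k_pulsating: 0.1428, ...}
    analysis:
      channel: mixed
      input_nostril: nasal_left
      enhancement_mode: constant # constant | frame
      erosion_voxels: 0
      fit_windows:               # per-ROI overrides
        maxillary_L:
          wash_in: {start_s: 34.5, end_s: 52.5, t0_s: 34.5}
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .phantom import CompartmentKinetics, PhantomSpec, default_kinetics
from .pipeline import FitWindow, default_fit_windows
from .protocol import Protocol, build_protocol

__all__ = ["DEFAULT_CONFIG", "load_config", "phantom_spec_from_config",
           "protocol_from_config", "fit_windows_from_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "variant": "pre_fess",
    "protocol": None,
    "phantom": {
        "grid_shape": [64, 64, 48],
        "voxel_mm": [3.0, 3.0, 3.0],
        "nasal_tau_s": 2.5,
        "noise_sigma_hu": 5.0,
        "compartments": {},
    },
    "analysis": {
        "channel": "mixed",
        "input_nostril": "nasal_left",
        "enhancement_mode": "constant",
        "erosion_voxels": 0,
        "fit_windows": {},
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load and validate a YAML config, merged over the defaults.

    Raises
    ------
    ConfigError
        On unreadable YAML, unknown top-level keys, or invalid values.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        path = Path(path)
        try:
            user = yaml.safe_load(path.read_text())
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
        cfg = _deep_merge(cfg, user)

    if cfg["variant"] not in ("pre_fess", "post_fess"):
        raise ConfigError(f"variant must be pre_fess or post_fess, got {cfg['variant']!r}")
    ph = cfg["phantom"]
    if len(ph["grid_shape"]) != 3:
        raise ConfigError(f"phantom.grid_shape must have 3 entries, got {ph['grid_shape']}")
    if ph["noise_sigma_hu"] < 0:
        raise ConfigError("phantom.noise_sigma_hu must be >= 0")
    if cfg["analysis"]["enhancement_mode"] not in ("constant", "frame"):
        raise ConfigError("analysis.enhancement_mode must be 'constant' or 'frame'")
    return cfg


def phantom_spec_from_config(cfg: Mapping[str, Any]) -> PhantomSpec:
    """Build a :class:`PhantomSpec` (preset kinetics + per-sinus overrides)."""
    ph = cfg["phantom"]
    compartments = default_kinetics(cfg["variant"])
    for name, fields in (ph.get("compartments") or {}).items():
        if name not in compartments:
            raise ConfigError(f"phantom.compartments: unknown sinus {name!r}")
        base = compartments[name]
        try:
            compartments[name] = CompartmentKinetics(
                name=name,
                k_laminar=fields.get("k_laminar", base.k_laminar),
                k_pulsating=fields.get("k_pulsating", base.k_pulsating),
                c_eq=fields.get("c_eq", base.c_eq),
                k_laminar_out=fields.get("k_laminar_out", base.k_laminar_out),
                k_pulsating_out=fields.get("k_pulsating_out", base.k_pulsating_out),
            )
        except ValueError as exc:
            raise ConfigError(f"phantom.compartments.{name}: {exc}") from exc
    try:
        return PhantomSpec(
            grid_shape=tuple(ph["grid_shape"]),
            voxel_mm=tuple(ph["voxel_mm"]),
            nasal_tau_s=ph["nasal_tau_s"],
            compartments=compartments,
            noise_sigma_hu=ph["noise_sigma_hu"],
            seed=int(cfg["seed"]),
        )
    except ValueError as exc:
        raise ConfigError(f"phantom: {exc}") from exc


def protocol_from_config(cfg: Mapping[str, Any]) -> Protocol:
    """Explicit ``protocol:`` block if given, else the published variant."""
    if cfg.get("protocol"):
        try:
            return Protocol.from_dict(cfg["protocol"])
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"protocol: {exc}") from exc
    return build_protocol(cfg["variant"])


def fit_windows_from_config(cfg: Mapping[str, Any]) -> dict[str, dict[str, FitWindow]]:
    """Default windows for the variant, overlaid with config overrides."""
    windows = default_fit_windows(cfg["variant"])
    for roi, per_dir in (cfg["analysis"].get("fit_windows") or {}).items():
        windows.setdefault(roi, {})
        for direction, w in per_dir.items():
            try:
                windows[roi][direction] = FitWindow(
                    float(w["start_s"]), float(w["end_s"]), float(w["t0_s"])
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(
                    f"analysis.fit_windows.{roi}.{direction}: needs start_s, "
                    f"end_s, t0_s ({exc})"
                ) from exc
    return windows
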