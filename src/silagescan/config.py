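"""YAML run configuration: validation, seed plumbing, config hashing.

A simulation config looks like::

    seed: 42              # mandatory; governs every stochastic stage
    seasons:
      - preset: "2021"    # or explicit SeasonConfig fields
      - n_plants: 50
        wp_mean: 67.0
        wp_sd: 6.0
        wp_min: 55.0
        wp_max: 81.0
        label: "custom"
    instruments:          # optional; defaults to the three-instrument set
      - instrument_id: 1
        wavelength_shift: 0.0
        gain: 1.0
        baseline_offset: 0.0
        noise_sd: 0.004
    grid:                 # optional; defaults to the 1350–2550 nm scanner grid
      start_nm: 1350, end_nm: 2550, step_start: 2.5, step_end: 8.8

Seeds for individual pipeline stages are derived from the root seed keyed by
stage name, so partial reruns reproduce exactly.
"""

from __future__ import annotations

import hashlib
import json
import zlib

import numpy as np
import yaml

from .synthetic import (
    ConfigError,
    InstrumentProfile,
    SeasonConfig,
    SpectralSceneConfig,
    default_profiles,
    make_wavelength_grid,
    season_preset,
)

__all__ = ["load_yaml", "build_simulation", "config_hash", "derive_seed",
           "ConfigError"]

_SEASON_FIELDS = {"n_plants", "wp_mean", "wp_sd", "wp_min", "wp_max",
                  "em_residual_sd", "sel", "scan_moisture_sd",
                  "n_replicates", "label"}
_PROFILE_FIELDS = {"instrument_id", "wavelength_shift", "gain",
                   "baseline_offset", "noise_sd", "em_response_gain",
                   "em_response_offset"}


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash of a config for output provenance."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def derive_seed(root_seed: int, stage: str) -> int:
    """Stage-keyed child seed below 2^31, deterministic in (seed, stage)."""
    return (int(root_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _season_from_dict(d: dict) -> SeasonConfig:
    if "preset" in d:
        base = season_preset(d["preset"])
        overrides = {k: v for k, v in d.items() if k != "preset"}
        bad = set(overrides) - _SEASON_FIELDS
        if bad:
            raise ConfigError(f"unknown season fields {sorted(bad)}")
        if overrides:
            from dataclasses import replace
            base = replace(base, **overrides)
        return base
    bad = set(d) - _SEASON_FIELDS
    if bad:
        raise ConfigError(f"unknown season fields {sorted(bad)}")
    missing = {"n_plants", "wp_mean", "wp_sd", "wp_min", "wp_max"} - set(d)
    if missing:
        raise ConfigError(f"season config missing fields {sorted(missing)}")
    return SeasonConfig(**d)


def _profile_from_dict(d: dict) -> InstrumentProfile:
    bad = set(d) - _PROFILE_FIELDS
    if bad:
        raise ConfigError(f"unknown instrument fields {sorted(bad)}")
    if "instrument_id" not in d:
        raise ConfigError("instrument profile needs instrument_id")
    return InstrumentProfile(**d)


def build_simulation(cfg: dict):
    """Validate a simulate config and return
    (season_cfgs, profiles, scene, grid, seed)."""
    if "seed" not in cfg:
        raise ConfigError("config must set a seed")
    seed = cfg["seed"]
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    seasons_raw = cfg.get("seasons")
    if not seasons_raw or not isinstance(seasons_raw, list):
        raise ConfigError("config must list at least one season")
    seasons = [_season_from_dict(dict(s)) for s in seasons_raw]
    profiles_raw = cfg.get("instruments")
    if profiles_raw is None:
        profiles = default_profiles()
    else:
        profiles = tuple(_profile_from_dict(dict(p)) for p in profiles_raw)
    scene = SpectralSceneConfig()
    grid_cfg = cfg.get("grid")
    if grid_cfg is None:
        grid = make_wavelength_grid(1350.0, 2550.0, 2.5, 8.8)
    else:
        grid = make_wavelength_grid(
            grid_cfg.get("start_nm", 1350.0), grid_cfg.get("end_nm", 2550.0),
            grid_cfg.get("step_start", 2.5), grid_cfg.get("step_end", 8.8))
    return seasons, profiles, scene, grid, seed
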