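"""Configuration files, seeded RNG streams, and run manifests.

A config file is a flat YAML (or JSON — YAML is a superset) mapping whose
keys are exactly the :class:`~.core.SimulationParams` field names plus an
allowed set of experiment keys.  Unknown keys are an error: silently
ignoring a typo in, say, ``mu_d`` would corrupt a study.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .core import ParamError, SimulationParams

__all__ = ["ConfigError", "load_config", "save_config", "spawn_rngs",
           "EXPERIMENT_KEYS"]


class ConfigError(ValueError):
    """Raised for unparsable, unknown-key, or out-of-range configuration."""


#: Keys understood by the experiment drivers and CLI, beyond the model
#: parameters themselves.
EXPERIMENT_KEYS = frozenset({
    "t_max", "stride", "max_events", "dt", "cutoff", "couple_to_birth",
    "replicates", "k1", "k_lo", "k_hi", "t_total", "window",
    "burn_in_time", "burn_in_gamma", "flip_count", "n0", "init",
    "phenotype_policy", "outdir",
})


def load_config(path) -> tuple[SimulationParams, dict]:
    """Parse and validate a config file -> ``(params, experiment_settings)``."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key: value mapping")
    param_keys = set(SimulationParams.field_names())
    unknown = set(raw) - param_keys - EXPERIMENT_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {sorted(unknown)}")
    params_dict = {k: v for k, v in raw.items() if k in param_keys}
    extras = {k: v for k, v in raw.items() if k in EXPERIMENT_KEYS}
    try:
        params = SimulationParams.from_dict(params_dict)
    except ParamError as e:
        raise ConfigError(f"{path}: {e}") from e
    return params, extras


def save_config(params: SimulationParams, path, extras: dict | None = None) -> None:
    """Write a config that :func:`load_config` round-trips exactly."""
    data = dict(params.to_dict())
    if extras:
        unknown = set(extras) - EXPERIMENT_KEYS
        if unknown:
            raise ConfigError(f"unknown experiment key(s): {sorted(unknown)}")
        data.update(extras)
    Path(path).write_text(
        yaml.safe_dump(data, default_flow_style=False, sort_keys=True)
    )


def spawn_rngs(seed: int, n_streams: int) -> list[np.random.Generator]:
    """``n_streams`` reproducible, statistically independent generators.

    Stream ``i`` depends only on ``(seed, i)``, so replicate results are
    invariant under the order in which replicates are executed.
    """
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_streams)
    return [np.random.default_rng(c) for c in children]
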