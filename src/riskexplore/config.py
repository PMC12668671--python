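"""YAML run configuration: environment constants, agent parameters, fit settings.

Every command echoes its fully resolved configuration into the run log so a
fit can be reproduced from its outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .environment import EnvConstants
from .fitting import PriorRanges
from .simulate import AgentParams

__all__ = ["load_yaml", "env_from_config", "agent_from_config", "priors_from_config", "echo_config"]


def load_yaml(path) -> dict:
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"could not parse YAML config {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    return data


def env_from_config(cfg: dict) -> EnvConstants:
    return EnvConstants(**cfg.get("environment", {}))


def agent_from_config(cfg: dict) -> AgentParams:
    if "agent" not in cfg:
        raise ValueError("config has no 'agent' section with the nine parameters")
    return AgentParams(**cfg["agent"])


def priors_from_config(cfg: dict) -> PriorRanges:
    pri = cfg.get("priors", {})
    kwargs = {k: tuple(v) for k, v in pri.items()}
    return PriorRanges(**kwargs)


def echo_config(cfg: dict, env: EnvConstants, extra: dict | None = None) -> str:
    """Serialize the effective configuration for provenance logging."""
    payload = {
        "config": cfg,
        "environment": asdict(env),
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2, default=str)
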