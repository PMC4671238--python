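"""Assessment configuration: YAML/JSON schema and defaults preset.

A config file names every distribution explicitly, e.g.::

    defaults: who_ipcs            # optional preset filling the blocks below
    endpoint:
      class: continuous           # continuous | deterministic_quantal | stochastic_quantal
      critical_effect_size: 0.05  # fraction (percent change / extra risk)
      direction: auto
    goal:
      target_incidence: 0.01
      confidence: 0.95
    adjustments:
      route: oral
      bw_animal: 0.496            # kg
      bw_human: 70.0              # kg
      alpha: {mean: 0.7, sd: 0.024}
      csaf_ddef: 1.0
      ahu_gsd: 2.0                # or sigma_ahu (log-SD)
      ou: []                      # list of {point, gsd} or {point, p5, p95}
    variability:
      sigma_h: {gm: 0.746, gsd: 1.59}   # or {fixed: value}
    sampling:
      n_boot: 1000
      n_mc: 1000000
      n_inner: 10000
    families: null                # default: all families for the data kind

The ``who_ipcs`` preset carries the harmonized historical-data defaults:
alpha ~ Normal(0.7, 0.024); AHU lognormal GM 1, GSD 2.0; OU omitted;
sigma_H lognormal GM 0.746, GSD 1.59; human BW 70 kg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .adjustments import AdjustmentConfig, LognormalSpec, OUComponent, VariabilitySpec
from .data_io import Direction, EndpointClass, EndpointSpec
from .engine import ProtectionGoal
from .errors import ConfigError

PRESETS = {
    "who_ipcs": {
        "adjustments": {
            "route": "oral",
            "bw_human": 70.0,
            "alpha": {"mean": 0.7, "sd": 0.024},
            "csaf_ddef": 1.0,
            "ahu_gsd": 2.0,
            "ou": [],
        },
        "variability": {"sigma_h": {"gm": 0.746, "gsd": 1.59}},
    }
}


@dataclass
class SamplingConfig:
    n_boot: int = 1000
    n_mc: int = 1_000_000
    n_inner: int = 10_000


@dataclass
class AssessmentConfig:
    endpoint: EndpointSpec
    goal: ProtectionGoal
    adjustments: AdjustmentConfig
    variability: VariabilitySpec
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    families: list[str] | None = None
    raw: dict = field(default_factory=dict)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _ou_component(entry) -> OUComponent:
    if "gsd" in entry:
        return OUComponent(point=float(entry["point"]), gsd=float(entry["gsd"]))
    if "p5" in entry and "p95" in entry:
        spec = LognormalSpec.from_interval(
            gm=float(entry.get("point", 1.0)),
            p5=float(entry["p5"]),
            p95=float(entry["p95"]),
        )
        return OUComponent(point=spec.gm, gsd=spec.gsd)
    raise ConfigError(f"OU component needs 'gsd' or ('p5','p95'): {entry}")


def parse_config(data: dict) -> AssessmentConfig:
    user_adj_keys = set(data.get("adjustments", {}))
    preset_name = data.get("defaults")
    if preset_name is not None:
        if preset_name not in PRESETS:
            raise ConfigError(
                f"unknown defaults preset {preset_name!r}; known: {sorted(PRESETS)}"
            )
        data = _merge(PRESETS[preset_name], data)

    try:
        ep = data["endpoint"]
        endpoint = EndpointSpec(
            endpoint_class=EndpointClass(ep["class"]),
            critical_effect_size=ep.get("critical_effect_size"),
            direction=Direction(ep.get("direction", "auto")),
        )
        goal_block = data.get("goal", {})
        goal = ProtectionGoal(
            m_star=endpoint.critical_effect_size,
            i_star=float(goal_block.get("target_incidence", 0.01)),
            confidence=float(goal_block.get("confidence", 0.95)),
        )
        adj = dict(data.get("adjustments", {}))
        alpha = adj.pop("alpha", {"mean": 0.7, "sd": 0.024})
        ahu_gsd = adj.pop("ahu_gsd", None)
        sigma_ahu = adj.pop("sigma_ahu", None)
        if ahu_gsd is not None and sigma_ahu is not None:
            # user-specified form wins over a preset-supplied one
            if "sigma_ahu" in user_adj_keys and "ahu_gsd" not in user_adj_keys:
                ahu_gsd = None
            elif "ahu_gsd" in user_adj_keys and "sigma_ahu" not in user_adj_keys:
                sigma_ahu = None
            else:
                raise ConfigError("give either ahu_gsd or sigma_ahu, not both")
        if ahu_gsd is not None:
            sigma_ahu = float(np.log(float(ahu_gsd)))
        elif sigma_ahu is None:
            sigma_ahu = float(np.log(2.0))
        ou = [_ou_component(c) for c in adj.pop("ou", [])]
        adjustments = AdjustmentConfig(
            route=adj.pop("route", "oral"),
            bw_animal=float(adj.pop("bw_animal")),
            bw_human=float(adj.pop("bw_human", 70.0)),
            alpha_mean=float(alpha["mean"]),
            alpha_sd=float(alpha["sd"]),
            rddr_rgdr=adj.pop("rddr_rgdr", None),
            sigma_daf=adj.pop("sigma_daf", None),
            csaf_ddef=float(adj.pop("csaf_ddef", 1.0)),
            ou_components=ou,
            sigma_ahu=sigma_ahu,
        )
        if adj:
            raise ConfigError(f"unknown adjustment keys: {sorted(adj)}")
        var_block = data.get("variability", {}).get("sigma_h", {})
        if "fixed" in var_block:
            variability = VariabilitySpec.fixed(float(var_block["fixed"]))
        else:
            variability = VariabilitySpec(
                gm=float(var_block.get("gm", 0.746)),
                gsd=float(var_block.get("gsd", 1.59)),
            )
        samp = data.get("sampling", {})
        sampling = SamplingConfig(
            n_boot=int(samp.get("n_boot", 1000)),
            n_mc=int(samp.get("n_mc", 1_000_000)),
            n_inner=int(samp.get("n_inner", 10_000)),
        )
    except KeyError as exc:
        raise ConfigError(f"missing required config key: {exc}") from exc
    return AssessmentConfig(
        endpoint=endpoint,
        goal=goal,
        adjustments=adjustments,
        variability=variability,
        sampling=sampling,
        families=data.get("families"),
        raw=data,
    )


def load_config(path) -> AssessmentConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return parse_config(data)
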