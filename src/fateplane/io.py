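"""Run configuration, serialization, and tabular output.

Configs are YAML with a fail-closed schema: unknown keys are rejected so a
typo cannot silently fall back to a default.  Every output table embeds the
metadata needed to re-run it exactly (parameters, condition, seed, n_runs,
dt) as comment headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Dict, Optional

import yaml

from .core import ModelParameters, get_preset
from .conditions import Condition, TimedModifier, build_condition
from .simulation import FateProportions

__all__ = [
    "RunConfig",
    "parse_config",
    "write_config",
    "config_to_dict",
    "params_to_dict",
    "params_from_dict",
    "condition_to_dict",
    "condition_from_dict",
    "write_proportions",
    "read_proportions",
]

_PARAM_KEYS = {"m0_norm", "m0_angle", "m1", "m2", "rate", "D", "gamma",
               "alpha", "n0", "n1_norm", "n1_angle", "coupling", "N"}
_COND_KEYS = {"egf_dose", "ectopic_egf", "notch_scale", "ectopic_notch",
              "notch_disabled", "egf_receptor_null_cells", "ac_ablation_time",
              "modifiers", "label"}
_RUN_KEYS = {"preset", "params", "strain", "condition", "n_runs", "dt",
             "seed", "scoring", "out"}


@dataclass
class RunConfig:
    params: ModelParameters
    condition: Condition
    n_runs: int = 2000
    dt: float = 0.005
    seed: int = 0
    scoring: str = "soft"
    out: Optional[str] = None
    preset_name: Optional[str] = None
    strain_name: Optional[str] = None


def _reject_unknown(d: Dict[str, Any], allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in {where}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


def params_to_dict(p: ModelParameters) -> Dict[str, Any]:
    return {
        "m0_norm": float(p.m0_norm), "m0_angle": float(p.m0_angle),
        "m1": [float(x) for x in p.m1], "m2": [float(x) for x in p.m2],
        "rate": float(p.rate), "D": float(p.D), "gamma": float(p.gamma),
        "alpha": float(p.alpha), "n0": float(p.n0),
        "n1_norm": float(p.n1_norm), "n1_angle": float(p.n1_angle),
        "coupling": bool(p.coupling), "N": int(p.N),
    }


def params_from_dict(d: Dict[str, Any]) -> ModelParameters:
    _reject_unknown(d, _PARAM_KEYS, "params")
    return ModelParameters(**d)


def condition_to_dict(c: Condition) -> Dict[str, Any]:
    return {
        "egf_dose": float(c.egf_dose), "ectopic_egf": float(c.ectopic_egf),
        "notch_scale": float(c.notch_scale),
        "ectopic_notch": float(c.ectopic_notch),
        "notch_disabled": bool(c.notch_disabled),
        "egf_receptor_null_cells": sorted(c.egf_receptor_null_cells),
        "ac_ablation_time": (None if c.ac_ablation_time is None
                             else float(c.ac_ablation_time)),
        "modifiers": [{"channel": m.channel,
                       "window": [float(m.window[0]), float(m.window[1])],
                       "delta": float(m.delta)} for m in c.modifiers],
        "label": c.label,
    }


def condition_from_dict(d: Dict[str, Any]) -> Condition:
    _reject_unknown(d, _COND_KEYS, "condition")
    d = dict(d)
    mods = tuple(
        TimedModifier(channel=m["channel"],
                      window=(m["window"][0], m["window"][1]),
                      delta=m["delta"])
        for m in d.pop("modifiers", []))
    cells = frozenset(d.pop("egf_receptor_null_cells", ()))
    return Condition(modifiers=mods, egf_receptor_null_cells=cells, **d)


def parse_config(path) -> RunConfig:
    """Load and validate a run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _reject_unknown(raw, _RUN_KEYS, "config")
    if ("preset" in raw) == ("params" in raw):
        raise ValueError("config must specify exactly one of 'preset'/'params'")
    if ("strain" in raw) == ("condition" in raw):
        raise ValueError("config must specify exactly one of 'strain'/'condition'")
    if "preset" in raw:
        params = get_preset(raw["preset"])
    else:
        params = params_from_dict(raw["params"])
    if "strain" in raw:
        cond = build_condition(raw["strain"])
    else:
        cond = condition_from_dict(raw["condition"])
    return RunConfig(
        params=params, condition=cond,
        n_runs=int(raw.get("n_runs", 2000)), dt=float(raw.get("dt", 0.005)),
        seed=int(raw.get("seed", 0)), scoring=str(raw.get("scoring", "soft")),
        out=raw.get("out"),
        preset_name=raw.get("preset"), strain_name=raw.get("strain"))


def config_to_dict(cfg: RunConfig) -> Dict[str, Any]:
    d: Dict[str, Any] = {}
    if cfg.preset_name:
        d["preset"] = cfg.preset_name
    else:
        d["params"] = params_to_dict(cfg.params)
    if cfg.strain_name:
        d["strain"] = cfg.strain_name
    else:
        d["condition"] = condition_to_dict(cfg.condition)
    d.update(n_runs=cfg.n_runs, dt=cfg.dt, seed=cfg.seed, scoring=cfg.scoring)
    if cfg.out is not None:
        d["out"] = cfg.out
    return d


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def _metadata_header(params: ModelParameters, cond: Optional[Condition],
                     n_runs: int, dt: float, seed) -> str:
    lines = ["# fateplane fate-proportion table"]
    lines.append("# params: " + yaml.safe_dump(
        params_to_dict(params), default_flow_style=True,
        width=10**6).strip())
    if cond is not None:
        lines.append("# condition: " + yaml.safe_dump(
            condition_to_dict(cond), default_flow_style=True,
            width=10**6).strip())
    lines.append(f"# n_runs: {n_runs}  dt: {dt}  seed: {seed}")
    return "\n".join(lines)


def write_proportions(fp: FateProportions, path, params: ModelParameters,
                      cond: Optional[Condition] = None, n_runs: int = 0,
                      dt: float = 0.0, seed=None) -> None:
    """Delimited-text fate-proportion table with re-run metadata."""
    df = fp.to_frame().reset_index(names="cell")
    with open(path, "w") as fh:
        fh.write(_metadata_header(params, cond, n_runs, dt, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_proportions(path) -> FateProportions:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#").set_index("cell")
    p = df[["p1", "p2", "p3"]].to_numpy()
    # written tables are rounded to 6 significant digits; renormalize
    return FateProportions(p / p.sum(axis=1, keepdims=True))
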