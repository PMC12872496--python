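"""Run configuration: YAML/JSON schema, intervention registry, validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

from . import interventions as iv
from .model import SolverOptions
from .parameters import PARAM_NAMES
from .state import CONDITIONS

PROTOCOLS = ("simulate", "rate-scan", "conductance-scan", "pace-pause",
             "phase3", "calibrate-contraction", "record-clamp")

# name -> (builder, description); builders take the intervention's params
# dict and return a ParameterSet transform
def _drug_builder(params):
    name = params.get("name")
    conc = params.get("concentration")
    if name in iv.DRUG_LIBRARY:
        drug = iv.DRUG_LIBRARY[name](conc) if conc is not None \
            else iv.DRUG_LIBRARY[name]()
    else:
        targets = tuple(iv.DrugTarget(t["channel"], t["ic50"], t["n_h"],
                                      t.get("units", "uM"))
                        for t in params.get("targets", ()))
        if not targets:
            raise ValueError(f"unknown drug {name!r} and no targets given")
        drug = iv.DrugSpec(name or "custom", conc or 0.0, targets,
                           params.get("units", "uM"))
    return lambda p: iv.apply_drug(p, drug)


INTERVENTION_REGISTRY = {
    "drug": _drug_builder,
    "af_remodeling": lambda params: (
        lambda p: iv.apply_af_remodeling(p, iv.RemodelingSpec(**params))),
    "scale_conductances": lambda params: (
        lambda p: iv.scale_conductances(p, dict(params))),
    "phase3_ina_mods": lambda params: iv.apply_phase3_ina_mods,
    "ikach": lambda params: (
        lambda p: iv.enable_ikach(p, params.get("ach", 1.0))),
    "ryr_sr_gate": lambda params: (
        lambda p: iv.sensitize_ryr_sr_gate(p, params.get("factor", 0.1))),
    "set_parameters": lambda params: (
        lambda p: p.with_updates(**params)),
}


class ConfigError(ValueError):
    """Schema violation with a field-level message."""


@dataclass
class RunConfig:
    """One CLI run: condition, ordered interventions, protocol, options."""

    protocol: str
    condition: str = "SR"
    interventions: List[dict] = field(default_factory=list)
    protocol_params: dict = field(default_factory=dict)
    solver: SolverOptions = field(default_factory=SolverOptions)
    output: dict = field(default_factory=dict)
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    def build_interventions(self):
        """Ordered (description, transform) pairs from the registry."""
        out = []
        for item in self.interventions:
            kind = item.get("kind")
            if kind not in INTERVENTION_REGISTRY:
                raise ConfigError(
                    f"interventions: unknown kind {kind!r}; registered: "
                    f"{sorted(INTERVENTION_REGISTRY)}")
            params = {k: v for k, v in item.items() if k != "kind"}
            out.append((f"{kind}:{params}",
                        INTERVENTION_REGISTRY[kind](params)))
        return out

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str)
            .encode()).hexdigest()[:16]

    def manifest(self) -> dict:
        from . import __version__
        return {"config_hash": self.config_hash(),
                "package_version": __version__,
                "protocol": self.protocol,
                "condition": self.condition,
                "solver": {"rtol": self.solver.rtol,
                           "atol_scale": self.solver.atol_scale,
                           "max_step": self.solver.max_step,
                           "dt_out": self.solver.dt_out},
                "seed": self.seed,
                "config": self.raw}


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "protocol" not in data:
        raise ConfigError(f"{path}: missing required field 'protocol'")
    protocol = data["protocol"]
    if protocol not in PROTOCOLS:
        raise ConfigError(
            f"{path}: protocol: unknown value {protocol!r}; "
            f"expected one of {PROTOCOLS}")
    condition = data.get("condition", "SR")
    if condition not in CONDITIONS:
        raise ConfigError(
            f"{path}: condition: unknown value {condition!r}; "
            f"expected one of {CONDITIONS}")
    ivs = data.get("interventions", [])
    if not isinstance(ivs, list):
        raise ConfigError(f"{path}: interventions: must be a list")
    solver_kw = data.get("solver", {})
    unknown = set(solver_kw) - {"rtol", "atol_scale", "max_step", "dt_out",
                                "method"}
    if unknown:
        raise ConfigError(f"{path}: solver: unknown fields {sorted(unknown)}")
    overrides = data.get("parameters", {})
    unknown = set(overrides) - set(PARAM_NAMES)
    if unknown:
        raise ConfigError(
            f"{path}: parameters: unknown names {sorted(unknown)}")
    if overrides:
        ivs = [{"kind": "set_parameters", **overrides}] + list(ivs)
    cfg = RunConfig(
        protocol=protocol, condition=condition, interventions=ivs,
        protocol_params=data.get("protocol_params", {}),
        solver=SolverOptions(**solver_kw),
        output=data.get("output", {}),
        seed=int(data.get("seed", 0)),
        raw=data)
    cfg.build_interventions()   # validates intervention kinds eagerly
    return cfg
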