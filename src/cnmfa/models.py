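"""Access to the packaged default C. necator H16 central-carbon model."""

from __future__ import annotations

from importlib import resources

import yaml

from .network import MetabolicModel, parse_model

__all__ = ["load_default_model", "default_config", "condition_setup",
           "CONDITIONS"]

CONDITIONS = ("hetero_fructose", "hetero_glycerol", "mixo_glycerol_co2")


def default_config() -> dict:
    src = resources.files("cnmfa.data").joinpath("cnecator_core.yaml")
    with resources.as_file(src) as p, open(p, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_default_model() -> MetabolicModel:
    """The packaged central-carbon model with roles and condition blocks."""
    src = resources.files("cnmfa.data").joinpath("cnecator_core.csv")
    with resources.as_file(src) as p, open(p, encoding="utf-8") as fh:
        text = fh.read()
    return parse_model(text, default_config())


def condition_setup(model: MetabolicModel, condition: str):
    """(measured flux values, constrained-demand overrides) for a condition."""
    if condition not in model.conditions:
        raise KeyError(f"unknown condition {condition!r}; have "
                       f"{sorted(model.conditions)}")
    block = model.conditions[condition]
    measured = {k: float(v) for k, v in (block.get("measured") or {}).items()}
    demand = block.get("demands")
    overrides = {}
    if demand is not None:
        overrides = {r.id: float(demand) for r in model.reactions
                     if r.flux_class == "constrained" and r.id.endswith("_drain")}
    return measured, overrides
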