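"""Model-input configuration: loading, validation, and translation into
engine objects.

The configuration is one human-readable YAML mapping (see
``data/default_config.yaml``, which ships the full published input set).
Every uncertain leaf is a ``{value, low, high, psa}`` mapping; those leaves
double as the parameter list for the deterministic and probabilistic
sensitivity analyses, addressed by dotted names
(``costs.end_of_life``, ``hazard_ratios.os`` ...).
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import yaml

from .engine import (
    AdverseEvent,
    EconSettings,
    RegimenComponent,
    StrategyDefinition,
    drug_cost_per_cycle,
)
from .survival import ParametricFit, SurvivalModel
from .uncertainty import ParameterSpec


class ConfigError(ValueError):
    """Raised for malformed or incomplete model configuration."""


def default_config() -> dict:
    """The packaged model-input set (published base case)."""
    text = (
        resources.files("psmcea").joinpath("data/default_config.yaml").read_text()
    )
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    if path is None:
        return default_config()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: expected a YAML mapping")
    return cfg


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def apply_overrides(config: dict, overrides: dict[str, float]) -> dict:
    """Deep-copy `config` and set ``<dotted.name>.value`` for each override."""
    cfg = copy.deepcopy(config)
    for name, value in overrides.items():
        node: Any = cfg
        keys = name.split(".")
        try:
            for key in keys:
                node = node[key]
        except (KeyError, TypeError):
            raise ConfigError(f"unknown parameter {name!r}") from None
        if not isinstance(node, dict) or "value" not in node:
            raise ConfigError(f"parameter {name!r} is not an uncertain leaf")
        node["value"] = value
    return cfg


def _leaf(config: dict, dotted: str) -> dict:
    node: Any = config
    for key in dotted.split("."):
        try:
            node = node[key]
        except (KeyError, TypeError):
            raise ConfigError(f"missing configuration entry {dotted!r}") from None
    return node


def _value(config: dict, dotted: str) -> float:
    leaf = _leaf(config, dotted)
    if not isinstance(leaf, dict) or "value" not in leaf:
        raise ConfigError(f"{dotted!r} is not a value leaf")
    return float(leaf["value"])


# ---------------------------------------------------------------------------
# Engine-object builders
# ---------------------------------------------------------------------------

def build_settings(config: dict) -> EconSettings:
    s = config["settings"]
    override = config.get("discount", {}).get("per_cycle", {}).get("value")
    return EconSettings(
        cycle_length_weeks=float(s["cycle_length_weeks"]),
        horizon_cycles=int(s["horizon_cycles"]),
        annual_discount=float(s["annual_discount_rate"]),
        per_cycle_discount_override=(
            float(override) if override is not None else None
        ),
        utility_pfs=_value(config, "utilities.pfs"),
        utility_pp=_value(config, "utilities.pp"),
        end_of_life_cost=_value(config, "costs.end_of_life"),
        ae_window_years=float(s["ae_window_years"]),
        half_cycle_correction=bool(s["half_cycle_correction"]),
        wtp_thresholds=tuple(float(w) for w in s["wtp_thresholds"]),
    )


def _regimen_components(
    config: dict, regimen_name: str, scenario: bool = False
) -> list[RegimenComponent]:
    regimen = config["regimens"][regimen_name]
    comps = []
    for item in regimen["components"]:
        drug = item["drug"]
        price = config["drug_prices"][drug]
        mg_per_kg = float(item.get("mg_per_kg", 0.0))
        if (
            scenario
            and drug == "bevacizumab_biosimilar"
            and item["kind"] == "weight_iv"
        ):
            mg_per_kg = float(config["scenario"]["bevacizumab_mg_per_kg"])
        comps.append(
            RegimenComponent(
                drug=drug,
                kind=item["kind"],
                unit_mg=float(price["unit_mg"]),
                unit_price=float(price["value"]),
                dose_mg=float(item.get("dose_mg", 0.0)),
                mg_per_kg=mg_per_kg,
                mg_per_day=float(item.get("mg_per_day", 0.0)),
            )
        )
    return comps


def _ae_profile(config: dict, arm: str) -> tuple[AdverseEvent, ...]:
    events = []
    for name, leaf in config["adverse_events"].get(arm, {}).items():
        events.append(
            AdverseEvent(
                name=name,
                per_cycle_probability=float(leaf["value"]),
                cost_per_event=_value(config, f"costs.ae_event.{name}"),
                disutility=_value(config, f"disutilities.{name}"),
            )
        )
    return tuple(events)


def build_strategy(
    config: dict,
    arm: str,
    pfs_model: SurvivalModel,
    os_model: SurvivalModel,
    scenario: bool = False,
) -> StrategyDefinition:
    """Assemble one arm's cost structure around its survival models."""
    settings = config["settings"]
    regimen = config["regimens"][arm]
    components = _regimen_components(config, arm, scenario=scenario)
    days_per_cycle = float(settings["cycle_length_weeks"]) * 7.0
    drug_cost = drug_cost_per_cycle(
        components,
        body_weight_kg=float(settings["body_weight_kg"]),
        days_per_cycle=days_per_cycle,
    )
    admin_cost = sum(
        _value(config, f"costs.admin_items.{item}")
        for item in regimen["admin_items"]
    )
    followup_cost = sum(
        _value(config, f"costs.followup_items.{item}")
        for item in config["costs"]["followup_items"]
    )
    subsequent = _value(config, f"costs.subsequent_per_cycle.{arm}")
    cap = regimen.get("treatment_cap_cycles")
    return StrategyDefinition(
        name=arm,
        pfs_model=pfs_model,
        os_model=os_model,
        drug_cost_per_cycle=drug_cost,
        admin_cost_per_cycle=admin_cost,
        followup_cost_per_cycle=followup_cost,
        subsequent_cost_per_cycle=subsequent,
        treatment_cap_cycles=int(cap) if cap is not None else None,
        ae_profile=_ae_profile(config, arm),
    )


def build_strategies(
    config: dict,
    fits: dict[str, ParametricFit],
    scenario: bool = False,
) -> tuple[StrategyDefinition, StrategyDefinition]:
    """Both arms: the intervention carries the fitted reference curves, the
    comparator the same curves HR-adjusted (HR = intervention vs. comparator).
    """
    hr_pfs = _value(config, "hazard_ratios.pfs")
    hr_os = _value(config, "hazard_ratios.os")
    intervention_name = config["metadata"]["intervention"]
    comparator_name = config["metadata"]["comparator"]
    intervention = build_strategy(
        config,
        intervention_name,
        SurvivalModel(fits["PFS"], 1.0),
        SurvivalModel(fits["OS"], 1.0),
        scenario=scenario,
    )
    comparator = build_strategy(
        config,
        comparator_name,
        SurvivalModel(fits["PFS"], hr_pfs),
        SurvivalModel(fits["OS"], hr_os),
    )
    return intervention, comparator


# ---------------------------------------------------------------------------
# Sensitivity-analysis parameter table
# ---------------------------------------------------------------------------

def _walk_leaves(node: Any, prefix: tuple[str, ...]) -> Iterator[tuple[str, dict]]:
    if isinstance(node, dict):
        if "value" in node and "low" in node and "high" in node:
            yield ".".join(prefix), node
            return
        for key, child in node.items():
            yield from _walk_leaves(child, prefix + (str(key),))


_UNCERTAIN_SECTIONS = (
    "drug_prices",
    "costs",
    "hazard_ratios",
    "adverse_events",
    "utilities",
    "disutilities",
)


def parameter_specs(config: dict) -> list[ParameterSpec]:
    """Every uncertain model input as a sensitivity-analysis parameter.

    Includes each ``{value, low, high, psa}`` leaf of the uncertain sections
    plus the per-cycle discount rate (whose base is the engine's operative
    rate when the config leaves it derived from the annual rate).
    """
    specs: list[ParameterSpec] = []
    for section in _UNCERTAIN_SECTIONS:
        if section not in config:
            continue
        for dotted, leaf in _walk_leaves(config[section], (section,)):
            specs.append(
                ParameterSpec(
                    name=dotted,
                    base_value=float(leaf["value"]),
                    low=float(leaf["low"]),
                    high=float(leaf["high"]),
                    psa_family=str(leaf.get("psa", "fixed")),
                )
            )
    disc = config.get("discount", {}).get("per_cycle")
    if disc is not None:
        base = disc.get("value")
        if base is None:
            base = build_settings(config).discount_per_cycle
        specs.append(
            ParameterSpec(
                name="discount.per_cycle",
                base_value=float(base),
                low=float(disc["low"]),
                high=float(disc["high"]),
                psa_family=str(disc.get("psa", "fixed")),
            )
        )
    return specs
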