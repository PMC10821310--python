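"""Study configuration: the full parameter set of one cost-effectiveness run.

A :class:`StudyConfig` bundles everything the model needs - survival curves
for both arms, strategy schedules, costs, utilities, population and engine
settings, plus the uncertainty ranges used by sensitivity analyses - and
round-trips losslessly through YAML.  Validation collects *every*
violation rather than stopping at the first, so a malformed file is
reported in one pass.

Uncertain parameters are addressed by dotted paths into the config tree,
e.g. ``utilities.pfs`` or
``intervention.first_line_drugs[serplulimab].cost_per_cycle``; list
elements are selected by their ``name``/``event`` field.  One
:class:`ParamRange` may carry several paths when the same published value
feeds both arms (shared chemotherapy prices, shared disutilities).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, asdict

import yaml

from .cohort import EconSettings
from .economics import (AdverseEvent, CostTable, DrugSchedule,
                        PopulationSpec, StrategySpec, UtilitySet)
from .survival import ParametricSurvival


class ConfigError(ValueError):
    """Configuration failed validation; ``problems`` lists every violation."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


@dataclass
class ParamRange:
    """Uncertainty specification for one (possibly shared) parameter."""

    name: str
    low: float
    high: float
    distribution: str  # beta | gamma | normal | uniform | fixed
    paths: list

    def validate(self, config: "StudyConfig") -> list:
        problems = []
        if self.distribution not in ("beta", "gamma", "normal", "uniform", "fixed"):
            problems.append(f"uncertainty[{self.name}].distribution unknown")
        if self.low > self.high:
            problems.append(f"uncertainty[{self.name}]: low > high")
        for p in self.paths:
            try:
                base = get_path(config, p)
            except (AttributeError, KeyError) as exc:
                problems.append(f"uncertainty[{self.name}]: bad path {p!r} ({exc})")
                continue
            if not (self.low <= base <= self.high) and self.distribution != "fixed":
                problems.append(
                    f"uncertainty[{self.name}]: base {base} at {p} outside "
                    f"[{self.low}, {self.high}]")
        return problems


@dataclass
class ArmCurves:
    """Fitted overall-survival and progression-free-survival curves."""

    os: ParametricSurvival
    pfs: ParametricSurvival


@dataclass
class SurvivalSet:
    intervention: ArmCurves
    comparator: ArmCurves


@dataclass
class StudyConfig:
    label: str
    settings: EconSettings
    population: PopulationSpec
    utilities: UtilitySet
    costs: CostTable
    survival: SurvivalSet
    intervention: StrategySpec
    comparator: StrategySpec
    uncertainty: list = field(default_factory=list)

    # -- validation -----------------------------------------------------

    def validate(self) -> "StudyConfig":
        problems = []
        problems += self.settings.validate()
        problems += self.population.validate()
        problems += self.utilities.validate()
        problems += self.costs.validate()
        problems += self.intervention.validate("intervention")
        problems += self.comparator.validate("comparator")
        for pr in self.uncertainty:
            problems += pr.validate(self)
        if problems:
            raise ConfigError(problems)
        return self

    # -- YAML round trip ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for arm in ("intervention", "comparator"):
            d["survival"][arm]["os"] = _curve_dict(getattr(self.survival, arm).os)
            d["survival"][arm]["pfs"] = _curve_dict(getattr(self.survival, arm).pfs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        problems = []
        required = ("label", "settings", "population", "utilities", "costs",
                    "survival", "intervention", "comparator")
        missing = [k for k in required if k not in d]
        if missing:
            raise ConfigError([f"missing section {k!r}" for k in missing])

        def curve(spec, where):
            try:
                return ParametricSurvival(spec["family"], tuple(spec["params"]))
            except (KeyError, ValueError) as exc:
                problems.append(f"{where}: {exc}")
                return ParametricSurvival("exponential", (1.0,))

        def strategy(spec, where):
            try:
                return StrategySpec(
                    name=spec["name"],
                    first_line_drugs=[DrugSchedule(**x) for x in spec["first_line_drugs"]],
                    second_line_proportion=spec["second_line_proportion"],
                    second_line_drug=DrugSchedule(**spec["second_line_drug"]),
                    ae_profile=[AdverseEvent(**x) for x in spec["ae_profile"]],
                    ae_lump_cost=spec["ae_lump_cost"],
                )
            except (KeyError, TypeError) as exc:
                problems.append(f"{where}: {exc}")
                return None

        surv = SurvivalSet(
            intervention=ArmCurves(
                os=curve(d["survival"]["intervention"]["os"], "survival.intervention.os"),
                pfs=curve(d["survival"]["intervention"]["pfs"], "survival.intervention.pfs")),
            comparator=ArmCurves(
                os=curve(d["survival"]["comparator"]["os"], "survival.comparator.os"),
                pfs=curve(d["survival"]["comparator"]["pfs"], "survival.comparator.pfs")),
        )
        cfg = cls(
            label=d["label"],
            settings=EconSettings(**d["settings"]),
            population=PopulationSpec(**d["population"]),
            utilities=UtilitySet(**d["utilities"]),
            costs=CostTable(**d["costs"]),
            survival=surv,
            intervention=strategy(d["intervention"], "intervention"),
            comparator=strategy(d["comparator"], "comparator"),
            uncertainty=[ParamRange(**x) for x in d.get("uncertainty", [])],
        )
        if problems:
            raise ConfigError(problems)
        return cfg.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "StudyConfig":
        return copy.deepcopy(self)

    def with_params(self, assignments: dict) -> "StudyConfig":
        """Deep copy with ``{path: value}`` assignments applied."""
        new = self.copy()
        for path, value in assignments.items():
            set_path(new, path, value)
        return new


def _curve_dict(c: ParametricSurvival) -> dict:
    return {"family": c.family, "params": list(c.params),
            "time_unit": c.time_unit}


def load_config(path) -> StudyConfig:
    """Read and validate a YAML study configuration."""
    return StudyConfig.from_yaml(path)


# -- dotted-path parameter access --------------------------------------

_SEG = re.compile(r"^(\w+)(?:\[([^\]]+)\])?$")


def _walk(obj, path: str):
    segments = path.split(".")
    for seg in segments[:-1]:
        obj = _step(obj, seg, path)
    return obj, segments[-1]


def _step(obj, seg: str, path: str):
    m = _SEG.match(seg)
    if not m:
        raise KeyError(f"bad path segment {seg!r} in {path!r}")
    attr, key = m.groups()
    obj = getattr(obj, attr)
    if key is not None:
        for item in obj:
            if getattr(item, "name", getattr(item, "event", None)) == key:
                return item
        raise KeyError(f"no element named {key!r} at {attr!r} in {path!r}")
    return obj


def get_path(config, path: str):
    """Read a parameter value addressed by dotted path."""
    parent, leaf = _walk(config, path)
    m = _SEG.match(leaf)
    if m and m.group(2) is not None:
        return _step(parent, leaf, path)
    return getattr(parent, leaf)


def set_path(config, path: str, value) -> None:
    """Assign a parameter value addressed by dotted path (in place)."""
    parent, leaf = _walk(config, path)
    if not hasattr(parent, leaf):
        raise KeyError(f"no attribute {leaf!r} at end of {path!r}")
    setattr(parent, leaf, value)
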