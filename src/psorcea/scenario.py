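"""Scenario data model: drugs, costs, utilities, timeline, strategies.

A scenario bundles everything the cohort engine needs: one
:class:`DrugProfile` per biologic (acquisition cost per dispense, dose and
dispense calendars, PASI75 response probabilities with 95% CIs), monitoring
and best-supportive-care costs, the two health-state utilities, and the
model timeline.  The bundled ``base_case_au_2020`` scenario transcribes the
2020 Australian PBS prices and the meta-analytic PASI75 rates used for the
eight outpatient biologics; all currency fields are 2020 AUD.

Scenario files are self-contained JSON or YAML documents; ``load_scenario``
validates every invariant and raises :class:`ScenarioValidationError` naming
the offending field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dosing import DispensePlan, DosingSchedule

BSC = "BSC"  # sentinel name of the absorbing best-supportive-care state


class ScenarioValidationError(ValueError):
    """A scenario field violates its invariant; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ScenarioValidationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class DrugProfile:
    """Economics and efficacy of one biologic.

    ``cost_per_dispense`` is the Australian health-system cost net of the
    AUD41.00 patient co-payment; no
    co-payment arithmetic happens at run time.  ``p_induction`` is the
    probability of PASI75 at the end of the 12-week induction period,
    ``p_maintenance`` the probability of retaining PASI75 at each 24-week
    maintenance review.
    """

    name: str
    cost_per_dispense: float
    schedule: DosingSchedule
    dispense_plan: DispensePlan
    p_induction: float
    p_induction_ci: tuple[float, float]
    p_maintenance: float
    p_maintenance_ci: tuple[float, float]

    def validate(self) -> None:
        pre = f"drugs[{self.name}]"
        _require(self.cost_per_dispense > 0, f"{pre}.cost_per_dispense",
                 "must be > 0")
        for label, p, (lo, hi) in (
            ("p_induction", self.p_induction, self.p_induction_ci),
            ("p_maintenance", self.p_maintenance, self.p_maintenance_ci),
        ):
            _require(0 < p < 1, f"{pre}.{label}", "must be in (0, 1)")
            _require(lo <= p <= hi, f"{pre}.{label}_ci",
                     f"CI ({lo}, {hi}) must bracket the point estimate {p}")
            _require(0 < lo <= hi < 1, f"{pre}.{label}_ci",
                     "bounds must lie in (0, 1) and be ordered")


@dataclass(frozen=True)
class MonitoringCosts:
    """Dermatologist visits and investigations, AUD per period."""

    visit_induction: float
    visit_maintenance: float
    investigations_induction: float
    investigations_maintenance: float

    def validate(self) -> None:
        for name in ("visit_induction", "visit_maintenance",
                     "investigations_induction", "investigations_maintenance"):
            _require(getattr(self, name) >= 0, f"monitoring.{name}",
                     "must be >= 0")

    @property
    def induction_total(self) -> float:
        return self.visit_induction + self.investigations_induction

    @property
    def maintenance_total(self) -> float:
        """Per 24-week maintenance period."""
        return self.visit_maintenance + self.investigations_maintenance


@dataclass(frozen=True)
class BscCosts:
    """Best supportive care: cyclosporine plus calcipotriol/betamethasone
    foam.  Induction figures cover the first 12-week period after entering
    BSC; maintenance figures are per 24-week period thereafter."""

    cyclosporine_induction: float
    cyclosporine_maintenance: float
    foam_induction: float
    foam_maintenance: float

    def validate(self) -> None:
        for name in ("cyclosporine_induction", "cyclosporine_maintenance",
                     "foam_induction", "foam_maintenance"):
            _require(getattr(self, name) >= 0, f"bsc.{name}", "must be >= 0")

    @property
    def entry_cycle_total(self) -> float:
        return self.cyclosporine_induction + self.foam_induction

    @property
    def maintenance_total(self) -> float:
        """Per 24-week period."""
        return self.cyclosporine_maintenance + self.foam_maintenance


@dataclass(frozen=True)
class UtilitySet:
    """Annual health-state utilities: uncontrolled psoriasis (PASI 16.5,
    below-PASI75 response) and controlled psoriasis (PASI 4.1)."""

    u_uncontrolled: float
    u_uncontrolled_sd: float
    u_controlled: float
    u_controlled_sd: float

    def validate(self) -> None:
        _require(0 <= self.u_uncontrolled < self.u_controlled <= 1,
                 "utilities", "require 0 <= u_uncontrolled < u_controlled <= 1")
        _require(self.u_uncontrolled_sd >= 0, "utilities.u_uncontrolled_sd",
                 "must be >= 0")
        _require(self.u_controlled_sd >= 0, "utilities.u_controlled_sd",
                 "must be >= 0")


@dataclass(frozen=True)
class Timeline:
    """Model clock: 12-week cycles over a 96-week horizon by default."""

    cycle_weeks: int = 12
    horizon_weeks: int = 96
    maintenance_review_interval_weeks: int = 24
    weeks_per_year: float = 52.0
    annual_discount_rate: float = 0.0

    def validate(self) -> None:
        _require(self.cycle_weeks > 0, "timeline.cycle_weeks", "must be > 0")
        _require(self.horizon_weeks % self.cycle_weeks == 0,
                 "timeline.horizon_weeks",
                 "must be divisible by cycle_weeks")
        _require(self.maintenance_review_interval_weeks % self.cycle_weeks == 0,
                 "timeline.maintenance_review_interval_weeks",
                 "must be divisible by cycle_weeks")
        _require(self.weeks_per_year > 0, "timeline.weeks_per_year",
                 "must be > 0")
        _require(self.annual_discount_rate >= 0,
                 "timeline.annual_discount_rate", "must be >= 0")

    @property
    def n_cycles(self) -> int:
        return self.horizon_weeks // self.cycle_weeks


@dataclass(frozen=True)
class Strategy:
    """An ordered sequence of biologic lines; best supportive care is the
    implicit absorbing terminal state after the last line fails."""

    name: str
    lines: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lines", tuple(self.lines))
        if len(set(self.lines)) != len(self.lines):
            raise ScenarioValidationError(
                f"strategy {self.name}: no drug may appear twice")
        if not self.lines:
            raise ScenarioValidationError(
                f"strategy {self.name}: needs at least one treatment line")


@dataclass(frozen=True)
class ScenarioConfig:
    drugs: Mapping[str, DrugProfile]
    monitoring: MonitoringCosts
    bsc: BscCosts
    utilities: UtilitySet
    timeline: Timeline = field(default_factory=Timeline)
    sequencing_rule: str = "base"
    notes: tuple[str, ...] = ()

    def validate(self) -> "ScenarioConfig":
        _require(len(self.drugs) >= 1, "drugs", "at least one drug required")
        for name, d in self.drugs.items():
            _require(name == d.name, f"drugs[{name}]",
                     "mapping key must equal profile name")
            d.validate()
        self.monitoring.validate()
        self.bsc.validate()
        self.utilities.validate()
        self.timeline.validate()
        _require(self.sequencing_rule in ("base", "alternative"),
                 "sequencing_rule", "must be 'base' or 'alternative'")
        return self


# ---------------------------------------------------------------------------
# sequencing rules

_PREFERRED = {
    # rule -> (second line, third line, fallback third line for the two
    # drugs that already occupy the preferred slots)
    "base": ("risankizumab", "ixekizumab", "guselkumab"),
    "alternative": ("guselkumab", "ixekizumab", "risankizumab"),
}


def sequence_for(first: str, rule: str = "base") -> tuple[str, ...]:
    """Second/third-line assignment for a given first-line biologic.

    Under the base rule the two most effective induction agents,
    risankizumab and ixekizumab, serve as second and third line; a cohort
    already starting on one of them uses the other as second line and
    guselkumab (third most effective) as third line.  The alternative rule
    swaps guselkumab into the second-line slot.
    """
    if rule not in _PREFERRED:
        raise ScenarioValidationError(
            f"sequencing_rule: unknown rule {rule!r}")
    second, third, fallback = _PREFERRED[rule]
    if first == second:
        return (first, third, fallback)
    if first == third:
        return (first, second, fallback)
    return (first, second, third)


def build_strategies(config: ScenarioConfig) -> list[Strategy]:
    """One strategy per drug as first line, under the scenario's rule."""
    strategies = []
    for name in config.drugs:
        lines = sequence_for(name, config.sequencing_rule)
        for d in lines:
            if d not in config.drugs:
                raise ScenarioValidationError(
                    f"strategy {name}: line drug {d!r} not in scenario")
        strategies.append(Strategy(name=name, lines=lines))
    return strategies


# ---------------------------------------------------------------------------
# (de)serialisation

def _drug_to_dict(d: DrugProfile) -> dict[str, Any]:
    return {
        "cost_per_dispense": d.cost_per_dispense,
        "dosing": {
            "loading_dose_weeks": list(d.schedule.loading_dose_weeks),
            "steady_interval_weeks": d.schedule.steady_interval_weeks,
        },
        "dispensing": {
            "induction_weeks": list(d.dispense_plan.induction_weeks),
            "maintenance_interval_weeks":
                d.dispense_plan.maintenance_interval_weeks,
            "maintenance_start_week": d.dispense_plan.maintenance_start_week,
        },
        "p_induction": d.p_induction,
        "p_induction_ci": list(d.p_induction_ci),
        "p_maintenance": d.p_maintenance,
        "p_maintenance_ci": list(d.p_maintenance_ci),
    }


def to_dict(config: ScenarioConfig) -> dict[str, Any]:
    return {
        "currency": "AUD (2020)",
        "drugs": {n: _drug_to_dict(d) for n, d in config.drugs.items()},
        "monitoring": vars(config.monitoring).copy(),
        "bsc": vars(config.bsc).copy(),
        "utilities": vars(config.utilities).copy(),
        "timeline": vars(config.timeline).copy(),
        "sequencing_rule": config.sequencing_rule,
        "notes": list(config.notes),
    }


def _drug_from_dict(name: str, raw: Mapping[str, Any]) -> DrugProfile:
    try:
        dosing = raw["dosing"]
        dispensing = raw["dispensing"]
        return DrugProfile(
            name=name,
            cost_per_dispense=float(raw["cost_per_dispense"]),
            schedule=DosingSchedule(
                tuple(int(w) for w in dosing["loading_dose_weeks"]),
                int(dosing["steady_interval_weeks"]),
            ),
            dispense_plan=DispensePlan(
                tuple(int(w) for w in dispensing["induction_weeks"]),
                int(dispensing["maintenance_interval_weeks"]),
                int(dispensing.get("maintenance_start_week", 12)),
            ),
            p_induction=float(raw["p_induction"]),
            p_induction_ci=tuple(float(x) for x in raw["p_induction_ci"]),
            p_maintenance=float(raw["p_maintenance"]),
            p_maintenance_ci=tuple(float(x) for x in raw["p_maintenance_ci"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ScenarioValidationError):
            raise
        raise ScenarioValidationError(f"drugs[{name}]: {exc}") from exc


def from_dict(raw: Mapping[str, Any]) -> ScenarioConfig:
    try:
        drugs = {n: _drug_from_dict(n, d) for n, d in raw["drugs"].items()}
        config = ScenarioConfig(
            drugs=drugs,
            monitoring=MonitoringCosts(**raw["monitoring"]),
            bsc=BscCosts(**raw["bsc"]),
            utilities=UtilitySet(**raw["utilities"]),
            timeline=Timeline(**raw.get("timeline", {})),
            sequencing_rule=raw.get("sequencing_rule", "base"),
            notes=tuple(raw.get("notes", ())),
        )
    except ScenarioValidationError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ScenarioValidationError(str(exc)) from exc
    return config.validate()


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a JSON or YAML scenario file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return from_dict(raw)


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    path = Path(path)
    data = to_dict(config)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def builtin_base_case() -> ScenarioConfig:
    """The bundled 2020 Australian base-case scenario (8 PBS biologics)."""
    raw = json.loads(
        resources.files("psorcea.data")
        .joinpath("base_case_au_2020.json")
        .read_text()
    )
    return from_dict(raw)
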