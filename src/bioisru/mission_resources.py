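"""Mission definitions and resource budgets.

Two reference missions are modelled: a six-person, 916-day return voyage to
Mars (210 d out, 496 d residence, 210 d back) and a four-person, 187-day
return voyage to the Moon (3.5 d out, 180 d residence, 3.5 d back).
Crew-generated waste streams (CO2, urine water, non-recycled hygiene water)
accumulate at fixed per-crew-day rates; environmental inventories (Martian
atmosphere, lunar shadowed-crater ejecta, soils/regolith) are weight-percent
compositions from which an excavator-plus-processor chain extracts
compounds.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources

from .elements import formula_weight, parse_formula

__all__ = [
    "MissionProfile",
    "WasteStream",
    "EnvironmentInventory",
    "ExcavatorModel",
    "MARS_MISSION",
    "MOON_MISSION",
    "PHASES",
    "load_waste_streams",
    "load_environment_inventories",
    "waste_budget",
    "elemental_content",
    "excavator_extraction_rate",
]

PHASES = ("outbound", "residence", "return", "residence+return")


@dataclass(frozen=True)
class MissionProfile:
    """Crew size and phase durations (days) of a mission."""

    name: str
    crew: int
    outbound_days: float
    residence_days: float
    return_days: float

    def __post_init__(self) -> None:
        if self.crew < 1:
            raise ValueError("crew must be at least 1")
        if min(self.outbound_days, self.residence_days, self.return_days) < 0:
            raise ValueError("phase durations must be non-negative")

    def phase_days(self, phase: str) -> float:
        days = {
            "outbound": self.outbound_days,
            "residence": self.residence_days,
            "return": self.return_days,
            "residence+return": self.residence_days + self.return_days,
        }
        if phase not in days:
            raise ValueError(f"unknown phase {phase!r}; valid phases: {PHASES}")
        return days[phase]

    @property
    def total_days(self) -> float:
        return self.outbound_days + self.residence_days + self.return_days


MARS_MISSION = MissionProfile("mars", 6, 210, 496, 210)
MOON_MISSION = MissionProfile("moon", 4, 3.5, 180, 3.5)


@dataclass(frozen=True)
class WasteStream:
    """A crew waste stream: total rate plus per-component rates (kg/crew/day).

    Components may be elements (carbon, oxygen, ...) tracked as partial
    rates of the stream. When *formula* is given, component fractions are
    checked against the formula's elemental composition within 1%.
    """

    species: str
    rate: float
    component_rates: dict[str, float] = field(default_factory=dict)
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"stream {self.species}: rate must be positive")
        for comp, r in self.component_rates.items():
            if not 0 <= r <= self.rate:
                raise ValueError(
                    f"stream {self.species}: component {comp} rate {r} outside "
                    f"[0, {self.rate}]"
                )
        if self.formula:
            counts = parse_formula(self.formula)
            total = formula_weight(self.formula)
            from .elements import ATOMIC_WEIGHTS
            element_names = {"carbon": "C", "oxygen": "O", "hydrogen": "H",
                             "nitrogen": "N"}
            for comp, r in self.component_rates.items():
                el = element_names.get(comp)
                if el is None or el not in counts:
                    continue
                expected = counts[el] * ATOMIC_WEIGHTS[el] / total
                if abs(r / self.rate - expected) > 0.01:
                    raise ValueError(
                        f"stream {self.species}: {comp} fraction {r / self.rate:.4f}"
                        f" inconsistent with formula {self.formula} ({expected:.4f})"
                    )

    def fraction(self, component: str) -> float:
        if component not in self.component_rates:
            raise KeyError(
                f"component {component!r} not tracked for stream {self.species}; "
                f"available: {sorted(self.component_rates)}"
            )
        return self.component_rates[component] / self.rate


@dataclass(frozen=True)
class EnvironmentInventory:
    """Location-tagged weight-percent composition of an extractable reservoir."""

    location: str
    components: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components.values()):
            raise ValueError(f"{self.location}: fractions must be non-negative")
        if sum(self.components.values()) > 100 + 1e-9:
            raise ValueError(f"{self.location}: weight fractions exceed 100%")


@dataclass(frozen=True)
class ExcavatorModel:
    """Regolith excavator whose throughput scales linearly with its mass.

    The reference point is an 80 kg machine lifting 500 kg of regolith in
    0.5 h; linear mass scaling is a stated model assumption.
    """

    mass: float = 80.0
    reference_mass: float = 80.0
    reference_throughput: float = 500.0
    reference_interval_h: float = 0.5

    def __post_init__(self) -> None:
        if min(self.mass, self.reference_mass, self.reference_throughput,
               self.reference_interval_h) <= 0:
            raise ValueError("excavator parameters must be positive")

    @property
    def regolith_per_day(self) -> float:
        """kg of regolith moved per day, assuming continuous operation."""
        return (self.mass / self.reference_mass) * self.reference_throughput * (
            24.0 / self.reference_interval_h
        )


_STREAM_FORMULAS = {"carbon_dioxide": "CO2", "nonrecycled_water": "H2O"}


def load_waste_streams() -> dict[str, WasteStream]:
    """Packaged crew-waste rate table as WasteStream objects."""
    text = resources.files("bioisru.data").joinpath("waste_streams.csv").read_text()
    rows = list(csv.DictReader(io.StringIO(text)))
    totals: dict[str, float] = {}
    comps: dict[str, dict[str, float]] = {}
    for row in rows:
        stream = row["stream"]
        rate = float(row["rate_kg_per_crew_day"])
        if row["component"] == "total":
            totals[stream] = rate
        else:
            comps.setdefault(stream, {})[row["component"]] = rate
    return {
        name: WasteStream(name, totals[name], comps.get(name, {}),
                          _STREAM_FORMULAS.get(name))
        for name in totals
    }


def load_environment_inventories() -> dict[str, EnvironmentInventory]:
    text = resources.files("bioisru.data").joinpath(
        "environment_inventories.csv").read_text()
    comps: dict[str, dict[str, float]] = {}
    for row in csv.DictReader(io.StringIO(text)):
        comps.setdefault(row["location"], {})[row["compound"]] = float(
            row["weight_percent"])
    return {loc: EnvironmentInventory(loc, c) for loc, c in comps.items()}


def waste_budget(profile: MissionProfile, stream: WasteStream, phase: str) -> float:
    """Total stream mass (kg) accumulated by the crew over a mission phase."""
    return stream.rate * profile.crew * profile.phase_days(phase)


def elemental_content(total_mass: float, stream: WasteStream,
                      component: str) -> float:
    """Mass (kg) of one tracked component within *total_mass* of a stream."""
    return total_mass * stream.fraction(component)


def excavator_extraction_rate(excavator: ExcavatorModel,
                              inventory: EnvironmentInventory,
                              compound: str) -> float:
    """kg/day of *compound* recoverable by one excavator, assuming complete
    extraction from the moved regolith."""
    if compound not in inventory.components:
        raise KeyError(
            f"compound {compound!r} not in {inventory.location} inventory; "
            f"available: {sorted(inventory.components)}"
        )
    return excavator.regolith_per_day * inventory.components[compound] / 100.0
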