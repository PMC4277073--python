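"""Non-biological comparison costs.

Three families of baselines anchor the trade study:

* propellant-plant shipped masses for the Mars and Moon ascent-fuel
  options (stored constants with citations; their derivations are
  chemical-plant designs outside this package's scope);
* wet-food shipping costs, scaled linearly from a six-crew, 916-day
  reference menu study, against a 0.617 kg/crew/day dehydrated-biomass
  requirement;
* habitat three-dimensional-printing costs, scaled linearly from a
  reference 40 m3 printed habitat (8 T total shipped, of which 3.8 T dry
  salts, yielding 6 m3 of structure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "BaselineCost",
    "FoodPlan",
    "HabitatReference",
    "load_baselines",
    "propellant_baselines",
    "food_plans",
    "habitat_reference",
    "wet_food_shipped",
    "dry_biomass_requirement",
    "habitat_costs",
    "iss_food_mass",
]


@dataclass(frozen=True)
class BaselineCost:
    """A stored non-biological cost line with its provenance."""

    scenario: str
    shipped_mass: float  # kg
    source_note: str

    def __post_init__(self) -> None:
        if self.shipped_mass <= 0:
            raise ValueError("baseline shipped mass must be positive")


@dataclass(frozen=True)
class FoodPlan:
    """A wet-food menu with its six-crew/916-day reference totals (kg)."""

    menu: str
    total_916d: float
    shipped_916d: float
    reference_crew: int = 6
    reference_days: float = 916.0

    def __post_init__(self) -> None:
        if self.shipped_916d > self.total_916d:
            raise ValueError("shipped food cannot exceed total food")


@dataclass(frozen=True)
class HabitatReference:
    """Reference printed-habitat costs, all scaled linearly with volume."""

    reference_habitat_volume: float = 40.0  # m3 enclosed
    total_shipped_t: float = 8.0
    dry_salts_t: float = 3.8
    structure_volume_m3: float = 6.0

    def __post_init__(self) -> None:
        if self.dry_salts_t >= self.total_shipped_t:
            raise ValueError("dry salts must be a strict part of total shipped mass")


def load_baselines() -> dict:
    return json.loads(
        resources.files("bioisru.data").joinpath("baselines.json").read_text()
    )


def propellant_baselines() -> dict[str, BaselineCost]:
    raw = load_baselines()["propellant"]
    return {
        key: BaselineCost(key, entry["shipped_mass_kg"], entry["source_note"])
        for key, entry in raw.items()
    }


def food_plans() -> dict[str, FoodPlan]:
    raw = load_baselines()["food"]
    return {
        menu: FoodPlan(menu, raw[menu]["total_916d_kg"], raw[menu]["shipped_916d_kg"],
                       raw["reference_crew"], raw["reference_days"])
        for menu in ("vegetarian", "mixed")
    }


def habitat_reference() -> HabitatReference:
    raw = load_baselines()["habitat"]
    return HabitatReference(
        reference_habitat_volume=raw["reference_habitat_volume_m3"],
        total_shipped_t=raw["total_shipped_t"],
        dry_salts_t=raw["dry_salts_t"],
        structure_volume_m3=raw["structure_volume_m3"],
    )


def wet_food_shipped(plan: FoodPlan, crew: int, days: float) -> float:
    """Shipped wet-food mass (kg), linear in crew and days from the
    reference menu study."""
    return plan.shipped_916d * (crew / plan.reference_crew) * (
        days / plan.reference_days
    )


def dry_biomass_requirement(crew: int, days: float,
                            rate_kg_crew_day: float = 0.617) -> float:
    """kg of fully dehydrated biomass needed to feed *crew* for *days*."""
    if crew < 0 or days < 0 or rate_kg_crew_day < 0:
        raise ValueError("inputs must be non-negative")
    return crew * days * rate_kg_crew_day


def iss_food_mass(crew: int, days: float,
                  rate_kg_crew_day: float = 1.83) -> float:
    """kg of container-style prepared food at the station provisioning rate."""
    return crew * days * rate_kg_crew_day


def habitat_costs(ref: HabitatReference, persons: int,
                  volume_per_person_m3: float) -> tuple[float, float, float]:
    """(total shipped T, dry salts T, structure volume m3) to print a
    habitat of persons × volume_per_person enclosed volume."""
    if persons < 0 or volume_per_person_m3 < 0:
        raise ValueError("inputs must be non-negative")
    scale = persons * volume_per_person_m3 / ref.reference_habitat_volume
    return (ref.total_shipped_t * scale, ref.dry_salts_t * scale,
            ref.structure_volume_m3 * scale)
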