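"""Off-the-shelf bioreactor catalog, sizing and fleet selection.

The catalog is a short table of stirred-tank skids (50–2000 L maximum
working volume) with empty mass, mean power draw per litre of working
volume at fixed aeration, and installed skid volume. Between catalog rows
properties are interpolated linearly in maximum working volume; a
"virtual" vessel of any intermediate nominal size can be constructed that
way (e.g. a 100 L vessel between the 50 and 200 L rows).

Two discrete selection problems recur in the trade study:

* cover: the cheapest multiset of reactors whose summed capacity covers a
  required working volume — minimising unit count first, then total empty
  mass, then skid volume;
* budget: the largest summed capacity attainable within an empty-mass
  budget (an unbounded-knapsack form) — tie-broken by minimal mass, then
  fewest units.

Both are solved by bounded exhaustive enumeration over multisets, which is
cheap at catalog sizes of a handful of rows and is checked against an
independent brute-force oracle in the test-suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

__all__ = [
    "ReactorSpec",
    "ReactorFleet",
    "Catalog",
    "load_catalog",
    "interpolate_property",
    "size_working_volume",
    "WorkingVolume",
    "select_fleet_cover",
    "select_fleet_budget",
    "fleet_totals",
    "assign_working_volumes",
]

PROPERTIES = ("min_working_volume", "empty_mass", "power_density", "skid_volume")


@dataclass(frozen=True)
class ReactorSpec:
    """One catalog row (or an interpolated virtual vessel)."""

    max_working_volume: float  # L
    min_working_volume: float  # L
    empty_mass: float          # kg
    power_density: float       # mW per L working volume
    skid_volume: float         # m3

    def __post_init__(self) -> None:
        if min(self.max_working_volume, self.min_working_volume, self.empty_mass,
               self.power_density, self.skid_volume) <= 0:
            raise ValueError("reactor properties must be positive")
        if self.min_working_volume > self.max_working_volume:
            raise ValueError("min working volume exceeds max")


@dataclass(frozen=True)
class ReactorFleet:
    """A multiset of reactors with assigned working volumes (L)."""

    units: tuple[tuple[ReactorSpec, float], ...]

    @property
    def total_capacity(self) -> float:
        return sum(spec.max_working_volume for spec, _ in self.units)

    @property
    def total_mass(self) -> float:
        return sum(spec.empty_mass for spec, _ in self.units)

    @property
    def total_assigned(self) -> float:
        return sum(v for _, v in self.units)


class Catalog:
    """A validated, size-sorted reactor catalog."""

    def __init__(self, specs: list[ReactorSpec]):
        if not specs:
            raise ValueError("catalog must not be empty")
        specs = sorted(specs, key=lambda s: s.max_working_volume)
        vols = [s.max_working_volume for s in specs]
        masses = [s.empty_mass for s in specs]
        skids = [s.skid_volume for s in specs]
        powers = [s.power_density for s in specs]
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("catalog volumes must be strictly increasing")
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("empty mass must increase strictly with size")
        if any(b <= a for a, b in zip(skids, skids[1:])):
            raise ValueError("skid volume must increase strictly with size")
        if any(b >= a for a, b in zip(powers, powers[1:])):
            raise ValueError("power density must decrease strictly with size")
        self.specs = specs

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(s) for s in self.specs]
        )

    def vessel_at(self, nominal_volume: float) -> ReactorSpec:
        """A virtual vessel of intermediate nominal size, properties
        linearly interpolated between the bracketing rows."""
        return ReactorSpec(
            max_working_volume=nominal_volume,
            min_working_volume=interpolate_property(
                self, nominal_volume, "min_working_volume"),
            empty_mass=interpolate_property(self, nominal_volume, "empty_mass"),
            power_density=interpolate_property(self, nominal_volume, "power_density"),
            skid_volume=interpolate_property(self, nominal_volume, "skid_volume"),
        )


def load_catalog() -> Catalog:
    """The packaged five-row stirred-tank catalog."""
    with resources.files("bioisru.data").joinpath("bioreactors.csv").open() as fh:
        df = pd.read_csv(fh)
    return catalog_from_frame(df)


def catalog_from_frame(df: pd.DataFrame) -> Catalog:
    """Build a catalog from a DataFrame in the packaged CSV schema."""
    return Catalog([
        ReactorSpec(
            max_working_volume=row["max_working_volume_l"],
            min_working_volume=row["min_working_volume_l"],
            empty_mass=row["empty_mass_kg"],
            power_density=row["power_density_mw_per_l"],
            skid_volume=row["skid_volume_m3"],
        )
        for _, row in df.iterrows()
    ])


def interpolate_property(catalog: Catalog, volume: float, prop: str) -> float:
    """Piecewise-linear interpolation of a catalog property in maximum
    working volume. Exact at catalog rows; no extrapolation."""
    if prop not in PROPERTIES:
        raise ValueError(f"unknown property {prop!r}; valid: {PROPERTIES}")
    vols = [s.max_working_volume for s in catalog.specs]
    if not vols[0] <= volume <= vols[-1]:
        raise ValueError(
            f"volume {volume} L outside catalog range [{vols[0]}, {vols[-1]}] L; "
            "extrapolation is not supported"
        )
    vals = [getattr(s, prop) for s in catalog.specs]
    return float(np.interp(volume, vols, vals))


@dataclass(frozen=True)
class WorkingVolume:
    """A sized working volume: raw value and next-whole-litre rounding."""

    raw: float
    whole: int


def size_working_volume(required_kg_per_day: float,
                        productivity_g_per_l_day: float) -> WorkingVolume:
    """Working volume needed to hit a daily production target.

    required (kg/day) over a volumetric productivity (g/L/day); reported raw
    and rounded up to the next whole litre.
    """
    if productivity_g_per_l_day <= 0:
        raise ValueError("productivity must be positive")
    if required_kg_per_day < 0:
        raise ValueError("required rate must be non-negative")
    raw = required_kg_per_day * 1000.0 / productivity_g_per_l_day
    return WorkingVolume(raw=raw, whole=math.ceil(raw))


def _enumerate_multisets(catalog: Catalog, n_units: int):
    return combinations_with_replacement(catalog.specs, n_units)


def select_fleet_cover(catalog: Catalog, required_volume: float,
                       max_units: int = 60) -> ReactorFleet:
    """Cheapest fleet whose summed capacity covers *required_volume* (L).

    Optimisation order: fewest units, then least total empty mass, then
    least total skid volume. Assigned working volumes default to an equal
    split of the requirement (see assign_working_volumes).
    """
    if required_volume <= 0:
        return ReactorFleet(units=())
    largest = catalog.specs[-1].max_working_volume
    n_min = math.ceil(required_volume / largest)
    if n_min > max_units:
        raise ValueError(
            f"requirement {required_volume} L needs more than {max_units} units"
        )
    best = None
    for combo in _enumerate_multisets(catalog, n_min):
        if sum(s.max_working_volume for s in combo) < required_volume:
            continue
        key = (sum(s.empty_mass for s in combo),
               sum(s.skid_volume for s in combo))
        if best is None or key < best[0]:
            best = (key, combo)
    assert best is not None  # n_min copies of the largest always cover
    return assign_working_volumes(list(best[1]), required_volume)


def select_fleet_budget(catalog: Catalog, mass_budget: float,
                        max_units: int = 60) -> ReactorFleet:
    """Largest summed capacity attainable within an empty-mass budget (kg).

    Tie-breaks: minimal total mass, then fewest units. Assigned volumes
    default to each unit's maximum (capacity is the objective).
    """
    cheapest = min(s.empty_mass for s in catalog.specs)
    if mass_budget < cheapest:
        raise ValueError(
            f"budget {mass_budget} kg below the smallest reactor ({cheapest} kg)"
        )
    n_max = min(int(mass_budget // cheapest), max_units)
    best = None
    for n in range(1, n_max + 1):
        for combo in _enumerate_multisets(catalog, n):
            mass = sum(s.empty_mass for s in combo)
            if mass > mass_budget:
                continue
            vol = sum(s.max_working_volume for s in combo)
            key = (-vol, mass, n)
            if best is None or key < best[0]:
                best = (key, combo)
    assert best is not None
    units = tuple((s, float(s.max_working_volume)) for s in best[1])
    return ReactorFleet(units=units)


def assign_working_volumes(specs: list[ReactorSpec],
                           required_volume: float) -> ReactorFleet:
    """Split a required working volume equally across units.

    Each unit's share is rounded up to the next whole litre and clipped to
    its maximum working volume; shares below a unit's catalog minimum are
    kept (the vessel simply runs under-filled) and flagged by fleet_totals.
    """
    if not specs:
        if required_volume > 0:
            raise ValueError("cannot assign volume to an empty fleet")
        return ReactorFleet(units=())
    share = required_volume / len(specs)
    units = tuple(
        (s, float(min(math.ceil(share), s.max_working_volume))) for s in specs
    )
    return ReactorFleet(units=units)


def fleet_totals(fleet: ReactorFleet) -> tuple[float, float, float]:
    """(empty mass kg, drawn power W, skid volume m3) of a fleet.

    Power is assigned volume × the unit's own power density. Assigned
    volumes above a unit's maximum are an error; below the minimum a
    warning is emitted (runs under-filled).
    """
    mass = power_mw = skid = 0.0
    for spec, assigned in fleet.units:
        if assigned > spec.max_working_volume + 1e-9:
            raise ValueError(
                f"assigned volume {assigned} L exceeds unit maximum "
                f"{spec.max_working_volume} L"
            )
        if assigned < spec.min_working_volume - 1e-9:
            warnings.warn(
                f"assigned volume {assigned} L below unit minimum "
                f"{spec.min_working_volume} L; vessel runs under-filled",
                stacklevel=2,
            )
        mass += spec.empty_mass
        power_mw += assigned * spec.power_density
        skid += spec.skid_volume
    return mass, power_mw / 1000.0, skid
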