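"""Species registry, balanced reactions and mass/mole/rate conversions.

This module carries the chemistry behind every production scenario:
conversions between volumetric productivities and daily masses, Henry's-law
dissolved-gas supply, recycle-adjusted hydrogen demand, water-electrolysis
hydrogen output, and carbon-equivalent productivity transfers between
products.

All computations use full-precision conventional atomic weights; printed
comparisons are made at the printed precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .elements import formula_weight, parse_formula

__all__ = [
    "ChemicalSpecies",
    "Reaction",
    "GasSupplySpec",
    "ElectrolyserSpec",
    "SPECIES",
    "load_reactions",
    "molar_mass",
    "mass_yield",
    "rate_convert",
    "dissolved_gas_supply",
    "yield_per_100mol",
    "net_h2_demand",
    "electrolyser_h2_rate",
    "carbon_equivalent_rate",
]

M_H2 = formula_weight("H2")
M_H2O = formula_weight("H2O")


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with its formula-derived composition."""

    name: str
    formula: str
    element_counts: dict[str, int] = field(default_factory=dict)
    molar_mass: float = 0.0

    @classmethod
    def from_formula(cls, name: str, formula: str) -> "ChemicalSpecies":
        counts = parse_formula(formula)
        return cls(name, formula, counts, formula_weight(formula))


@dataclass(frozen=True)
class Reaction:
    """A stoichiometrically balanced transformation.

    Coefficients are keyed by species name. Element balance is asserted
    exactly (to floating tolerance for rational coefficients), mass balance
    within 0.05%.
    """

    name: str
    reactants: dict[str, float]
    products: dict[str, float]
    species: dict[str, ChemicalSpecies]

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for sp in side:
                if sp not in self.species:
                    raise ValueError(f"reaction {self.name}: unknown species {sp!r}")
        balance: dict[str, float] = {}
        for sp, coef in self.reactants.items():
            for el, n in self.species[sp].element_counts.items():
                balance[el] = balance.get(el, 0.0) + coef * n
        for sp, coef in self.products.items():
            for el, n in self.species[sp].element_counts.items():
                balance[el] = balance.get(el, 0.0) - coef * n
        for el, net in balance.items():
            if abs(net) > 1e-9:
                raise ValueError(
                    f"reaction {self.name} not balanced in {el}: residual {net}"
                )
        m_in = sum(c * self.species[s].molar_mass for s, c in self.reactants.items())
        m_out = sum(c * self.species[s].molar_mass for s, c in self.products.items())
        if abs(m_in - m_out) > 5e-4 * m_in:
            raise ValueError(
                f"reaction {self.name} mass imbalance: {m_in} vs {m_out} g/mol"
            )

    def coefficient(self, species_name: str) -> float:
        if species_name in self.reactants:
            return self.reactants[species_name]
        if species_name in self.products:
            return self.products[species_name]
        raise KeyError(
            f"species {species_name!r} not in reaction {self.name} "
            f"(has {sorted({**self.reactants, **self.products})})"
        )


@dataclass(frozen=True)
class GasSupplySpec:
    """Sparged-gas supply into a stirred tank, limited by Henry's law.

    flow: gas volumetric flow (L/h); partial_pressure: bar of the dissolving
    species; henry_constant: dissolved concentration per unit partial
    pressure (mmol L^-1 bar^-1).
    """

    flow_l_per_h: float
    partial_pressure_bar: float
    henry_constant_mmol_per_l_bar: float

    def __post_init__(self) -> None:
        if min(self.flow_l_per_h, self.partial_pressure_bar,
               self.henry_constant_mmol_per_l_bar) < 0:
            raise ValueError("gas supply parameters must be non-negative")


@dataclass(frozen=True)
class ElectrolyserSpec:
    """A water electrolyser: unit mass (kg) and water throughput (g/h)."""

    unit_mass_kg: float = 6.0
    water_flow_g_per_h: float = 3000.0

    def __post_init__(self) -> None:
        if self.unit_mass_kg <= 0 or self.water_flow_g_per_h < 0:
            raise ValueError("electrolyser mass must be positive, flow non-negative")


def _load_species() -> dict[str, ChemicalSpecies]:
    text = resources.files("bioisru.data").joinpath("species.csv").read_text()
    out: dict[str, ChemicalSpecies] = {}
    for line in text.strip().splitlines()[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        name, formula = [f.strip() for f in line.split(",")[:2]]
        out[name] = ChemicalSpecies.from_formula(name, formula)
    return out


SPECIES: dict[str, ChemicalSpecies] = _load_species()


def load_reactions() -> dict[str, Reaction]:
    """Packaged reaction registry; every entry is balance-checked on load."""
    raw = json.loads(
        resources.files("bioisru.data").joinpath("reactions.json").read_text()
    )
    return {
        name: Reaction(name, entry["reactants"], entry["products"], SPECIES)
        for name, entry in raw.items()
    }


def molar_mass(formula: str) -> float:
    """Molar mass (g/mol) of a formula string."""
    return formula_weight(formula)


def mass_yield(reaction: Reaction, given: str, mass_kg: float, target: str) -> float:
    """Mass of *target* produced from *mass_kg* of limiting species *given*.

    Single-substrate form: mass × (ν_target M_target)/(ν_given M_given).
    """
    c_given = reaction.coefficient(given)
    c_target = reaction.coefficient(target)
    m_given = reaction.species[given].molar_mass
    m_target = reaction.species[target].molar_mass
    return mass_kg * (c_target * m_target) / (c_given * m_given)


def rate_convert(rate_mmol_per_l_h: float, species: ChemicalSpecies) -> float:
    """Volumetric productivity mmol L^-1 h^-1 → g L^-1 day^-1."""
    if rate_mmol_per_l_h < 0:
        raise ValueError("rate must be non-negative")
    return rate_mmol_per_l_h * 24.0 * species.molar_mass / 1000.0


def dissolved_gas_supply(spec: GasSupplySpec) -> float:
    """Daily dissolved-gas delivery (mol/day) for a sparged supply.

    The gas stream equilibrates at the species partial pressure, so each
    litre of sparged gas carries H·p mmol into solution.
    """
    return (spec.henry_constant_mmol_per_l_bar * spec.partial_pressure_bar
            * spec.flow_l_per_h * 24.0 / 1000.0)


def yield_per_100mol(product_rate_g_l_day: float, working_volume_l: float,
                     product: ChemicalSpecies, substrate_supply_mol_day: float) -> float:
    """Molar yield as mol product per 100 mol substrate supplied."""
    if substrate_supply_mol_day <= 0:
        raise ValueError("substrate supply must be positive")
    product_mol_day = product_rate_g_l_day * working_volume_l / product.molar_mass
    return 100.0 * product_mol_day / substrate_supply_mol_day


def net_h2_demand(product: ChemicalSpecies, daily_mass_kg: float,
                  net_h2_per_mol: float) -> float:
    """kg/day of make-up hydrogen after product-water recycle.

    net_h2_per_mol is the post-recycle H2 coefficient per mole of product
    (e.g. 3 for the PHB repeating unit, 2 for methane once both product
    waters are electrolysed back).
    """
    if net_h2_per_mol < 0:
        raise ValueError("net H2 coefficient must be non-negative")
    mol_product = daily_mass_kg * 1000.0 / product.molar_mass
    return mol_product * net_h2_per_mol * M_H2 / 1000.0


def electrolyser_h2_rate(spec: ElectrolyserSpec) -> float:
    """kg/day of H2 from full electrolysis of the water throughput."""
    water_g_day = spec.water_flow_g_per_h * 24.0
    return water_g_day * (2 * M_H2) / (2 * M_H2O) / 1000.0


def carbon_equivalent_rate(rate_mmol_l_day: float, source: ChemicalSpecies,
                           target: ChemicalSpecies) -> float:
    """Transfer a molar productivity between products at equal carbon flux."""
    c_from = source.element_counts.get("C", 0)
    c_to = target.element_counts.get("C", 0)
    if c_from == 0 or c_to == 0:
        raise ValueError(
            f"carbon-equivalent rate needs carbon in both species "
            f"({source.name}: {c_from}, {target.name}: {c_to})"
        )
    return rate_mmol_l_day * c_from / c_to
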