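"""Synthetic scenario generation for property testing.

Generates random but structurally valid missions, waste streams, reactor
catalogs and balanced reactions so that every pipeline stage can be
exercised without the packaged tables. Only structural validity is
emulated (monotone catalogs, element-conserving reactions, positive
rates), not the statistics of real organisms or missions.

A single integer seed drives everything; each entity draws from its own
counter-derived substream so generation is order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .bioreactor_catalog import Catalog, ReactorSpec
from .elements import ATOMIC_WEIGHTS
from .mission_resources import MissionProfile, WasteStream
from .stoichiometry import ChemicalSpecies, Reaction

__all__ = ["GeneratorConfig", "ScenarioGenerator"]

_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "crew": (2, 8),
    "duration_days": (5, 600),
    "productivity_g_l_day": (0.1, 500.0),
    "catalog_rows": (3, 6),
    "waste_rate_kg_crew_day": (0.05, 3.0),
    "reactor_volume_l": (20, 4000),
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_scenarios: int = 10
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")


class ScenarioGenerator:
    """Counter-seeded generator of missions, catalogs and reactions."""

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config or GeneratorConfig()

    def _rng(self, counter: int) -> np.random.Generator:
        return np.random.default_rng([self.config.seed, counter])

    def generate_catalog(self, counter: int = 0) -> Catalog:
        """A random catalog with the structure of the packaged one:
        strictly increasing volume/mass/skid, strictly decreasing power
        density."""
        rng = self._rng(counter)
        lo_rows, hi_rows = self.config.ranges["catalog_rows"]
        n = int(rng.integers(int(lo_rows), int(hi_rows) + 1))
        v_lo, v_hi = self.config.ranges["reactor_volume_l"]
        vols = np.sort(rng.uniform(v_lo, v_hi, size=n))
        # enforce strict separation between rows
        vols = vols + np.arange(n) * 1.0
        masses = np.cumsum(rng.uniform(20, 300, size=n)) + rng.uniform(30, 120)
        skids = np.cumsum(rng.uniform(0.1, 1.5, size=n)) + rng.uniform(0.2, 0.8)
        powers = np.sort(rng.uniform(1.0, 12.0, size=n))[::-1]
        powers = powers + np.arange(n, 0, -1) * 0.01
        return Catalog([
            ReactorSpec(
                max_working_volume=float(vols[i]),
                min_working_volume=float(vols[i]) * float(rng.uniform(0.1, 0.3)),
                empty_mass=float(masses[i]),
                power_density=float(powers[i]),
                skid_volume=float(skids[i]),
            )
            for i in range(n)
        ])

    def generate_reaction(self, counter: int = 0) -> Reaction:
        """A random element-balanced reaction over {C, H, O, N}.

        A product C_c H_h O_o N_n is drawn and balanced against CO2, H2,
        NH3 reactants with H2O and O2 closing hydrogen and oxygen; all
        coefficients are exact rationals scaled to integers, so balance
        holds by construction.
        """
        rng = self._rng(counter)
        c = int(rng.integers(1, 9))
        n = int(rng.integers(0, 3))
        h = 3 * n + 2 * int(rng.integers(1, 7))   # keeps h - 3n even, positive
        o = int(rng.integers(0, 5))
        formula = f"C{c}H{h}" + (f"O{o}" if o else "") + (f"N{n}" if n else "")
        product = ChemicalSpecies.from_formula(f"product_{counter}", formula)

        extra_h2 = int(rng.integers(0, 4))
        m = Fraction(h - 3 * n, 2) + extra_h2        # H2 coefficient
        w = Fraction(3 * n) + 2 * m - h              # H2O product; = 2*extra_h2
        w = w / 2
        q = (Fraction(2 * c) - o - w) / 2            # O2: product if >0 else reactant

        species = {
            "carbon_dioxide": ChemicalSpecies.from_formula("carbon_dioxide", "CO2"),
            "hydrogen": ChemicalSpecies.from_formula("hydrogen", "H2"),
            "ammonia": ChemicalSpecies.from_formula("ammonia", "NH3"),
            "water": ChemicalSpecies.from_formula("water", "H2O"),
            "oxygen": ChemicalSpecies.from_formula("oxygen", "O2"),
            product.name: product,
        }
        reactants: dict[str, Fraction] = {"carbon_dioxide": Fraction(c)}
        products: dict[str, Fraction] = {product.name: Fraction(1)}
        if n:
            reactants["ammonia"] = Fraction(n)
        if m > 0:
            reactants["hydrogen"] = m
        if w > 0:
            products["water"] = w
        if q > 0:
            products["oxygen"] = q
        elif q < 0:
            reactants["oxygen"] = -q

        denom = math.lcm(*[f.denominator for f in
                           list(reactants.values()) + list(products.values())])
        return Reaction(
            name=f"synthetic_{counter}",
            reactants={k: float(v * denom) for k, v in reactants.items()},
            products={k: float(v * denom) for k, v in products.items()},
            species=species,
        )

    def generate_mission(self, counter: int = 0
                         ) -> tuple[MissionProfile, dict[str, WasteStream]]:
        """A random mission profile with formula-consistent waste streams."""
        rng = self._rng(counter)
        c_lo, c_hi = self.config.ranges["crew"]
        d_lo, d_hi = self.config.ranges["duration_days"]
        profile = MissionProfile(
            name=f"synthetic_{counter}",
            crew=int(rng.integers(int(c_lo), int(c_hi) + 1)),
            outbound_days=float(rng.uniform(d_lo, d_hi)),
            residence_days=float(rng.uniform(d_lo, d_hi)),
            return_days=float(rng.uniform(d_lo, d_hi)),
        )
        r_lo, r_hi = self.config.ranges["waste_rate_kg_crew_day"]
        streams: dict[str, WasteStream] = {}
        element_names = {"C": "carbon", "H": "hydrogen", "O": "oxygen",
                         "N": "nitrogen"}
        for name, formula in (("carbon_dioxide", "CO2"), ("water", "H2O"),
                              ("ammonia", "NH3")):
            rate = float(rng.uniform(r_lo, r_hi))
            sp = ChemicalSpecies.from_formula(name, formula)
            comps = {
                element_names[el]: rate * cnt * ATOMIC_WEIGHTS[el] / sp.molar_mass
                for el, cnt in sp.element_counts.items()
            }
            streams[name] = WasteStream(name, rate, comps, formula)
        return profile, streams
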