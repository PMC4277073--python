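"""End-to-end bioproduction scenarios and their cost comparisons.

Each scenario combines a mission's resource budget, an organism's
volumetric productivity, bioreactor sizing from the catalog and a
non-biological baseline into a single ScenarioResult:

* methane_scenario — CH4 (with O2 co-product) for ascent propellant, fed
  by atmospheric CO2 (electrolyser-limited), by excavated crater-ejecta
  CO2, or by crew respiration CO2 in transit;
* food_scenario — dehydrated cyanobacterial biomass against wet-food
  menus;
* phb_scenario — polyhydroxybutyrate printer feedstock against shipped
  dry salts for regolith-based printing;
* pharma_scenario — on-demand acetaminophen at a carbon-equivalent
  productivity transferred from an engineered-ethylene chassis.

Durations are carried raw and rounded to the nearest whole day; assigned
working volumes are rounded up to the next whole litre. Published organism
productivities (204.1, 492.8, 1.0, 37.2 g/L/day) are used as stated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import baselines as bl
from . import bioreactor_catalog as brc
from . import mission_resources as mr
from . import stoichiometry as st

__all__ = [
    "OrganismSpec",
    "ScenarioResult",
    "ORGANISMS",
    "methane_scenario",
    "food_scenario",
    "phb_scenario",
    "pharma_scenario",
    "savings",
    "report",
]

CO2_SOURCES = ("atmosphere_unlimited", "excavator", "crew_waste")


@dataclass(frozen=True)
class OrganismSpec:
    """A production organism: product species and volumetric productivity."""

    name: str
    product: str                       # species name in the registry
    volumetric_productivity: float     # g/L/day
    offgas_purity: float | None = None      # %
    net_h2_per_mol_product: float | None = None  # post-recycle H2 coefficient

    def __post_init__(self) -> None:
        if self.volumetric_productivity <= 0:
            raise ValueError("productivity must be positive")
        if self.offgas_purity is not None and not 0 < self.offgas_purity <= 100:
            raise ValueError("offgas purity must be in (0, 100]")


ORGANISMS: dict[str, OrganismSpec] = {
    # published top volumetric productivities, as reported
    "m_thermoautotrophicum": OrganismSpec(
        "Methanobacterium thermoautotrophicum (Marburg)", "methane", 204.1,
        offgas_purity=96.0, net_h2_per_mol_product=2.0),
    "methanobacterium_kn15": OrganismSpec(
        "Methanobacterium strain KN-15", "methane", 492.8,
        offgas_purity=18.3, net_h2_per_mol_product=2.0),
    "spirulina": OrganismSpec(
        "Arthrospira platensis / maxima (Spirulina)", "biomass_placeholder", 1.0),
    "c_necator": OrganismSpec(
        "Cupriavidus necator H16", "phb_monomer", 37.2,
        net_h2_per_mol_product=3.0),
}


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome of one production scenario on one mission."""

    scenario: str
    product: str
    product_mass_required: float        # kg
    daily_rate: float                   # kg/day
    duration_raw: float                 # days, unrounded
    duration_days: int                  # nearest whole day
    working_volume_l: float             # raw sized working volume
    shipped_mass_bio: float             # kg
    power_w: float
    skid_volume_m3: float | None
    baselines: dict[str, float] = field(default_factory=dict)   # label -> kg
    savings_pct: dict[str, float] = field(default_factory=dict)  # label -> %
    residence_fraction: float | None = None  # % of residence time
    coverage_pct: float | None = None   # % of the requirement met in-window
    feasible: bool = True
    notes: str = ""


def savings(bio_mass: float, baseline_mass: float) -> float:
    """Shipped-mass saving (%) of the biological option over a baseline."""
    if baseline_mass <= 0:
        raise ValueError("baseline mass must be positive")
    return 100.0 * (baseline_mass - bio_mass) / baseline_mass


def _round_days(raw: float) -> int:
    return int(math.floor(raw + 0.5))


def _single_vessel(catalog: brc.Catalog, working_volume: int,
                   nominal_volume_l: float | None) -> brc.ReactorSpec:
    """The vessel housing a working volume: an explicit (possibly
    interpolated) nominal size, else the smallest covering catalog row."""
    if nominal_volume_l is not None:
        for spec in catalog:
            if spec.max_working_volume == nominal_volume_l:
                return spec
        return catalog.vessel_at(nominal_volume_l)
    for spec in catalog:
        if spec.max_working_volume >= working_volume:
            return spec
    raise ValueError(
        f"no catalog vessel can hold {working_volume} L; largest is "
        f"{catalog.specs[-1].max_working_volume} L"
    )


def methane_scenario(mission: mr.MissionProfile,
                     organism: OrganismSpec,
                     electrolyser: st.ElectrolyserSpec,
                     ch4_target_kg: float | None,
                     co2_source: str,
                     catalog: brc.Catalog,
                     *,
                     excavator: mr.ExcavatorModel | None = None,
                     inventory: mr.EnvironmentInventory | None = None,
                     crew_co2_stream: mr.WasteStream | None = None,
                     vessel_nominal_l: float | None = None,
                     n_electrolysers: int = 1,
                     plant_mass_kg: float = 0.0,
                     baseline: bl.BaselineCost | None = None) -> ScenarioResult:
    """Methanogenic CH4 production sized against its limiting feedstock.

    atmosphere_unlimited: CO2 is free (Mars atmosphere); the daily rate is
    hydrogen-limited by the electrolyser through the post-recycle net H2
    coefficient. excavator: CO2-limited by one excavator working the given
    inventory. crew_waste: CO2-limited by crew respiration; when no target
    is given the product accumulates over the outbound leg.
    """
    if co2_source not in CO2_SOURCES:
        raise ValueError(f"unknown CO2 source {co2_source!r}; valid: {CO2_SOURCES}")
    if ch4_target_kg is not None and ch4_target_kg < 0:
        raise ValueError("CH4 target must be non-negative")

    ch4 = st.SPECIES["methane"]
    reactions = st.load_reactions()
    methanogenesis = reactions["methanogenesis"]
    notes = []

    if co2_source == "atmosphere_unlimited":
        h2_kg_day = st.electrolyser_h2_rate(electrolyser)
        net = organism.net_h2_per_mol_product or 2.0
        mol_ch4 = h2_kg_day * 1000.0 / st.M_H2 / net
        rate = mol_ch4 * ch4.molar_mass / 1000.0
        notes.append(f"electrolyser-limited at {h2_kg_day:.3f} kg H2/day")
    elif co2_source == "excavator":
        if excavator is None or inventory is None:
            raise ValueError("excavator source needs an excavator and an inventory")
        co2_rate = mr.excavator_extraction_rate(excavator, inventory,
                                                "carbon_dioxide")
        rate = st.mass_yield(methanogenesis, "carbon_dioxide", co2_rate, "methane")
        notes.append(f"CO2-limited at {co2_rate:.2f} kg/day from one excavator")
    else:  # crew_waste
        stream = crew_co2_stream or mr.load_waste_streams()["carbon_dioxide"]
        co2_rate = stream.rate * mission.crew
        rate = st.mass_yield(methanogenesis, "carbon_dioxide", co2_rate, "methane")
        notes.append(f"CO2-limited at {co2_rate:.2f} kg/day from crew respiration")

    wv = brc.size_working_volume(rate, organism.volumetric_productivity)
    vessel = _single_vessel(catalog, wv.whole, vessel_nominal_l)
    fleet = brc.ReactorFleet(units=((vessel, float(wv.whole)),))
    mass, power_w, skid = brc.fleet_totals(fleet)
    shipped = mass + n_electrolysers * electrolyser.unit_mass_kg + plant_mass_kg

    in_transit = co2_source == "crew_waste"
    if ch4_target_kg is None:
        window = mission.outbound_days if in_transit else mission.residence_days
        duration_raw = window
        produced = rate * window
    else:
        duration_raw = ch4_target_kg / rate if rate > 0 else 0.0
        produced = ch4_target_kg
    duration = _round_days(duration_raw)

    res_frac = None
    if not in_transit and mission.residence_days > 0:
        res_frac = 100.0 * duration / mission.residence_days

    result_baselines = {}
    result_savings = {}
    if baseline is not None:
        result_baselines[baseline.scenario] = baseline.shipped_mass
        result_savings[baseline.scenario] = savings(shipped, baseline.shipped_mass)

    return ScenarioResult(
        scenario=f"methane_{mission.name}_{co2_source}",
        product="methane",
        product_mass_required=produced,
        daily_rate=rate,
        duration_raw=duration_raw,
        duration_days=duration,
        working_volume_l=wv.raw,
        shipped_mass_bio=shipped,
        power_w=power_w,
        skid_volume_m3=skid,
        baselines=result_baselines,
        savings_pct=result_savings,
        residence_fraction=res_frac,
        notes="; ".join(notes),
    )


def food_scenario(mission: mr.MissionProfile,
                  catalog: brc.Catalog,
                  organism: OrganismSpec | None = None,
                  *,
                  fleet: brc.ReactorFleet | None = None,
                  mass_budget_kg: float | None = None,
                  dry_rate_kg_crew_day: float = 0.617) -> ScenarioResult:
    """Dehydrated biomass for the residence-plus-return diet, produced
    during residence, against both wet-food menus.

    By default the fleet is cover-optimal for the full requirement; a fixed
    fleet or an empty-mass budget can be imposed instead, in which case the
    result reports partial coverage.
    """
    organism = organism or ORGANISMS["spirulina"]
    requirement = bl.dry_biomass_requirement(
        mission.crew, mission.residence_days + mission.return_days,
        dry_rate_kg_crew_day)
    window = mission.residence_days
    required_rate = requirement / window if window > 0 else 0.0
    wv = brc.size_working_volume(required_rate, organism.volumetric_productivity)

    if fleet is None:
        if mass_budget_kg is not None:
            fleet = brc.select_fleet_budget(catalog, mass_budget_kg)
        else:
            fleet = brc.select_fleet_cover(catalog, wv.raw)
    mass, power_w, skid = brc.fleet_totals(fleet)

    daily = fleet.total_assigned * organism.volumetric_productivity / 1000.0
    produced = min(daily * window, requirement) if requirement > 0 else 0.0
    coverage = 100.0 * produced / requirement if requirement > 0 else 100.0
    duration_raw = requirement / daily if daily > 0 else 0.0

    plans = bl.food_plans()
    result_baselines = {
        menu: bl.wet_food_shipped(plan, mission.crew,
                                  mission.residence_days + mission.return_days)
        for menu, plan in plans.items()
    }
    result_savings = {menu: savings(mass, base)
                      for menu, base in result_baselines.items()}

    return ScenarioResult(
        scenario=f"food_{mission.name}",
        product="spirulina_biomass",
        product_mass_required=requirement,
        daily_rate=daily,
        duration_raw=duration_raw,
        duration_days=_round_days(min(duration_raw, window)),
        working_volume_l=wv.raw,
        shipped_mass_bio=mass,
        power_w=power_w,
        skid_volume_m3=skid,
        baselines=result_baselines,
        savings_pct=result_savings,
        residence_fraction=(100.0 * min(duration_raw, window) / window
                            if window > 0 else None),
        coverage_pct=coverage,
        feasible=coverage >= 100.0 - 1e-9,
        notes=f"coverage {coverage:.1f}% of requirement over {window:g} d residence",
    )


def phb_scenario(mission: mr.MissionProfile,
                 catalog: brc.Catalog,
                 volume_per_person_m3: float = 20.0,
                 organism: OrganismSpec | None = None,
                 *,
                 fleet: brc.ReactorFleet | None = None,
                 electrolyser: st.ElectrolyserSpec | None = None,
                 habitat: bl.HabitatReference | None = None,
                 plant_mass_kg: float | None = None,
                 phb_density_kg_m3: float = 1250.0) -> ScenarioResult:
    """PHB printer feedstock for a printed habitat, against dry salts.

    The habitat structure volume follows from the linear habitat-cost
    scaling; its PHB mass at 1250 kg/m3 is produced by a fixed fleet
    (default two 2000 L vessels at 1500 L each). Make-up hydrogen uses the
    post-recycle coefficient of 3 H2 per monomer and must fit within one
    electrolyser.
    """
    organism = organism or ORGANISMS["c_necator"]
    habitat = habitat or bl.habitat_reference()
    electrolyser = electrolyser or st.ElectrolyserSpec(
        unit_mass_kg=6.0, water_flow_g_per_h=2998.0)
    if plant_mass_kg is None:
        plant_mass_kg = bl.load_baselines()["plants"]["soil_processing_plant_kg"]

    total_t, salts_t, structure_m3 = bl.habitat_costs(
        habitat, mission.crew, volume_per_person_m3)
    phb_mass = structure_m3 * phb_density_kg_m3

    if fleet is None:
        big = catalog.specs[-1]
        fleet = brc.ReactorFleet(units=((big, 1500.0), (big, 1500.0)))
    mass, power_w, skid = brc.fleet_totals(fleet)
    daily = fleet.total_assigned * organism.volumetric_productivity / 1000.0

    duration_raw = phb_mass / daily if daily > 0 else 0.0
    duration = _round_days(duration_raw)

    phb = st.SPECIES[organism.product]
    h2_demand = st.net_h2_demand(phb, daily,
                                 organism.net_h2_per_mol_product or 3.0)
    h2_capacity = st.electrolyser_h2_rate(electrolyser)
    feasible = h2_demand <= h2_capacity + 1e-9
    notes = (f"H2 make-up {h2_demand:.2f} kg/day vs electrolyser capacity "
             f"{h2_capacity:.2f} kg/day")
    if not feasible:
        notes += " — EXCEEDS single-electrolyser capacity"

    # the 6 kg electrolyser is part of the soil-processing plant line item
    shipped = mass + plant_mass_kg
    result_baselines = {"dry_salts": salts_t * 1000.0, "total": total_t * 1000.0}
    result_savings = {}
    if salts_t > 0:
        result_savings["dry_salts"] = savings(mass, salts_t * 1000.0)
        result_savings["total"] = savings(shipped, total_t * 1000.0)

    res_frac = (100.0 * duration / mission.residence_days
                if mission.residence_days > 0 else None)
    wv = brc.size_working_volume(daily, organism.volumetric_productivity)

    return ScenarioResult(
        scenario=f"phb_{mission.name}",
        product="phb",
        product_mass_required=phb_mass,
        daily_rate=daily,
        duration_raw=duration_raw,
        duration_days=duration,
        working_volume_l=wv.raw,
        shipped_mass_bio=shipped,
        power_w=power_w,
        skid_volume_m3=skid,
        baselines=result_baselines,
        savings_pct=result_savings,
        residence_fraction=res_frac,
        feasible=feasible,
        notes=notes,
    )


def pharma_scenario(dose_mg: float = 325.0,
                    stock_tablets: int = 100,
                    working_volume_l: float = 2.0,
                    ethylene_rate_mmol_l_day: float = 6.0) -> ScenarioResult:
    """On-demand acetaminophen at the carbon-equivalent molar productivity
    of the engineered-ethylene chassis (same organism, same gene-insertion
    count)."""
    if stock_tablets < 0 or dose_mg < 0:
        raise ValueError("dose and stock must be non-negative")
    ethylene = st.SPECIES["ethylene"]
    apap = st.SPECIES["acetaminophen"]
    molar_rate = st.carbon_equivalent_rate(ethylene_rate_mmol_l_day, ethylene, apap)
    mg_per_l_day = molar_rate * apap.molar_mass
    daily_mg = mg_per_l_day * working_volume_l
    need_mg = dose_mg * stock_tablets
    duration_raw = need_mg / daily_mg if need_mg > 0 else 0.0
    power_mw = bl.load_baselines()["pharma"]["small_vessel_power_mw"]

    return ScenarioResult(
        scenario="pharma_acetaminophen",
        product="acetaminophen",
        product_mass_required=need_mg / 1e6,
        daily_rate=daily_mg / 1e6,
        duration_raw=duration_raw,
        duration_days=math.ceil(duration_raw),
        working_volume_l=working_volume_l,
        shipped_mass_bio=0.0,
        power_w=power_mw / 1000.0,
        skid_volume_m3=None,
        notes=(f"carbon-equivalent rate {molar_rate:g} mmol/L/day "
               f"({mg_per_l_day:.1f} mg/L/day); power is a cited small-vessel "
               "constant, not computed from the catalog"),
    )


_REPORT_COLUMNS = ["scenario", "product", "axis", "bio_value", "baseline_label",
                   "baseline_value", "savings_pct"]


def report(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long-format comparison table: one row per scenario per cost axis."""
    rows = []
    for r in results:
        base_label = next(iter(r.baselines), None)
        axes = {
            "shipped_mass_kg": r.shipped_mass_bio,
            "power_w": r.power_w,
            "skid_volume_m3": r.skid_volume_m3,
            "duration_days": r.duration_days,
        }
        for axis, value in axes.items():
            rows.append({
                "scenario": r.scenario,
                "product": r.product,
                "axis": axis,
                "bio_value": value,
                "baseline_label": base_label if axis == "shipped_mass_kg" else None,
                "baseline_value": (r.baselines.get(base_label)
                                   if axis == "shipped_mass_kg" else None),
                "savings_pct": (r.savings_pct.get(base_label)
                                if axis == "shipped_mass_kg" else None),
            })
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)
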