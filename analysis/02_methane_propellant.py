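#!/usr/bin/env python
"""Methane-oxygen propellant bioproduction scenarios.

Three feedstock routes: Mars atmospheric CO2 (hydrogen-limited by the
electrolyser), lunar crater-ejecta CO2 from one scaled excavator, and crew
respiration CO2 in transit. Writes results/methane_scenarios.csv.
"""

import warnings
from pathlib import Path

from bioisru import bioreactor_catalog as brc
from bioisru import mission_resources as mr
from bioisru import production_scenarios as ps
from bioisru import stoichiometry as st

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    warnings.simplefilter("ignore", UserWarning)
    catalog = brc.load_catalog()
    organism = ps.ORGANISMS["m_thermoautotrophicum"]
    inv = mr.load_environment_inventories()["moon_crater_ejecta"]

    mars = ps.methane_scenario(
        mr.MARS_MISSION, organism, st.ElectrolyserSpec(6, 2998), 6570,
        "atmosphere_unlimited", catalog)
    moon = ps.methane_scenario(
        mr.MOON_MISSION, organism, st.ElectrolyserSpec(), 2168, "excavator",
        catalog, excavator=mr.ExcavatorModel(mass=108), inventory=inv,
        vessel_nominal_l=100, n_electrolysers=2)
    transit = ps.methane_scenario(
        mr.MARS_MISSION, organism, st.ElectrolyserSpec(), None, "crew_waste",
        catalog)

    results = [mars, moon, transit]
    ps.report(results).to_csv(OUT / "methane_scenarios.csv", index=False)

    print(f"Mars surface: {mars.daily_rate:.2f} kg CH4/day "
          f"({mars.notes}); {mars.working_volume_l:.0f} L working volume, "
          f"{mars.power_w * 1000:.1f} mW, campaign {mars.duration_days} d "
          f"({mars.residence_fraction:.0f}% of residence).")
    print(f"Moon surface: {moon.daily_rate:.2f} kg CH4/day from one 108 kg "
          f"excavator; 70 L culture in an interpolated 100 L vessel "
          f"({moon.power_w * 1000:.1f} mW, {moon.skid_volume_m3:.3f} m3); "
          f"campaign {moon.duration_days} d.")
    print(f"Mars transit: {transit.daily_rate:.2f} kg CH4/day from crew CO2 "
          f"gives {transit.product_mass_required:.0f} kg over the "
          f"{transit.duration_days} d outbound leg; emergency option ships "
          f"{transit.shipped_mass_bio:.0f} kg.")


if __name__ == "__main__":
    main()
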