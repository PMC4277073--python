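#!/usr/bin/env python
"""Combined comparison of all four bioproduction scenarios against their
non-biological baselines, plus the resource-to-product mapping table.

Writes results/summary.csv and results/mapping.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from bioisru import bioreactor_catalog as brc
from bioisru import mission_resources as mr
from bioisru import production_scenarios as ps
from bioisru import stoichiometry as st

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

MAPPING = [
    ("CO2 + H2", "Methanobacterium thermoautotrophicum", "CH4-O2 propellant"),
    ("CO2 + H2 + N2", "Arthrospira platensis / maxima", "Spirulina food"),
    ("CO2 + H2 + N2 + O2", "Cupriavidus necator", "PHB biopolymer"),
    ("CO2 + H2 + N2", "engineered Synechocystis sp. PCC 6803",
     "acetaminophen pharmaceutical"),
]


def main() -> None:
    warnings.simplefilter("ignore", UserWarning)
    catalog = brc.load_catalog()
    inv = mr.load_environment_inventories()["moon_crater_ejecta"]
    organism = ps.ORGANISMS["m_thermoautotrophicum"]

    results = [
        ps.methane_scenario(mr.MARS_MISSION, organism,
                            st.ElectrolyserSpec(6, 2998), 6570,
                            "atmosphere_unlimited", catalog),
        ps.methane_scenario(mr.MOON_MISSION, organism, st.ElectrolyserSpec(),
                            2168, "excavator", catalog,
                            excavator=mr.ExcavatorModel(mass=108),
                            inventory=inv, vessel_nominal_l=100,
                            n_electrolysers=2),
        ps.food_scenario(mr.MARS_MISSION, catalog),
        ps.phb_scenario(mr.MARS_MISSION, catalog),
        ps.phb_scenario(mr.MOON_MISSION, catalog),
        ps.pharma_scenario(),
    ]
    ps.report(results).to_csv(OUT / "summary.csv", index=False)
    pd.DataFrame(MAPPING, columns=["inputs", "organism", "output"]).to_csv(
        OUT / "mapping.csv", index=False)

    print("Scenario durations and headline savings:")
    for r in results:
        line = (f"  {r.scenario:35s} {r.duration_days:4d} d   "
                f"shipped {r.shipped_mass_bio:7.0f} kg")
        if r.savings_pct:
            line += f"   best saving {max(r.savings_pct.values()):5.1f}%"
        print(line)


if __name__ == "__main__":
    main()
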