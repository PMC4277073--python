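#!/usr/bin/env python
"""Regenerate the crew-waste resource budgets for the Mars and Moon
missions from per-crew-day rates, plus the excavator-extraction rates for
lunar crater-ejecta CO2.

Writes results/mission_budgets.csv and results/extraction_rates.csv.
"""

from pathlib import Path

import pandas as pd

from bioisru import mission_resources as mr

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    streams = mr.load_waste_streams()
    rows = []
    for mission in (mr.MARS_MISSION, mr.MOON_MISSION):
        for name, stream in streams.items():
            for phase in ("outbound", "residence", "return"):
                total = mr.waste_budget(mission, stream, phase)
                rows.append({"mission": mission.name, "stream": name,
                             "phase": phase, "component": "total",
                             "mass_kg": round(total, 2)})
                for comp in stream.component_rates:
                    rows.append({
                        "mission": mission.name, "stream": name, "phase": phase,
                        "component": comp,
                        "mass_kg": round(mr.elemental_content(total, stream, comp), 2),
                    })
    budgets = pd.DataFrame(rows)
    budgets.to_csv(OUT / "mission_budgets.csv", index=False)

    inv = mr.load_environment_inventories()["moon_crater_ejecta"]
    ex_rows = []
    for mass in (80, 108):
        ex = mr.ExcavatorModel(mass=mass)
        ex_rows.append({
            "excavator_mass_kg": mass,
            "regolith_kg_per_day": ex.regolith_per_day,
            "co2_kg_per_day": mr.excavator_extraction_rate(ex, inv,
                                                           "carbon_dioxide"),
        })
    pd.DataFrame(ex_rows).to_csv(OUT / "extraction_rates.csv", index=False)

    mars_co2 = budgets.query(
        "mission=='mars' and stream=='carbon_dioxide' and component=='total'")
    print("Crew CO2 budgets, Mars (kg):")
    print(mars_co2[["phase", "mass_kg"]].to_string(index=False))
    print("\nOne 80 kg excavator recovers "
          f"{ex_rows[0]['co2_kg_per_day']:.1f} kg CO2/day from crater ejecta; "
          f"a scaled 108 kg machine {ex_rows[1]['co2_kg_per_day']:.2f} kg/day.")


if __name__ == "__main__":
    main()
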