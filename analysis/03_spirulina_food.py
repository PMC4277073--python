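#!/usr/bin/env python
"""Cyanobacterial food production against wet-food shipping baselines.

Mars: full dehydrated-biomass coverage from a cover-optimal fleet.
Moon: a single large vessel (partial coverage) and the break-even
empty-mass budget. Writes results/food_scenarios.csv.
"""

import warnings
from pathlib import Path

from bioisru import bioreactor_catalog as brc
from bioisru import mission_resources as mr
from bioisru import production_scenarios as ps

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    warnings.simplefilter("ignore", UserWarning)
    catalog = brc.load_catalog()

    mars = ps.food_scenario(mr.MARS_MISSION, catalog)
    big = catalog.specs[-1]
    moon_single = ps.food_scenario(mr.MOON_MISSION, catalog,
                                   fleet=brc.ReactorFleet(((big, 2000.0),)))
    moon_budget = ps.food_scenario(mr.MOON_MISSION, catalog, mass_budget_kg=667)
    moon_full = ps.food_scenario(mr.MOON_MISSION, catalog)

    results = [mars, moon_single, moon_budget, moon_full]
    ps.report(results).to_csv(OUT / "food_scenarios.csv", index=False)

    print(f"Mars: {mars.product_mass_required:.0f} kg dehydrated biomass over "
          f"{mars.duration_days} d at {mars.daily_rate:.3f} kg/day; fleet "
          f"{mars.shipped_mass_bio:.0f} kg saves "
          f"{mars.savings_pct['vegetarian']:.0f}% vs vegetarian and "
          f"{mars.savings_pct['mixed']:.0f}% vs mixed wet food "
          f"({mars.power_w:.3f} W, {mars.skid_volume_m3:.3f} m3).")
    print(f"Moon, one 2000 L vessel: covers {moon_single.coverage_pct:.0f}% of "
          f"the requirement; wet-food baselines are "
          f"{moon_single.baselines['vegetarian']:.0f}-"
          f"{moon_single.baselines['mixed']:.0f} kg.")
    print(f"Moon, break-even 667 kg budget: fleet of "
          f"{moon_budget.shipped_mass_bio:.0f} kg covers "
          f"{moon_budget.coverage_pct:.0f}%.")
    print(f"Moon, 100% coverage: fleet mass {moon_full.shipped_mass_bio:.0f} kg "
          "— exceeds the wet-food baselines, so full lunar coverage does not "
          "pay off at current productivity.")


if __name__ == "__main__":
    main()
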