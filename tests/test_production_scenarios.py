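"""End-to-end production scenarios against their printed anchors."""

import warnings

import pytest

from bioisru import baselines as bl
from bioisru import bioreactor_catalog as brc
from bioisru import mission_resources as mr
from bioisru import production_scenarios as ps
from bioisru import stoichiometry as st

MT = ps.ORGANISMS["m_thermoautotrophicum"]


@pytest.fixture(autouse=True)
def _quiet_underfill():
    # several published fleets deliberately run vessels under-filled
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


class TestMethaneScenarios:
    def test_mars_electrolyser_limited(self, catalog):
        r = ps.methane_scenario(
            mr.MARS_MISSION, MT, st.ElectrolyserSpec(6, 2998), 6570,
            "atmosphere_unlimited", catalog)
        assert r.daily_rate == pytest.approx(32.0, abs=0.1)
        assert round(r.working_volume_l) == 157
        assert r.duration_days == 205
        assert r.power_w * 1000 == pytest.approx(938.5, rel=0.005)
        assert r.skid_volume_m3 == pytest.approx(1.553)
        assert round(r.residence_fraction) == 41

    def test_moon_excavator(self, catalog, inventories):
        r = ps.methane_scenario(
            mr.MOON_MISSION, MT, st.ElectrolyserSpec(), 2168, "excavator",
            catalog, excavator=mr.ExcavatorModel(mass=108),
            inventory=inventories["moon_crater_ejecta"],
            vessel_nominal_l=100, n_electrolysers=2)
        assert r.daily_rate == pytest.approx(14.17, abs=0.01)
        assert r.working_volume_l == pytest.approx(69.4, abs=0.1)
        assert r.duration_days == 153
        assert r.power_w * 1000 == pytest.approx(497.2, abs=0.5)
        assert r.skid_volume_m3 == pytest.approx(0.991, abs=5e-4)

    def test_mars_transit_crew_co2(self, catalog):
        r = ps.methane_scenario(
            mr.MARS_MISSION, MT, st.ElectrolyserSpec(), None, "crew_waste",
            catalog)
        assert r.daily_rate == pytest.approx(2.19, abs=0.005)
        assert round(r.product_mass_required) == 459
        assert r.working_volume_l < 11
        assert r.shipped_mass_bio == pytest.approx(171)  # 50 L vessel + unit
        assert r.power_w * 1000 == pytest.approx(84.32, abs=0.01)
        assert r.skid_volume_m3 == pytest.approx(0.710, abs=5e-4)

    def test_residence_co2_methane_total(self, catalog, waste_streams):
        co2 = mr.waste_budget(mr.MARS_MISSION, waste_streams["carbon_dioxide"],
                              "residence")
        ch4 = st.mass_yield(st.load_reactions()["methanogenesis"],
                            "carbon_dioxide", co2, "methane")
        assert round(ch4) == 1085

    def test_zero_target_zero_duration(self, catalog):
        r = ps.methane_scenario(mr.MARS_MISSION, MT, st.ElectrolyserSpec(),
                                0.0, "atmosphere_unlimited", catalog)
        assert r.duration_days == 0

    def test_unknown_source_rejected(self, catalog):
        with pytest.raises(ValueError, match="atmosphere_unlimited"):
            ps.methane_scenario(mr.MARS_MISSION, MT, st.ElectrolyserSpec(),
                                1.0, "magic", catalog)


class TestFoodScenarios:
    def test_mars_full_coverage(self, catalog):
        r = ps.food_scenario(mr.MARS_MISSION, catalog)
        assert round(r.product_mass_required) == 2614
        assert r.daily_rate == pytest.approx(5.271, abs=5e-4)
        assert r.shipped_mass_bio == pytest.approx(2382)
        assert round(r.savings_pct["vegetarian"]) == 32
        assert round(r.savings_pct["mixed"]) == 38
        assert r.power_w == pytest.approx(12.687, abs=5e-4)
        assert r.skid_volume_m3 == pytest.approx(14.844, abs=5e-4)
        assert r.feasible

    def test_moon_single_vessel_partial_coverage(self, catalog):
        big = catalog.specs[-1]
        r = ps.food_scenario(mr.MOON_MISSION, catalog,
                             fleet=brc.ReactorFleet(((big, 2000.0),)))
        assert r.daily_rate == pytest.approx(2.0)
        assert round(r.coverage_pct) == 79
        assert not r.feasible

    def test_moon_break_even_budget(self, catalog):
        r = ps.food_scenario(mr.MOON_MISSION, catalog, mass_budget_kg=667)
        assert r.shipped_mass_bio == pytest.approx(611)
        assert round(r.coverage_pct) == 42

    def test_zero_requirement_full_coverage(self, catalog):
        mission = mr.MissionProfile("depot", 2, 10, 30, 10)
        r = ps.food_scenario(mission, catalog, dry_rate_kg_crew_day=0.0)
        assert r.product_mass_required == 0.0
        assert r.coverage_pct == 100.0


class TestPhbScenarios:
    def test_mars_habitat(self, catalog):
        r = ps.phb_scenario(mr.MARS_MISSION, catalog)
        assert r.product_mass_required == pytest.approx(22500)
        assert r.daily_rate == pytest.approx(111.6)
        assert r.duration_days == 202
        assert r.shipped_mass_bio == pytest.approx(3416)
        assert round(r.savings_pct["dry_salts"]) == 86
        assert r.savings_pct["total"] == pytest.approx(85.8, abs=0.1)
        assert round(r.residence_fraction) == 41
        assert r.feasible  # 7.84 kg/day H2 within one electrolyser
        assert r.power_w == pytest.approx(7.221, abs=5e-4)
        assert r.skid_volume_m3 == pytest.approx(9.896, abs=5e-4)

    def test_moon_habitat(self, catalog):
        r = ps.phb_scenario(mr.MOON_MISSION, catalog)
        assert r.product_mass_required == pytest.approx(15000)
        assert r.duration_days == 134
        assert round(r.residence_fraction) == 74
        assert round(r.savings_pct["dry_salts"]) == 79

    def test_zero_structure(self, catalog):
        r = ps.phb_scenario(mr.MARS_MISSION, catalog, volume_per_person_m3=0.0)
        assert r.product_mass_required == 0.0
        assert r.duration_days == 0

    def test_h2_demand_above_capacity_flagged(self, catalog):
        r = ps.phb_scenario(mr.MARS_MISSION, catalog,
                            electrolyser=st.ElectrolyserSpec(6, 1000))
        assert not r.feasible
        assert "EXCEEDS" in r.notes


class TestPharmaScenario:
    def test_replenish_100_tablets(self):
        r = ps.pharma_scenario(dose_mg=325, stock_tablets=100,
                               working_volume_l=2.0)
        assert r.duration_days == 72
        assert "1.5 mmol/L/day" in r.notes

    def test_carbon_equivalent_molar_rate(self):
        got = st.carbon_equivalent_rate(6, st.SPECIES["ethylene"],
                                        st.SPECIES["acetaminophen"])
        assert got == pytest.approx(1.5)

    def test_zero_stock(self):
        assert ps.pharma_scenario(stock_tablets=0).duration_days == 0


class TestSavings:
    def test_reported_values(self):
        assert ps.savings(3416, 24000) == pytest.approx(85.8, abs=0.1)
        assert round(ps.savings(1588, 11400)) == 86

    def test_equal_masses_zero_saving(self):
        assert ps.savings(123.0, 123.0) == 0.0

    def test_bounds(self):
        assert ps.savings(0.0, 10.0) == 100.0
        assert ps.savings(5.0, 10.0) < 100.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ps.savings(1.0, 0.0)


def test_duration_weakly_decreases_with_productivity(catalog):
    """With a fixed fleet, a faster organism never lengthens the campaign."""
    durations = []
    for prod in (5.0, 20.0, 37.2, 80.0, 200.0):
        org = ps.OrganismSpec("x", "phb_monomer", prod,
                              net_h2_per_mol_product=3.0)
        r = ps.phb_scenario(mr.MARS_MISSION, catalog, organism=org)
        durations.append(r.duration_raw)
    assert all(b <= a + 1e-9 for a, b in zip(durations, durations[1:]))


class TestReport:
    def test_empty_list_gives_headered_empty_table(self):
        df = ps.report([])
        assert df.empty
        assert list(df.columns) == ps._REPORT_COLUMNS

    def test_mars_food_row(self, catalog):
        df = ps.report([ps.food_scenario(mr.MARS_MISSION, catalog)])
        mass_row = df[df.axis == "shipped_mass_kg"].iloc[0]
        assert mass_row.bio_value == pytest.approx(2382)
        assert round(mass_row.savings_pct) in (32, 38)
        assert set(df.axis) == {"shipped_mass_kg", "power_w", "skid_volume_m3",
                                "duration_days"}

    def test_one_row_per_scenario_per_axis(self, catalog, inventories):
        results = [
            ps.food_scenario(mr.MARS_MISSION, catalog),
            ps.phb_scenario(mr.MARS_MISSION, catalog),
            ps.pharma_scenario(),
        ]
        df = ps.report(results)
        assert len(df) == 4 * len(results)
        assert df.scenario.nunique() == len(results)
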