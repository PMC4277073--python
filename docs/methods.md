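# Methods

`bioisru` is a deterministic trade-study model: it maps the resource
inventories of two reference crewed missions through stoichiometric
bioproduction and bioreactor-sizing calculations to shipped-mass, power,
volume and duration costs for four biological products, and compares those
costs with non-biological baselines. There is no fitting or simulation in
the statistical sense; every result is a closed-form chain of mass
balances, linear scalings and small discrete optimisations, which is why
the test-suite can pin almost every headline number exactly.

## Missions and resource budgets

Two missions are hard-wired as defaults and overridable via config:

* Mars: 6 crew, 210 d outbound, 496 d residence, 210 d return;
* Moon: 4 crew, 3.5 d outbound, 180 d residence, 3.5 d return.

Crew waste streams accumulate at fixed per-crew-day rates (CO2 1.0,
urine water 1.5, non-recycled hygiene water 2.37 kg/crew/day) with
component sub-rates (carbon 0.273, oxygen 0.727 of CO2, etc.). A budget is
always rate × crew × phase-days, so budgets are exactly linear in crew and
duration — a property test, not just a unit test. Component fractions of
formula-pure streams are validated against the formula's elemental
composition within 1% at construction.

The packaged waste-rate table stores the *rates*; phase totals are always
recomputed. A few cells of the source table render garbled in transcription
(they fuse adjacent columns); the CSV carries a provenance note on each
affected component and the recomputed value is used throughout.

Environmental inventories (Mars atmosphere, lunar shadowed-crater ejecta
plume, soils/regolith) are weight-percent tables. The excavator model
scales a reference machine (80 kg moving 500 kg regolith per 0.5 h)
linearly in machine mass — an explicit model assumption — and assumes
complete extraction of the target compound from the moved regolith, so one
80 kg machine yields 28.8 kg CO2/day from 0.12 wt% crater ejecta and a
108 kg machine 38.88 kg/day.

## Chemistry

Molar masses come from an in-package table of conventional IUPAC atomic
weights plus a small formula parser; the tests cross-check the weight table
against rdkit's periodic table. Two deliberate species choices matter:

* acetate is carried as the ion C2H3O2 (59.04 g/mol), which is what
  reproduces the reported 27.3 mol acetate per 100 mol H2;
* PHB is carried as its repeating unit C4H6O2 (86.09 g/mol) with a *net*
  post-recycle make-up coefficient of 3 H2 per monomer, which reproduces
  the 7.84 kg/day hydrogen demand at 111.6 kg/day of polymer.

Reactions are validated at load: exact element conservation and mass
closure within 0.05%. The methanogenesis net form assumes both product
waters are electrolysed back (2 net H2 per CH4, with the O2 credit from
the electrolyser); the PHB net form is 3 H2 + 4 CO2 → C4H6O2 + 3 O2.

Dissolved-gas supply is Henry's-law equilibrium on the sparged stream:
H·p mmol per litre of gas, times flow and 24 h. For the reported
acetogenesis experiment (15 L/h, 1.7 bar H2, H = 0.749 mmol/L/bar, 1 L
working volume, 7.4 g/L/day acetate) this gives 0.4584 mol H2/day and a
27.3 mol/100 mol yield.

Electrolyser hydrogen output is the hydrogen mass fraction of water times
the daily water throughput. A 6 kg unit at its rated 3000 g/h makes
8.06 kg H2/day; at the 2998 g/h operating point used in the propellant
design, 8.05 kg/day. (A published figure of 8.14 kg/day at 2998 g/h is not
reproducible by this mass balance; the computed value is used and the
discrepancy noted here.)

## Bioreactor catalog, sizing and selection

The catalog is five stirred-tank skids (50–2000 L maximum working volume)
with empty mass, power density (mW/L at 0.02 vvm) and skid volume. Between
rows, properties interpolate linearly in maximum working volume; this
choice exactly reproduces the quoted 497.2 mW and 0.991 m³ for a 70 L
culture in a virtual 100 L vessel. Linear interpolation gives 189.7 kg for
that vessel's empty mass where 193 kg has been quoted elsewhere; no
interpolation scheme of this catalog yields 193, so linear is kept and the
difference treated as a calibration note. The 43.7 mW draw of a 3 L pharma
vessel is below the catalog range and is stored as a cited constant, never
computed.

Working volumes are sized as required daily mass over volumetric
productivity and rounded **up** to the next whole litre (69.4→70,
157.0→157, 10.7→11 all match the quoted values). Within a multi-unit
fleet the requirement is split equally and each share rounded up to a
whole litre, which reproduces three 2000 L vessels at 1757 L (5.271 kg/day
of biomass, 12.687 W, 14.844 m³).

Fleet selection is solved by bounded exhaustive enumeration over reactor
multisets:

* **cover** — minimise unit count first, then total empty mass, then skid
  volume, subject to summed capacity ≥ requirement. Minimising count
  before mass is essential: it selects {2000, 1000} (1240 kg) for the
  lunar requirement and 3 × 2000 (2382 kg) for Mars, whereas pure mass
  minimisation would pick a cheaper four-unit Mars fleet that the
  published design does not use.
* **budget** — maximise summed capacity subject to total empty mass ≤
  budget, tie-broken by minimal mass then fewest units; at the 667 kg
  lunar break-even this yields {1000, 50} = 1050 L at 611 kg.

Both selectors are verified against an independent brute-force oracle
(exhaustive enumeration up to six units) on 200 seeded random catalogs,
and monotonicity (cover mass vs requirement, budget capacity vs budget) is
asserted on sweeps.

A quoted transit design assigns 11 L to a 50 L vessel whose catalog
minimum is 12 L; totals therefore *warn* on under-filled vessels rather
than erroring (over-filling is still an error).

## Scenarios

**Methane.** Three feedstock routes: (i) Mars atmosphere — CO2 free, rate
hydrogen-limited through the net 2 H2/CH4 coefficient, giving
32.04 kg/day, a 157 L culture in a 200 L vessel (938.5 mW, 1.553 m³) and a
205-day campaign for the default 6.57 t target; (ii) lunar excavation —
CO2-limited at 14.17 kg CH4/day, 70 L in an interpolated 100 L vessel,
153 days for the default 2.17 t target; (iii) crew respiration in transit
— 2.19 kg/day, 459 kg over the 210-day outbound leg, shipped mass 171 kg
with one electrolyser. The Mars electrolyser runs at 2998 g/h: the rated
constraint is 3000 g/h, but the 2998 g/h operating point is the one the
propellant-plant design quotes, and it is what closes the 157 L → 938.5 mW
chain. Default targets (6.57 t Mars, 2.17 t Moon) are config parameters
consistent with the 30–40 t (Mars) and 10 t (Moon) ascent-propellant
requirements at an O2:CH4 mixture ratio near 3.6; the oxygen co-product
side is informational, not costed, because oxygen-plant masses are
baseline constants.

**Food.** The dehydrated-biomass requirement (0.617 kg/crew/day over
residence + return) is produced during residence at 1 g/L/day. Mars:
2614 kg needs 5269 L of working volume, covered by 3 × 2000 L (2382 kg),
saving 32%/38% against the vegetarian/mixed wet-food baselines scaled from
the 6-crew/916-day reference menus. The Moon variants (single vessel at
79% coverage; 667 kg break-even budget at 42%) show that lunar residence
is too short for full coverage to pay off.

**PHB.** Habitat printing costs scale linearly from the 40 m³ reference
(8 t shipped / 3.8 t salts / 6 m³ structure). Substituting PHB at
1250 kg/m³, a fixed fleet of two 2000 L vessels at 1500 L each makes
111.6 kg/day at 37.2 g/L/day: 22 500 kg in 202 days on Mars (86% saving
vs 11.4 t of salts; 85.8% vs the 24 t total with the 1828 kg soil plant
included), 15 000 kg in about 134 days on the Moon (79%). The 7.84 kg/day
hydrogen make-up is checked against single-electrolyser capacity and the
result carries a feasibility flag.

**Pharmaceutical.** Acetaminophen productivity is estimated by carbon
equivalence from the same chassis's engineered ethylene rate: 6 mmol/L/day
of C2H4 ≡ 1.5 mmol/L/day of C8H9NO2 (226.7 mg/L/day; a quoted
230 mg/L/day corresponds to rounding the molar figure, which is treated as
authoritative). A 2 L working volume replenishes 100 × 325 mg tablets in
72 days; smaller stocks in days.

## Rounding conventions

Durations are carried raw and reported to the nearest whole day; the
published campaign lengths (205, 153, 202, 134 days) are nearest-day
roundings of the raw values (ceiling would give 135 for the lunar PHB
case). Working volumes round up (you cannot under-size a vessel).
Comparisons with quoted values are made at the precision they were printed
at, never tighter.

## Synthetic scenario generation

The generator exists so every pipeline stage can be property-tested
without the packaged tables. It produces structurally valid inputs only —
catalogs with strictly monotone volume/mass/skid and strictly decreasing
power density, element-balanced random reactions over {C, H, O, N} (built
from exact rational coefficients, so conservation holds by construction),
and missions with formula-consistent waste streams inside realistic ranges
(crew 2–8, phases 5–600 d, productivities 0.1–500 g/L/day, catalogs of
3–6 rows). It makes no claim of statistical realism: passing generated
tests demonstrates correctness of the arithmetic and optimisation logic,
not that real organisms or hardware behave like the draws. A single seed
drives counter-derived substreams per entity, so generation order cannot
change results.

## Known limitations

* Nutrient and growth-media mass is assumed fully recycled (the stated
  design assumption); it is exposed only through the feasibility notes,
  not costed.
* The propellant-plant baseline masses are literature constants; the model
  cannot re-derive them, so plant-mass *reduction percentages* for the
  Mars/Moon propellant scenarios are not asserted anywhere.
* No kinetics, thermodynamics, pH/temperature dependence, or downstream
  separation costs; offgas purity is carried as a datum, not modelled.
* The nitrous oxide–hydrocarbon propellant route and habitat
  structural-property comparison are out of scope.
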