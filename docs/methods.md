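# Methods

This note documents the models behind `varigrass`, the provenance of the
defaults, what the synthetic cohort does and does not emulate, and the
numerical choices that matter.

## 1. Commercial yield scaling (`yield_scaling`)

Per-plant year-3 dry mass (kg) at each common-garden site is converted to
a per-area yield by multiplying by the site planting density (plants/m²;
1 kg/m² = 10 Mg/ha).  The three default sites are Tifton (1.20 m⁻², 3
control replicates), Knoxville (0.17 m⁻², 2) and Watkinsville (0.22 m⁻²,
1).  Site yields are combined by a weighted arithmetic mean with Tifton
weighted 3× (its density is closest to commercial seeding); weights are
renormalized over the sites actually present for a genotype.  Two
multiplicative corrections follow: 1.4 (spaced plants → dense swards) and
0.5 (small-plot → commercial-scale on marginal land).  Year-3 yield is
treated as the stand plateau; no stand-age trajectory is modelled.

Exclusion filters run in a fixed order: (1) mortality in any replicate at
any site; (2) replicate coefficient of variation — population SD over
mean of per-plant mass — strictly greater than 1 at any site with ≥ 2
replicates (population SD because replicate counts are 2–3, where the
n/n−1 choice is material; the choice is configurable); (3) projected
commercial yield strictly below 7.5 dry Mg/ha (exactly 7.5 passes).  A
site with surviving plants but zero mean mass has an undefined CV and is
excluded as `cv_exceeded`.  The ×3 site weight is applied per site, not
per replicate — the sources do not distinguish the two when replicate
counts differ; per-site is the interpretation implemented.

## 2. Composition closure (`composition`)

Sugar assays and lignin estimates are made on destarched,
ethanol-extracted biomass; all five measured fractions are multiplied by
0.95 to re-express them per unit whole dry biomass (ash is taken as
measured on whole biomass and not rescaled; a flag flips that if an assay
shared the extracted basis).  The rescale is linear and deliberately not
idempotent — the pipeline applies it exactly once, and a test pins that.

Closure adds assumed minors (mannan 0, acetate 0.020, sucrose 0, protein
0.031 mass fraction) and assigns the remainder to non-ethanol-soluble
extractives, so the component vector sums to one exactly.  Negative
extractives (named components > 1) raise an error listing the overfull
components.  The fermentable carbohydrate mass fraction (FCMF) is
glucan + xylan + arabinan; galactan is excluded because galactose is not
fermented in the conversion model.  The S/G ratio is carried but unused
downstream; ash passes through closure and affects only the mass balance.

Carbohydrates are kept on a **monomeric-equivalent** basis end to end (no
162/180 anhydro correction).  The published FCMF window (0.62–0.67) and
mean process yield (~372 L/Mg) are mutually consistent only on this
basis: 0.645 × ~0.89 × 0.511 / 0.789 ≈ 372 L/Mg.

## 3. Synthetic cohort generator (`synthetic_cohort`)

The generator is the package's stand-in for the (undeposited) field and
laboratory data.  It emulates the *marginal* population statistics and
the independence structure of the study cohort; it does not emulate
site × genotype interactions, establishment-year dynamics, spatial field
effects, or assay error correlation.  Passing tests therefore demonstrate
pipeline correctness and the structural conclusions (yield dominance),
not agronomic realism of any individual genotype.

**Composition.**  Each component is an independent truncated normal on
the extracted basis.  Dispersions for the four sugars are obtained by
inverting the published Scott's-rule histogram bin widths at n = 331
(w = 3.49·s·n^(−1/3)): glucose and xylose s = 0.0198, arabinose 0.00397,
galactose 0.00199, truncated at ±2.5 s.  Lignin is 0.19 ± 0.0095
(bin-width-derived, matching the printed 19 ± 1%) truncated to
[0.15, 0.21]; S/G 0.68 ± 0.08 on [0.47, 0.91]; ash 0.03 ± 0.008 on
[0.01, 0.05].  Sugar locations (glucose 0.400, xylose 0.2474, arabinose
0.0316, galactose 0.0105) are calibrated so the closed-basis FCMF is
centred at 0.645, the midpoint of the published window.  A joint
rejection step keeps every genotype's closed FCMF inside [0.62, 0.67]
(and discards the rare closure-infeasible draw).  One published statistic
cannot be honoured simultaneously: a process-yield CV of 2.63% is
infeasible for any unimodal law confined to that FCMF window (a uniform
caps it near 2.2%); the generator keeps the hard window and realizes
~2.1% CV.  The published S/G bin width (0.08) is likewise inconsistent
with Scott's rule given the printed SD; the printed SD wins.

**Biomass.**  Genotype mean plant mass is lognormal
(log-mean 0.8600, log-SD 0.44), replicate masses are the genotype mean
times mean-one lognormal noise with CV 0.20, and each plant dies
independently with probability 0.19 (mass recorded as 0).  These three
values are calibrated so the *filtered* cohort reproduces the published
downstream statistics: ~84 of 331 genotypes passing, commercial-yield
mean ≈ 15.3 Mg/ha (= 5700 L/ha ÷ 372 L/Mg), CV ≈ 40.6%, and a span of
roughly 7.5–39 Mg/ha.  Composition and biomass draws are independent by
construction, mirroring the reported absence of a yield–quality
correlation.

**Determinism.**  Each genotype consumes its own child RNG stream
spawned from the cohort seed by index, so a fixed seed gives a
bit-identical cohort and enlarging a cohort never perturbs existing
genotypes.  Truncated normals are sampled by exact inverse-CDF
(scipy `ndtr`/`ndtri`), vectorization-safe and reproducible.

## 4. Delivered feedstock cost (`logistics`)

The discrete-event supply-chain simulation the study used is replaced by
its closed-form reduction: total $/Mg = a/Y + b/√Y + c, where the a-term
collects per-hectare costs (land rent, amortized establishment,
maintenance, per-ha harvest), the b-term is transport through the
supply-shed radius (at fixed refinery demand the shed area scales as 1/Y,
the radius as Y^(−1/2)), and c collects per-Mg harvest, storage and
grinding.  All components are grossed up by 1/(1 − DML) with DML = 3% so
costs are per Mg delivered.  `calibrate_cost_params` solves a and b from
the two published anchors (≈$119/Mg at 7.5 Mg/ha, $70/Mg at 39 Mg/ha)
given c = $55/Mg, validates strict decrease, convexity and the published
flatness (< 2% change per +1 Mg/ha above 18 Mg/ha), and rejects
increasing or infeasible anchor sets.  The split of a and c into named
components (75/25 production/harvest; 35/28/37 harvest/storage/grind) is
not identified by the anchors and is a documented plausible choice; only
the totals propagate downstream.  Grower profit is excluded: this is a
techno-economic reactor-throat cost, not a farm-gate price.

## 5. Conversion (`conversion`)

Ethanol mass fraction = Σᵢ sugarᵢ × convᵢ × 0.511, with overall
conversions glucose 0.90 and arabinose 0.70 (the published endpoints),
galactose 0 (not fermented), and xylose 0.89 — an inferred value,
calibrated so the default cohort mean process yield sits at ~372 L/Mg;
it is config-overridable.  Process yield = g/g ÷ 0.789 kg/L × 1000.
The model is linear in the sugar vector, independent of lignin, ash and
extractives, and bounded by the stoichiometric ceiling
(all sugars × 0.511).

Energy side: combustible residue = lignin + unconverted carbohydrates +
extractives + protein (ash and acetate excluded), burned at a single
LHV of 21 MJ/kg (lignin-dominated residue; one LHV is a deliberate
simplification).  Process heat demand (4500 MJ/Mg feed) is met first;
the surplus becomes electricity at a 25% boiler-to-wire efficiency,
clamped at zero with a warning if the residue cannot cover the demand.
These three energy parameters are engineering defaults; they set the
coproduct magnitude (~0.6 kWh/L at the cohort mean) and the allocation
fraction (~0.90), and only those.  Field ethanol yield is the exact
product of process yield and commercial yield.

## 6. TEA (`tea`)

Annual production = 1814.37 Mg/day (2000 dry U.S. tons) × 350.4 days ×
process yield.  Cashflow model: three-year construction spending
(8/60/32%), straight-line depreciation over 7 years, 35% tax on income
floored at zero (no loss carryforward), 30-year life, 10% discount rate,
no working capital and no startup ramp — a reduced-order n-th-plant
convention.  Electricity is credited at $0.057/kWh.  The MFSP solves
NPV(price) = 0 by deterministic bisection on [0, 10] $/L to |NPV| < $1
(price resolution ~1e-9 $/L at this plant scale).

The reference design's absolute capital and opex are not published, so
the non-feedstock variable operating cost was calibrated **once** so that
a packaged corn-stover reference composition at its reference delivered
cost ($64.49/Mg) returns MFSP = $0.570/L, the published stover benchmark;
the result (0.0773 $/L) is frozen in the defaults.  MFSPs are therefore
comparative between genotypes — differences are meaningful, absolute
levels inherit the anchor.  The per-genotype breakdown (feedstock,
capital incl. depreciation shield, opex, coproduct credit) is computed by
re-solving with each block zeroed; in the normal regime the DCF is affine
in the blocks and the contributions sum to the MFSP exactly (a residual,
zero to solver precision, is folded into opex).

## 7. LCA (`lca`)

Functional unit 1 L ethanol; cradle-to-biorefinery-gate.  Agriculture
inputs are per-hectare-year (establishment entries per rotation,
amortized over the 9 harvested years of the 10-year rotation) divided by
the field ethanol yield; logistics and biorefinery inputs are per-Mg
constants divided by the process yield — so agriculture impacts fall with
biomass yield, while logistics/biorefinery impacts vary only with
composition.  Both herbicides ride one sprayer pass; seed is trucked
161 km; cultivation is rain-fed (no irrigation entry exists, and a test
enforces it).  Ethanol combustion, biogenic CO₂, soil carbon, N₂O and
land-use change are out of scope.  Energy-based allocation
LHV/(LHV + 3.6·kWh/L) attributes impacts to ethanol; because
higher-FCMF genotypes leave less combustible residue, their allocation
fraction is higher, which partly offsets their per-litre dilution — this
feedback is what keeps GWP slightly *more* yield-determined than MFSP
and AWARE strictly less so.

The factor table (`data/inventory_factors.csv`) is a **synthetic,
calibrated fixture**: a licensed background inventory database cannot be
redistributed, so input quantities were fixed at agronomically
representative values (e.g. N 86 kg/ha/yr, enzyme 11.2 kg/Mg feed) and a
small number of swing entries (N and enzyme quantities, two CED factors,
two AWARE factors) were solved once against the published cohort impact
anchors (GWP 466–586, mean 517 g CO₂e/L; CED 8.70–10.5, mean 9.50 MJ/L;
AWARE 45.3–51.7, mean 48.3 m³/L), then frozen.  AWARE factors bundle
scarcity-weighted embodied water of input production and are the least
literature-like numbers in the table.  Absolute impacts are comparative,
like the MFSP.

## 8. Cohort analysis (`analysis`)

Scott's normal reference rule (3.49·s·n^(−1/3)) for histogram bins;
unweighted OLS (scipy `linregress`) on genotype-level values for all
trend fits, reported as slope/intercept/R²; zero-variance regressors are
an error in `fit_r2` and a NaN-flagged row in cohort summaries.
Representative-genotype selection for process-contribution analysis takes
the four yield/FCMF extremes first (ties broken by lexicographic
genotype id), then evenly spaced yield quantiles, deterministically.

## 9. Problem sizes and runtime

Default cohorts are the study scale (331 genotypes, ~84 passing); the
entire pipeline runs in well under a second, and the property/marginal
tests use cohorts up to 10 000 genotypes.  All randomness flows from a
single integer seed.

## 10. Known limitations

* Composition→conversion coupling is linear; pretreatment severity,
  inhibitors, drought-induced recalcitrance and lignin-quality (S/G)
  effects are not modelled.
* The cost curve has no weather/queueing/equipment-availability
  dynamics and no compositional change in storage.
* The DCF has no working capital, startup ramp, loss carryforward or
  equipment-level capital scaling with composition.
* LCA absolute levels depend on the calibrated fixture; soil carbon,
  N₂O and land-use change — the main divergences from agricultural
  GHG models — are excluded by scope.
* The generator draws composition independently of yield by design; it
  cannot be used to study yield–quality trade-offs.
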