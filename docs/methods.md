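# Methods

## Scope and model structure

`plastexpo` implements a screening-level consumer-exposure model for
six plasticizers in children's products, with two exposure routes:
oral ingestion of chemical migrating into saliva during mouthing, and
dermal absorption from skin contact.  Inhalation and indoor-dust
ingestion are excluded (those routes are dominated by sources other
than the products themselves), as is any mechanistic migration model:
the migration rate is assigned from the article's chemical content,
which is exactly the simplification the sensitivity analysis module is
there to probe.

## Ingestion

`dose = MR · CA · (D_mouthing/60) · (Dur/60) · ED/(BW·AT)` in
mg kg⁻¹ d⁻¹.  MR is mg cm⁻² h⁻¹ and CA cm²; `D_mouthing/60` converts
minutes of mouthing per hour of use into an hour fraction, and
`Dur/60` is the daily use time in hours, so the product of the two is
the daily mouthing time in hours.  `Dur` (min/d) is shared with the
dermal model as the daily article-contact duration.  The two-level
content policy (≥1% w/w → 10, below → 0.1 mg cm⁻² h⁻¹) is the
default; the boundary is closed on the high side, so a content of
exactly 1% receives the higher rate.  The four-level policy adds the
10⁻³ and 10⁻⁴ classes for sensitivity analysis; its lower class
bounds (0.1% and 0.01% w/w) are a package convention chosen
decade-wise because the source model's cut points for those classes
are not published.

## Dermal absorption

`dose = C_art · (SA/BW) · l · FA · ED/AT`, with intermediates as in
the README.  Numerical and unit choices that were genuinely open:

* **Diffusion distance.** The printed linear form `l = 2·D·Dur/60`
  cannot produce a length from m² h⁻¹ and minutes; the diffusion-length
  reading `l = 2√(D·Dur/60)` (metres → cm) restores units and matches
  the quantity's meaning (mean distance a molecule diffuses per
  contact).  The literal linear form remains available behind
  `diffusion_distance(..., literal=True)` for auditing.
* **FA grouping.** The numerator is `3 + χ[1 − exp(−a·Dur′/t_lag)]`
  over denominator `3(1+χ)`.  This parse makes FA ∈ (0, 1], equal to 1
  for a non-volatile chemical, and *decreasing* in χ — reproducing the
  qualitative behaviour that poorly water-soluble chemicals (DEHA,
  DEHP, DINP: large χ through small S_w·K_p) have low FA.
* **Units in χ.** `h` (m h⁻¹) is converted to cm h⁻¹ before dividing
  by `K_p` (cm h⁻¹), and the exponent uses `Dur` in hours because
  `t_lag` is in hours; with R = 62.37 mL Torr K⁻¹ mmol⁻¹, MW in
  mg mmol⁻¹ and S_w in mg mL⁻¹, χ is dimensionless.
* **Permeability components.** K_lip, K_pol and K_aq are not published
  for these chemicals, so they are estimated from MW and log Kow with
  the standard screening correlations (Potts–Guy lipid pathway,
  constant 1.5×10⁻⁵ cm h⁻¹ polar pathway, Cleek–Bunge 2.6/√MW aqueous
  boundary layer) and are overridable per chemical so literature
  values can be pinned.
* **C_art from % w/w** needs an article density; the default
  1.2 g cm⁻³ (typical plasticized PVC) is config-overridable and only
  rescales the calibrated defaults.

## Calibration of the default factor presets

The published screening outputs were produced with consumer-exposure-
model defaults (D, Dur, h, a, SA/BW, mouthing times) that are not
printed; only two outputs pin them down: the high-migration ingestion
dose (5.0×10⁻¹ mg kg⁻¹ d⁻¹ at MR = 10) and the DEHP dermal dose at
the 0.01% w/w inclusion threshold (8.6×10⁻⁶ mg kg⁻¹ d⁻¹).  Each
packaged preset therefore fixes plausible values for the observable
factors (CA = 10 cm², Dur = 60 min/d, BW and hand skin area per
preset, T = 298 K, h = 6 m h⁻¹, a = 1, h_sc = 15 μm) and solves the
two least-constrained parameters against the anchors, in closed form:
`D_mouthing` from the ingestion anchor (dose is linear in it) and the
solid-phase diffusion coefficient `D` from the dermal anchor (FA and
t_lag do not depend on D).  For the default 15 kg child this gives
D_mouthing = 4.5 min h⁻¹ and D ≈ 2.3×10⁻¹⁶ m² h⁻¹ — a small
diffusivity, at the rigid end of the plasticizer-in-PVC literature
range, which is where the anchor puts it given the other defaults.
Both doses are homogeneous of degree 1 in their concentration input,
so the calibration transfers exactly to every other concentration;
that linearity is what the dermal category-maximum predictions rely
on.  Non-DEHP dermal magnitudes follow mechanistically from the shared
D and chemical-specific FA; they are *not* individually calibrated,
and the published per-chemical dermal minima for the other chemicals
(which span a wider range than FA ∈ (0, 1] can produce under a shared
D) are not reproduced — only ratios across concentrations are
asserted for them.

## Deterministic engine

Scenario definitions: the maximum scenario uses the category's maximum
detected concentration; the minimum scenario uses the 100 mg/kg
inclusion-threshold concentration rather than the lowest observed
value, because that convention makes the per-chemical minima constant
across categories, which is how the published minima behave.  The
inclusion filter itself is strict (`detected and > 100 mg/kg`): a
category cell whose maximum sits exactly at 100 mg/kg (mat/DBP,
stationery/DIBP) drops out of the deterministic assessment, leaving 21
reportable (category, chemical) pairs.  MOE = reference dose / dose,
with a zero dose yielding an explicit "undefined" marker rather than
infinity; MOE < 100 raises a boolean screening flag, not a verdict.
Everything is computed at full precision, and 2-significant-figure
scientific formatting is applied only in the display layer.

## Monte Carlo engine

Per iteration and age group (0–2 and 3–12 years): draw BW, hand skin
area SA, mouthing contact area CA and mouthing duration; per category
an activity duration ED (h/d) using the activity mapping stay-in-home
→ accessories, stay-out-of-home → shoes, playing → mat and toy, study
→ stationery, personal sanitation → toilet; and per (category,
chemical) an article concentration.  ED plays the role the fixed `Dur`
plays deterministically (daily contact time), for both mouthing time
and the dermal contact duration.  Concentration distributions are
lognormals fitted by matching the log-mean and log-SD (sample SD,
ddof = 1) of the category's values with non-detects — including
entirely unmeasured products — substituted at LOQ/2; a degenerate
sample collapses to a point mass, and fewer than two products is an
explicit "insufficient data" condition.  The migration-rate
distribution is the induced image of the concentration draw under the
content policy (two-point under the default policy).  Doses are summed
over the six categories per route per iteration; totals are
ingestion + dermal per iteration, not per statistic.  Reported
statistics are the empirical median and 95th percentile (linear
interpolation between order statistics), each paired with its own MOE,
so MOE at the 95th-percentile dose is the lower value.

Anthropometric and activity draws use truncated normals (bounds
mean ± 3 SD and zero) to exclude non-physical negatives.  Randomness
comes from one master seed expanded through `SeedSequence.spawn` into
one child stream per (age group, parameter), in a fixed order, making
results bit-reproducible for a given seed; 10,000 iterations is the
default.

The packaged age-group profiles are **placeholders, not
authoritative**: the national exposure-factors handbook statistics a
real assessment needs are not published in machine-readable form, so
the shipped profiles contain plausible values for Korean children
(they do encode the one robust qualitative contrast — much more
mouthing and lower body weight at 0–2 than at 3–12, which drives the
younger group's higher ingestion dose).  Consequently the Monte Carlo
engine is validated on properties (degenerate-distribution equivalence
with the deterministic engine, seed reproducibility, median stability
across seeds, age-group ordering), never on published percentile
values.  The expectation that ingestion exceeds dermal exposure by
roughly 10–1000× is checked as a soft band: a warning, not a failure,
since with placeholder profiles the ratio can leave the band.

## Synthetic survey generator

The generator emulates the 3345-product survey from its published
margins only.  The combinatorial structure (which products carry which
chemicals) is solved deterministically: the number of DEHP-carrying
multi-plasticizer products per category is apportioned by largest
remainder under feasibility caps, extra co-detection slots likewise,
and each co-detected chemical is laid onto products by a cumulative-
offset round-robin that guarantees no duplicate chemical per product
and at least one partner per multi product.  The two DBP+DINP shoes
and the ten single-DEP toys are placed first as fixed constraints.
Only concentrations and cosmetic subcategory labels consume
randomness, so the margin counts are seed-invariant and a fixed seed
reproduces the file byte-for-byte.

Detected concentrations are drawn on (100 mg/kg, cell maximum] from a
truncated lognormal; where the cell maximum exceeds 1% w/w the
pre-truncation distribution is centred so roughly a quarter of draws
exceed 1% (log-SD 1.5), ensuring both migration-rate classes occur;
the exact cell maximum is assigned to exactly one product so every
published category maximum is reproduced exactly.  What the generator
does **not** emulate: true concentration distributions (only box plots
are published), measurement error and matrix effects, and any
real joint structure beyond the published co-occurrence rules — so
tests passing on synthetic data validate the pipeline's mechanics and
the published margins, not distributional claims about real surveys.

## Known limitations

* Physicochemical property values (MW, p_vap, S_w, log Kow) are
  literature inputs shipped as a versioned CSV; the values actually
  used to produce the published tables are unknowable, and χ (hence
  FA) is sensitive to p_vap and S_w for the sparingly soluble esters.
* Two published rows are internally inconsistent (stationery DIBP's
  total and accessories DEHP's total do not equal their printed
  components) and are excluded from exact comparisons.
* No cumulative multi-chemical risk metric: MOE is per chemical, as in
  the screening design.
* Problem sizes used throughout the test suite are the study's own:
  the full 3345-product survey, 10,000 Monte Carlo iterations, and 20
  replicate seeds for the stability check.
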