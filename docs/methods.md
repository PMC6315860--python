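# Methods

This note documents the models, parameters and numerical choices behind
`cyanoflux`, in the order a reader would meet them: the steady-state flux
model, the biomass equation, the reduced core network and what it does and
does not emulate, the simulation protocols, and the numerics.

## Steady-state flux model

All simulations are linear programs over the flux cone
{ v : S v = 0, l ≤ v ≤ u }. Exchange reactions follow the COBRA sign
convention (negative flux = uptake); "unconstrained" is represented by the
conventional finite bound ±1000 mmol/gDCW/h. The biomass pseudo-reaction's
flux is the specific growth rate μ (1/h); all other fluxes are mmol/gDCW/h.

A `Medium` lists the exchange bounds of nutrients present in the growth
medium (the reference, Zarrouk-like medium opens HCO₃⁻, NO₃⁻, phosphate,
sulfate and photons to uptake between 0 and 1000). Applying a medium resets
every unlisted exchange to secretion-only (0, 1000) and opens the freely
exchanged species — CO₂, O₂, H₂O, and H⁺ — to (−1000, 1000). Protons are
included in the free set as a deliberate model choice: secretion of charged
overflow products (lactate⁻, acetate⁻) requires a proton counter-flux for
charge closure, and tracking periplasmic pH is out of scope.

## Biomass equation

The reference macromolecular composition (%w/w) of exponentially growing
cells is: proteins 51.44, carbohydrates 31.62, lipids 4.98, DNA 0.88,
RNA 3.12, colorants 2.84, vitamins 0.11, minerals 2.79, ash 2.27.

Each pool is drained as monomers with coefficients
cₖ = 10·f·xₖ / Σⱼ xⱼMⱼ (mmol/gDCW), using residue masses *as polymerized*.
Monomer tables shipped with the package:

* **proteins** — six residues standing in for the full amino-acid palette
  (mole fractions: ala 0.25, gly 0.15, ser 0.12, cys 0.04, asp 0.20,
  glu 0.24). The set is chosen so the biomass nitrogen and sulfur demands
  are well defined (every residue carries one N; cysteine carries the S);
  the resulting nitrogen content (≈16.5% of protein mass) matches the usual
  protein-nitrogen rule of thumb. These frequencies are editable inputs,
  not genome reconstructions.
* **carbohydrates** — the glycogen glucosyl monomer C₆H₁₀O₅ (162.141 g/mol).
* **lipids** — a single phosphoglycerolipid-like pseudo-monomer C₄₁H₇₉O₁₀P
  (763.05 g/mol), built from one glycerol-3-phosphate backbone and 19
  acetyl units, so lipids contribute to the phosphorus demand.
* **DNA / RNA** — one purine and one pyrimidine residue each (dGMP/dTMP and
  AMP/UMP residues, 50:50), with integer residue formulas.
* **colorants + vitamins** — one shared phycobilin-like pigment-vitamin
  pseudo-monomer C₃₃H₃₈N₄O₆ (586.7 g/mol); a declared approximation, since
  the organism's true pigment/vitamin inventory is far richer.
* **minerals** — free sulfate and phosphate ions (50:50 molar), an
  inorganic drain with no carbon.
* **ash** — no precursor: mass closure is 1000·(100 − 2.27)/100 = 977.3
  mg/gDCW, and the package's tests assert it.

Growth-associated maintenance (GAM) defaults to 30 mmol ATP/gDCW, a typical
cyanobacterial value; it is hydrolyzed in the biomass reaction
(ATP + H₂O → ADP + Pi + H⁺) on top of any per-monomer energy costs.

Resulting element demands per gDCW (computed, not assumed): C 36.4, N 6.06,
P 0.337, S 0.362 mmol.

## The reduced core network

`make_core_model()` deterministically generates a 62-metabolite, 71-reaction
network over three compartments (cytoplasm, thylakoid lumen for photons,
extracellular). Contents:

* **Light reactions (lumped).** Linear electron flow:
  8 photons + 2 NADP⁺ + 3 ADP + 3 Pi + H⁺ → O₂ + 2 NADPH + 3 ATP — a
  quantum demand of 8 photons per 2 NADPH with 1.5 ATP coupled per NADPH
  (both parameters). Cyclic electron flow: 4 photons per ATP. Respiration:
  P/O = 1.5 (2 NADH + O₂ + 3 ADP + 3 Pi → 2 NAD⁺ + 3 ATP), plus a
  reversible transhydrogenase.
* **CCM + carbon fixation.** ATP-dependent bicarbonate uptake, reversible
  carbonic anhydrase, and a Calvin–Benson–Bassham lump
  3 CO₂ + 9 ATP + 6 NADPH + 5 H₂O → G3P + 9 ADP + 8 Pi + 6 NADP⁺ + 3 H⁺
  (composed from balanced sub-steps, so it is exactly element- and
  charge-balanced).
* **Glycolysis/gluconeogenesis** with the enzymes named in central-carbon
  flux maps (PGI, PGMT, PFK, FBPase, aldolase, TPI, a GAPDH+PGK lump,
  phosphoglycerate mutase, enolase, pyruvate kinase, PDH), a reversible
  non-oxidative pentose phosphate lump (5 G3P + 2 H₂O ⇌ 3 Ru5P + 2 Pi),
  and the cyanobacterial TCA cycle: citrate synthase, an
  aconitase+NADP-IDH lump, the 2-oxoglutarate decarboxylase /
  succinate-semialdehyde dehydrogenase bypass that closes the otherwise
  incomplete cycle, SDH (lumped to NAD), fumarase, MDH and PEP carboxylase.
* **Assimilation.** Nitrate reduction NO₃⁻ + 4 NADPH + 6 H⁺ → NH₄⁺ +
  4 NADP⁺ + 3 H₂O; ABC-type transporters (1 ATP per ion) for nitrate,
  sulfate, phosphate and bicarbonate.
* **Biosynthesis lumps.** One reaction per biomass monomer, from the
  canonical precursor (pyruvate, 3PG, OAA, 2-OG, Ru5P, acetyl-CoA + G3P).
  Each lump is closed exactly over the currency set {CO₂, NH₄⁺, H₂O, H⁺,
  Pi, NADPH/NADP⁺, SO₄²⁻} by a rational-arithmetic linear solve — the
  currency vectors span (C, H, N, O, P, S, charge), so closure always
  exists and is unique. Explicit ATP costs (e.g. 6 per purine, 19 per
  lipid) are added as element-neutral ATP hydrolyses. Hand-balanced
  versions of the six amino-acid lumps are frozen in the test suite as
  independent oracles of this solver.
* **Glycogen (four reactions).** Synthesis (glgA, G1P → glycogen + Pi, the
  monomer treatment), utilization for biomass growth (a parallel G1P →
  glycogen-equivalent reaction feeding the biomass carbohydrate term),
  storage/export transport, and degradation (glgP, bounds (0, 0) by
  default — inactive under autotrophic growth). Keeping utilization
  separate from synthesis is what makes the synthesis flux a clean readout
  of net storage: it is exactly zero in nutrient-sufficient growth instead
  of tracking the 1.95·μ carbohydrate demand of biomass.
* **Overflow routes.** Lactate dehydrogenase and a
  phosphotransacetylase+acetate-kinase lump with secretion-only exchanges
  for pyruvate, acetate and lactate (no uptake).
* **Maintenance.** ATPM (NGAM) with lower bound 0.34 mmol ATP/gDCW/h — see
  below.

Every internal reaction is elementally and charge balanced; the only
balance-unverifiable reactions are the two photon consumers (photons are
massless). The generated model passes both closed-system energy-leak tests
by construction, and the test suite asserts all of this on every run.

### NGAM and the dark-heterotrophic anchor

The network yields 20 ATP per glucose in the dark (2 substrate-level +
12 reducing equivalents × P/O 1.5). The measured heterotrophic glucose
uptake of 0.017 mmol/gDCW/h is interpreted as maintenance-level consumption,
so NGAM defaults to exactly 0.017 × 20 = 0.34 mmol ATP/gDCW/h. Dark growth
on ≤ 0.017 glucose is then *feasible with optimum exactly zero* — the
substrate covers maintenance and nothing else. Setting NGAM above the yield
would make the condition infeasible rather than zero-growth, which is why
"strictly above the yield" was rejected during design.

### Photon units (α) — calibrated, not predicted

Irradiance is printed in μmol photons/m²/s while fluxes are mmol/gDCW/h; no
first-principles conversion exists without culture geometry. The generator
therefore calibrates α = (photon flux bound)/(printed irradiance) once per
generation so that the reference autotrophic condition (irradiance 100,
HCO₃⁻ uptake 0.2) yields μ = 0.0252 1/h. Growth is piecewise linear in the
photon bound (an NGAM offset plus a constant light-limited slope), so α
comes from two probe LPs, verified by a third, with a bisection fallback.
The default model has α ≈ 0.1003; the autotrophic growth rate is thus an
anchor, not a prediction, and is documented as such wherever it appears.
Under the calibrated reference the core model is light-limited (CO₂ is
freely exchanged), so nutrient scans at HCO₃⁻ = 1.6 mmol/gDCW/h operate in
carbon excess as intended.

## Protocols

* **Growth validation.** Autotroph (photons + HCO₃⁻), heterotroph (glucose
  ≤ 0.017 in the dark; optimum exactly 0), mixotroph (both; provably ≥ the
  autotroph by LP relaxation). Secretion profiles at these optima show O₂
  release in the light and O₂ consumption + CO₂ release in the dark.
* **Carbohydrate maximization under N depletion.** Nitrate uptake and
  growth fixed to zero, glycogen synthesis maximized. With HCO₃⁻ as sole
  carbon source the optimum is exactly uptake/6 by carbon balance — the
  package's self-check for this protocol.
* **Nutrient scans.** HCO₃⁻ fixed at 1.6 mmol/gDCW/h (carbon excess),
  photons at the calibrated reference. At each grid point the solve is
  two-stage: maximize growth, then maximize glycogen synthesis with growth
  fixed at its optimum (numerical slack 10⁻⁹). A single-stage glycogen
  maximization would route *all* carbon to storage at every uptake and
  could never reproduce the observed growth curve alongside the glycogen
  curve; the two-stage scheme is therefore the package's documented
  reading. The growth-saturating ("optimal") uptake is found by bisection
  to 10⁻⁶ and equals μ* times the per-gDCW element demand, which the tests
  verify against an element-census oracle.
* **Central flux maps.** The nutrient is capped at a fraction (default 0.5)
  of its optimal uptake; growth is fixed at its optimum under the cap and
  glycogen synthesis at its two-stage optimum; geometric FBA then selects
  the unique centered distribution of the remaining degrees of freedom.
  Fixing both stages before centering is deliberate: with growth alone
  fixed, the L1 center parks glycogen at zero (the PFK/FBPase
  ATP-dissipation cycle's wide flux ranges dominate the distance), which
  would contradict the storage behavior these maps are meant to display.

## Numerics

* LP backend: scipy.optimize.linprog / HiGHS, primal and dual feasibility
  tolerances 10⁻⁹; reported-flux comparisons use 10⁻⁶.
* FVA: objective fraction defaults to 1.0 (ranges at the optimum);
  unbounded directions are reported as ±inf, never clamped.
* Geometric FBA: fix the objective at its optimum, take the FVA bounding
  box, L1-center toward the box midpoint, then re-tighten the box subject
  to Σ|vⱼ − mⱼ| ≤ p (the achieved distance, with slack
  max(10⁻⁷, 10⁻⁶·p) absorbing backend tolerance; the per-coordinate clamp
  |vⱼ − mⱼ| ≤ p backstops numerically infeasible sub-LPs). Convergence
  when the box width is below 10⁻⁶; iteration cap 50 with an explicit
  error carrying the residual width. The result is invariant to reaction
  ordering within 10⁻⁶ and idempotent under re-solving with all fluxes
  fixed.
* Leak tests: tolerance 10⁻⁶ mmol/gDCW/h separates leak-free from LP
  noise; the NAD(P)H probe is run separately per cofactor pair (NADPH and
  NADH) and the worse optimum is reported; probes operate on copies, the
  input model is never mutated. Maintenance lower bounds are relaxed in
  the closed system (a closed system cannot pay a forced demand; the probe
  asks what the network *can* produce).
* Producibility: energy cofactors are drained against their partner
  species (ATP → ADP hydrolysis, NAD(P)H → NAD(P)⁺ oxidation) because
  conserved moieties cannot carry flux through a bare drain.
* The generator contains no randomness: identical parameters produce
  identical models and manifests, bit for bit.

## What the core model does and does not emulate

The generator reproduces the *structure* of cyanobacterial central
metabolism and the *qualitative laws* of glycogen overproduction under
nutrient limitation — the growth/glycogen trade-off with its sharp threshold at the
optimal uptake, zero dark-heterotrophic growth, O₂/CO₂ secretion patterns,
carbon conservation, and clean QC (balance + leak freedom). Tests passing
on it therefore validate the algorithms and protocols, not the biology of
any particular strain. It does not emulate: the full ~1100-reaction
reconstruction (gene associations are placeholder locus tags; pathways are
lumped), compartment-resolved bioenergetics (no proton-motive force, no
thylakoid/cytoplasm pH distinction), photoinhibition or photon-capture
geometry (hence the calibrated α), absolute autotrophic/mixotrophic growth
rates beyond the calibration anchor, the vitamin/pigment pathway inventory,
and any kinetics or dynamics (FBA snapshots only; the 96-h nutrient-shift
time courses are out of scope).

## Known limitations

* The PFK/FBPase pair forms a thermodynamically unrealistic
  ATP-dissipation cycle, as in most FBA models without loop-law
  constraints; it is harmless for optima but shapes FVA ranges, which is
  why the flux-map protocol pins both objectives before centering.
* The SDH lump donates electrons to NAD⁺ (true succinate oxidation uses
  the quinone pool), slightly overestimating the P/O yield of the TCA
  bypass; NGAM is defined against this network's own yield, so internal
  consistency is preserved.
* Monomer tables are coarse (6 amino acids, 2+2 nucleotides); absolute
  element demands shift if they are refined, and the optimal-uptake values
  shift proportionally — the threshold *law* does not.
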