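# Methods

## Chain representation

A chain is an ordered tuple of identifiable residues (M/G), non-reducing end
first, plus two terminal states: whether the non-reducing end carries the
4,5-unsaturated Δ ring, and whether the reducing end is free or derivatised
with 2-aminobenzamide (2-AB). Δ is a *terminal state*, not a residue letter,
because β-elimination destroys the C5 stereocentre: no measurement can
recover the erased identity, so an unsaturated chain of DP *n* has *n* − 1
letters. The ASCII alias `d` for `Δ` and the `-2AB` suffix keep file formats
robust under encoding-hostile tooling.

## Mass model

A glycosidically linked uronate residue is C6H8O6 (monoisotopic
176.03209 Da). A saturated chain of *n* rings is *n*·176.03209 + 18.01056
(one water for the free ends); an unsaturated chain has lost that water to
β-elimination, giving *n*·176.03209. Negative-mode ESI observes [M−H]⁻
(−1.00728). Nominal m/z is the rounded monoisotopic value; at integer
precision nominal and rounded-monoisotopic coincide for all species in range,
so the choice is immaterial for DP ≤ 6. The released unsaturated monomer and
its ring-opened form DEH share C6H8O6 (nominal 175); the hydrated cyclic TPC
is C6H10O7 (nominal 193) and is isobaric with free saturated uronic acid.
Isotope envelopes, multiple charging and the 2-AB adduct mass are not
modelled (the label is used for fluorescence detection only).

## Cleavage chemistry

Every cut conserves ring count and follows β-elimination:

* **Endo cut** at the bond between letters *i* and *i*+1: the upstream
  fragment keeps the parent non-reducing end and exposes a saturated,
  detectable reducing end (letter *i*); the downstream fragment loses letter
  *i*+1 to its new Δ terminus and inherits the reducing-end label. The bond
  between the Δ ring and letter 1 carries no letter pair and is not an endo
  substrate; with the default minimum fragment sizes it would be excluded
  anyway.
* **Exo cut** removes the non-reducing-end ring: UDP1 if the parent was
  unsaturated, a saturated M/G monomer otherwise; the newly exposed ring
  becomes the remainder's Δ terminus. When one glycosidic bond remains, the
  cut resolves the chain into two monomers. Whether the very first exo cut
  on a saturated chain releases a saturated or unsaturated unit is not
  observable in the data this package models; the rule adopted — the
  released unit inherits the parent's non-reducing-end state, and the final
  reducing-end ring leaves saturated — is isolated in `exo_step` and chosen
  because it reproduces both the DEH/TPC-dominated exo end point and the
  2-AB ladder end point. 2-AB disaccharides resist exo cleavage (steric
  hindrance of the label), so labelled trajectories terminate at the
  labelled disaccharide with probability 1. Whether an exolyase cleaves a
  *saturated* free disaccharide is untested in the data modelled here; the
  default allows it.
* **Truncation** is the deterministic k-fold exo operator on a mixture:
  erase the first k letters of every chain and re-aggregate identical
  sequences. Up to dp − 2 cuts are possible for both label states (cutting a
  labelled DP3 down to the blocked labelled DP2 is allowed; cutting the
  blocked DP2 itself is not).

The monomer conversions UDP1 → DEH → TPC are non-enzymatic and fast relative
to digestion, so they are treated as an instantaneous relabelling of the
released pool with configurable endpoint fractions
(`speciate_unsaturated`); no kinetics are modelled and the three species are
accounted as one "unsaturated monomer" pool wherever yield is reported.

## Kinetic model

`simulate_digest` is an exact Gillespie simulation over a pool of chains.
Propensities are mass-action per chain:

* each cleavable internal bond a(1→4)b contributes u₁·cal·k(a,b), where the
  2×2 table k is the smallest model able to express block preference. The
  G-preferring preset k(G,G)=1, k(M,G)=0.25, k(G,M)=0.1, k(M,M)=0.01 is a
  tunable configuration default, not a measured quantity. Minimum fragment
  sizes (2 rings on either side) mean an endolytic digest never releases
  monomers.
* each cleavable non-reducing end contributes u₂·cal·r(dp). The exo profile
  r is piecewise-linear through anchors (dp 2 → 3.0, dp 4 → 6.5) down to a
  polymer tail of 1.0 at dp ≥ 30: the optimum sits at the tetrasaccharide
  and is 6.5-fold above polymeric substrate. Only those two facts are
  anchored; intermediate sizes are interpolation, not transcription.

Activities u are in mU (1 U = 1 µmol reducing ends released/min). A single
calibration constant cal maps activity units to propensity scale; the
default 2×10⁻³ events/(min·mU·unit rate) is frozen so that 100 mU of
exolyase performs ≈2 cuts per chain over a 10-minute assay on the
desk-scale polymer pool — enough repeated cuts that the exo-only arm's
unsaturated-monomer yield is reliably positive (the first cut on each
saturated chain releases a saturated monomer). Absolute wet-bench rates are
not claimed; per-chain mass action also differs from an enzyme-saturated
assay, where rate is per enzyme rather than per substrate chain, so
size-activity comparisons are made at matched chain counts.

`final_products` summarises replicate end states. True absorption
(t_end = ∞) with a strictly positive rate table eventually cuts every M–M
bond and leaves only DP2/DP3; the "exhaustive digest" the product tables
describe corresponds to a long-but-finite horizon. The default (120 min at
100 mU) gives unit-rate bonds a hazard ≈ 6 while M–M bonds stay ≈ 94 %
intact, which is what leaves M-rich tetramers and larger in the product
spectrum. Quantitative reproduction of any particular product ratio is out
of scope.

## NMR forward model and inference

One H-4 proton per Δ terminus and one β-anomeric proton per reducing end, so
integrated areas are proportional to moles (relaxation/NOE corrections are
not modelled) and only ratios carry information; the forward map is linear
in mixture fractions and scale-invariant in readout space. The two
alternative ΔG shifts are one analyte class, and possible overlap of the
reducing-end G doublet with the M singlet range is assumed resolved upstream
— inputs are pre-integrated areas. Only β-anomer areas enter the
reducing-end quantification. Qualitative "ΔM only"/"ΔG only" readouts are
encoded as area pairs (0, 1)/(1, 0).

Marginal extraction: p₍k+1₎ is the neighbour marginal after k cuts
(k = 0 … dp−3); p₍dp−1₎ comes from the parent's reducing-end areas, which
truncation does not touch. At DP 2 both observables collapse onto one
position and the H-4 areas are taken as primary. The joint is the outer
product of the marginals; species below the prune threshold (default 0.5 %,
chosen so a four-species DP5 support survives) are dropped and the rest
renormalised. The construction moment-matches the observed marginals
exactly, so the consistency residual is ≈0 by design and a large residual
signals corrupted inputs; what the residual *cannot* detect is positional
correlation, which is stated in every summary and report. Display rounding
follows the convention of two-species-integer / otherwise-one-decimal; full
precision is retained internally.

## Synergy accounting

Three arms at matched total activity: combined (the experiment's endo/exo
split, 50/50 by default), endo-only and exo-only, each receiving the total
mU. Yield is the released unsaturated-monomer pool; the synergy ratio is
combined/exo-only and is undefined when the exolyase is absent. The ratio's
absolute value depends on the frozen calibration; the properties asserted by
the test suite are qualitative — combined strictly exceeds exo-only on
polymeric substrate across seeds (ratio > 2 under the frozen defaults),
endo-only yields no monomers — plus the 6.5× profile anchor.

## Synthetic data

Chains are first-order Markov over {M, G}: stay probabilities give geometric
blocks (mean 1/(1 − stay)); presets emulate >90 % polyM, >90 % polyG and a
mixed block copolymer (stay 0.7/0.7, mean block ≈3.3, G fraction 0.5), with
chain length fixed or uniform in a range. Real alginates have
source-dependent M/G ratios, higher-order block structure and broad,
non-uniform size distributions; passing tests therefore demonstrate
correctness of the inference machinery on block-like chains, not coverage of
any particular algal source. Readout noise is multiplicative,
area·max(N(1, cv), 0), with cv = 0.05 as the default measurement-quality
assumption. Chromatogram fixtures place one Gaussian per size class
(σ = 0.25 ml, centres 1.8 ml apart, larger species eluting earlier) with
area equal to molar fraction — valid because every Δ-containing chain
carries exactly one 235-nm chromophore; the paired integrator uses ±4σ
windows clipped midway between neighbours and flags pairs closer than 4σ as
unresolvable. Column dispersion physics and extinction-coefficient effects
are not modelled.

## Numerical conventions and problem sizes

All randomness flows through `numpy.random.Generator` seeds; a fixed seed
fixes trajectories byte-for-byte in serialised output. Mixture fractions
must sum to 1 within 1e-9 (loaders renormalise with a logged warning beyond
1e-6). Event selection iterates species in canonical sort order so results
are independent of dict insertion history. The test suite validates the
Gillespie sampler against exact jump-chain enumeration on ≤DP4 substrates
(total-variation distance < 3 SE at 10⁴ replicates) and runs synergy
property checks on pools of 25 chains of DP 60 over 10 simulated minutes —
sizes chosen as the smallest at which the qualitative behaviour (size
effects, fragment-feeding) is unambiguous.

## Known limitations

* Positional independence is an assumption, not an inference; correlated
  mixtures are unidentifiable from marginal data.
* Hexasaccharide and larger fractions are sequenced only as far as their
  marginals; no attempt is made to resolve joints beyond that.
* Per-chain mass-action kinetics do not emulate enzyme saturation; absolute
  specific activities (U/mg) and wet-bench fold changes are out of scope.
* pH, temperature, metal-ion and inactivation effects on the enzymes are not
  modelled.
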