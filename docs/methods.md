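# Methods

## The metric

The average oxidation state of carbon in a molecule or moiety
C_cH_hN_nO_oP_pS_s with net charge Z is

    Z_C = (2o + 3n − 5p − 4s − h + Z) / c.

It follows from charge balance once every non-carbon atom is given a fixed
oxidation state: H +1, O −2, N −3, P +5 (the phosphate convention) and S +4
for sulfonic-acid sulfur, the only sulfur species in the lipid inventory
(the sulfoquinovosyl headgroup).  `ChemicalFormula` therefore carries an
explicit count of +4-assigned sulfur; Z_C computation refuses any formula
with unassigned sulfur rather than defaulting it, so future sulfur species
cannot silently inherit the sulfonic state.  Charge created by
pH-dependent (de)protonation cancels against the hydrogens it moves and
leaves Z_C unchanged; the permanent +1 of quaternary ammonium headgroups
(PC, BL, TM-KL, TM-OL) does not, and is carried in the registry formulae.
Where inputs are integral the arithmetic is exact (`fractions.Fraction`),
so repeating decimals such as −1/6 are represented exactly and rounded only
at output.

## Structural partition

Each lipid splits into headgroup(s) + backbone(s) + alkyl chains, with the
connector atoms (ester/ether oxygen, amide NH, the first methylene of a
C–C link) belonging to the backbone.  This makes nC comparable across
linkage chemistries and makes the partition *exact*: the component
formulae always sum to the full-lipid formula, which is enforced as an
invariant test across every headgroup/backbone combination in the registry.

Conventions that matter:

* every fully-linked glycerol backbone is C3H5O3 (Z_C = 1/3); GDGT and
  cardiolipin (DPG) count two backbones per lipid;
* GDGTs carry two headgroups; when all sugar/phosphate moieties cluster on
  one end, the other end's hydroxyl hydrogen is itself a headgroup ("H",
  formula H, no carbon).  Any split of moieties between the two ends gives
  the same total headgroup composition, so the accounting is
  position-independent;
* chains: ester/amide C_nH_(2n−1)O (acyl from the carbonyl carbon),
  ether/C–C C_nH_(2n+1), GDGT half-chain C_nH_(2n) (ether to the backbone,
  C–C to the partner half-chain, default n = 20); −2 H per unsaturation or
  internal ring, +1 O per hydroxylation.  Cyclopropane rings in non-GDGT
  chains are indistinguishable from unsaturations by mass and are encoded
  as such;
* non-glycerol backbones (CER C3H6NO2, DIOL C3H6O2, FA-OH-FAm C3H4NO2,
  FA-OH-FAm-OH C3H4NO3) are figure-derived defaults satisfying the
  three-carbon/three-connector rule, with the amide nitrogen counted
  backbone-side so the ornithine headgroup keeps a single nitrogen; the
  extra hydroxyl of FA-OH-FAm-OH is counted backbone-side.  Only the
  headgroup/backbone/chain *split* of Z_C depends on these choices — the
  full-lipid formula does not.

The annotation grammar mirrors field shorthand (`HEAD-BACKBONE(totC:totU)`,
`HEAD-GDGT(rings)`, `AR` for archaeol as an isoprenoid diether, `DPG(…)`
for cardiolipin with four acyl chains, `NAcG-P`/`2G-NAcG-G` DAG variants
with a third headgroup-attached chain).  Total chain carbons are split as
evenly as integers allow (e.g. C55 → 28 + 27): every computed metric
consumes totals, so the split is immaterial; per-chain syntax
(`16:0/18:1`) overrides it.

## Quantification

x_i = (I_i/(RF_i·mi_i)) / Σ_j(I_j/(RF_j·mi_j)), where I is the integrated
parent-ion peak area, RF the response factor of the assigned calibration
standard and mi the parent-ion monoisotopic mass.  Standards are assigned
per (headgroup, backbone) combination from the packaged registry: all
tetraethers share the glycosyl-GDGT standard, all aminolipids the DGTS-d9
standard; a missing combination is an explicit error, never a silent
default.  RF slopes are instrument-specific lab numbers, so they default
to 1.0 (mass-normalized peak-area fractions) unless a calibration YAML is
supplied; the synthetic generator exercises non-trivial slopes.  mi
includes the adduct (proton by default, ammonium selectable) — whether to
normalize by the adduct-bearing or neutral mass is not standardized, so
both modes exist (`include_adduct_mass`), with the parent-ion reading as
the default.  Zero-area records keep x = 0 rather than being dropped so
bootstrap perturbation cannot resurrect them.  Isotope masses are pinned
CODATA/IUPAC monoisotopic values in one table; an independent
mass-spectrometry library reproduces them in the tests.

## Averaging

Sample-level properties are ratios of abundance-weighted sums:
Σ_i Ξ_i x_i / Σ_i n_i x_i, with Ξ_i the property totalled over a lipid's
components of one type and n_i the component count (full-IPL formulae use
n_i = 1).  Component Z_C is computed from the *average formula* — the
ratio-of-averages — because Z_C of a mixture is not the mean of member
Z_C values when carbon counts differ (equal moles of C2H6 and CO2 average
to C1.5H3O, Z_C = −2/3, not +0.5).  The naive molar mean is kept only as a
separately named diagnostic.  Rings per GDGT renormalizes mole fractions
within GDGTs and counts each GDGT once; a GDGT-free sample reports the
quantity as undefined (None), never 0.  The carbon-free "H" headgroup
contributes its hydrogen to the headgroup average and one instance to the
denominator, though it has no Z_C of its own.

## Bootstrap

999 iterations (default).  Peak areas are multiplied by independent
Uniform[0.7, 1.3] draws; the RF of each headgroup/backbone combination is
multiplied by 10^Uniform[−2, +2], shared across all lipids with that
combination and — by default — across samples within an iteration (a
systematic-error model; per-sample scope is selectable).  The bounded
uniform shapes are the minimal reading of "vary by up to"; they are
isolated in `BootstrapConfig` and could be swapped.  A master seed spawns
per-iteration child streams, so individual iterations are reproducible.
Structural consequences verified in tests: zero widths give zero spread;
RF perturbation alone cannot move a sample with a single RF combination
(the factor cancels in the normalization); headgroup Z_C is far more
sensitive than chain Z_C because RF swings reweight whole lipid classes
whose headgroups differ much more than their chains.

## Gradients and regression

Dissolved O₂ in mg/L is converted to log10 molality as
log10((mg/L/1000)/31.998), taking 1 L of dilute solution as 1 kg of
solvent (0.2 mg/L → −5.20).  Field conductivity is normalized to 25 °C by
Cond_T/(1 + 0.02·(T − 25)).  Full-lipid, backbone and chain Z_C are fitted
by ordinary least squares with 95% prediction intervals; headgroup Z_C,
which peaks mid-gradient, gets a local quadratic smoother with tricube
weights and span 0.9, its band drawn at fit ± 1.96 × a local-linear
smooth of the squared residuals.  The smoother is written in-package
because the available lowess implementations are degree-1 and provide no
local residual scale; the contract is the stated algorithm, not numeric
agreement with any particular implementation.  Regressions in the analysis
scripts are fitted to pooled bootstrap draws with observed values overlaid.

## Synthetic data

The generator emulates a six-site outflow channel: temperature 90 → 30 °C,
O₂ 0.2 → 6 mg/L (geometric, so log-molal O₂ is near-linear in distance),
and a lipid mixture interpolated logistically between an upstream
endmember (tetraether/diether-rich: x_ether ≈ 0.91, nC ≈ 19.8,
nUnsat ≈ 0, ≈1.7 rings per GDGT) and a downstream endmember (ester-rich:
x_ester ≈ 0.90, nC ≈ 16.8, nUnsat ≈ 0.78, ≈3.5 rings per GDGT), matching
the compositional structure reported for alkaline hot-spring surveys.  The
inventory spans every backbone multiplicity the pipeline handles.  Peak
areas invert the quantification model, I = x·RF·mi·scale, times
multiplicative log-normal noise (σ = 0.2 in ln units, a realistic scale
for manual peak integration; chosen once and not tuned).  Because the
site mixture is a Möbius function of the logistic coordinate, ground-truth
IPL Z_C is strictly monotone along the channel.

What the generator does *not* emulate: between-spring heterogeneity,
censored (below-detection) lipids, annotation error, isotope-pattern
overlap, and chromatographic artifacts.  Passing end-to-end tests
therefore demonstrate correctness of the computation under the stated
error model, not robustness of the field inference to identification
mistakes.

## Problem sizes and numerics

Test and analysis runs use the six-site default survey; bootstrap tests use
99–500 iterations and the analysis scripts the full 999 (seconds of
runtime).  Slope recovery is checked with a percentile interval over 500
bootstrap draws of the cross-site slope against the slope implied by the
noise-free ground truth.  Mole fractions normalize to 1 within 1e−12;
sample summaries are order-invariant; a bootstrap with zero widths
reproduces the unperturbed values bit-for-bit (its reported sd is compared
to zero at 1e−12, the accumulation error of the variance of identical
floats).  Degenerate inputs fail loudly: empty samples, all-zero
intensities, carbon-free formulae queried for Z_C, unassigned response
factors, fractional formulae queried for parent-ion mass.

## Known limitations

* Component Z_C splits for the non-glycerol backbones rest on
  figure-derived default formulae (above); full-lipid Z_C is unaffected.
* Default response factors of 1.0 make absolute mole fractions
  mass-normalized peak-area fractions; relative trends in Z_C are the
  robust output, as the bootstrap quantifies.
* The local smoother is a faithful implementation of the stated algorithm
  but is not numerically identical to R's `loess.sd`.
* No modeling of limits of detection, isotope correction, or raw-spectrum
  processing; annotations are trusted input.
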