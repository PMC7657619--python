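# Methods

## Steady-state model

All accounting assumes a chemostat at steady state: specific growth
rate equals the dilution rate *D* and every extracellular concentration
is constant, so the specific production rate of species *s* is

    q_s = (c_s / M_s) · D / (X_N / 1000)        [mmol · g N⁻¹ · h⁻¹]

with c_s in mg/liter, M_s the molar mass in g/mol and X_N the cell
nitrogen concentration in mg N/liter. Nothing dynamic is modelled:
wash-in/wash-out transients are out of scope.

### Why per gram of cell nitrogen

Under nitrogen limitation the biomass C/N ratio rises (reserve polymer
accumulation), so a rate per gram dry weight conflates catalytic
machinery with storage material. Cell nitrogen is proportional to the
protein that actually carries flux; it is the default normalization.
Dry-weight normalization is offered as an option through an assumed
biomass carbon content of 0.45 g C/g cells.

## Molar-mass conventions

Organic acids have two masses: free acid and anion (lower by 1.008).
The packaged balance tables close only with **anion** masses
(the CO₂ inference and carbon recoveries reproduce their printed values
that way), while the packaged flux table reproduces only with
**free-acid** masses. Both conventions are first-class and every
conversion takes the convention as an explicit argument; the
inconsistency between the two source tables is documented here rather
than silently resolved. Atomic masses are fixed four-decimal IUPAC
values, so all derived numbers are bit-stable.

## CO₂ inference

`CO2 = acetate + ethanol [+ valine] + 2·isobutanol − formate` on a mole
basis. The valine term is part of the full argument (valine synthesis
from two pyruvate nets one CO₂) but the reference balance tables omit
it, and only the omitting variant reproduces them; `include_valine`
therefore defaults to `False`. A negative inferred CO₂ (formate
exceeding the sum of the positive terms) raises a
balance-inconsistency error instead of returning a nonsense value.

## Amino-acid totals: declared vs computed

The reference amino-acid profiles print total carbon and nitrogen rows.
The carbon total agrees with an elemental summation over the free amino
acids to within 1% (C. thermocellum column: computed 40.6 vs declared
40.5 mg C/liter), but the nitrogen totals do not (declared 20.6 /
23.4 mg N/liter vs computed 11.1 / 14.3); how the declared nitrogen
totals were obtained is not stated in the source data. The package
keeps both values: balance closure and the nitrogen-uptake flux consume
the **declared** totals when present (matching the published
accounting), and `AminoAcidProfile.element_mass` always provides the
elemental computation for comparison. Neither is ever substituted for
the other silently.

## Rounding

Recoveries are stored unrounded and rendered to one decimal. The PP_i
demand function computes exactly by default; `quantize=True` rounds the
catabolic cellobiose and each demand component to 0.1 mmol before
summing, which is the arithmetic used in the published figure
(catabolic 11.6 → 23.2 + 30.9 = 54.1 mmol PP_i/g, where exact
arithmetic gives 11.64 → 23.3 + 31.0 = 54.3). Both values are within
0.4% of each other; the quantized path exists to reproduce the printed
chain verbatim, not because it is more correct.

## Stoichiometry engine

Reactions are maps species → `fractions.Fraction`; combination is an
exact weighted sum, so intermediates cancel symbolically. Species
naming is case-sensitive with an alias table (`PP_i` → `PPi`).
Abstract species without full formulas carry a phosphate pseudo-element
ledger (ATP 3, ADP 2, AMP 1, PP_i 2, P_i 1, GTP 3, GDP 2, PEP 1, sugar
mono-/bis-phosphates 1/2) so phosphate conservation is checkable
without elemental formulas. Two schematic nets circulate in print in
forms that do not balance on this ledger — a pentose-cycle net lacking
a product P_i and an in-vivo PPDK summation lacking product ATP; both
appear typographical. The library stores the corrected forms as
defaults and the verbatim forms as `*_as_printed` variants flagged
unbalanced; the engine does not guess authorial intent. Schematic
equations conventionally omit water; the pyrophosphatase step keeps its
H₂O and net comparisons drop water explicitly (`Reaction.without`).

The one-ATP-per-peptide-bond saving of PP_i recycling is computed as
the difference in ATP-equivalents consumed by the two tRNA-charging
nets, where consuming ATP, GTP or PEP each counts one equivalent (PEP
because `PEP + ADP -> pyruvate + ATP` regenerates one ATP forgone).

## Energetics defaults

All budget constants live in one overridable configuration
(`EnergeticsDefaults`, mirrored in `data/energetics_defaults.yaml`):
biomass yield 0.16 g cells/g cellobiose, anabolic requirement 3.7 mmol
cellobiose/g cells, unaccounted fraction 0.16 (= 1 − recovery/100),
PPDK flux share 2/3 (from dynamic ¹³C labeling), 2 PP_i per cellobiose
at PP_i-PFK and 4 PEP per cellobiose, anabolic PP_i credit 11 mmol/g,
base ATP requirement 34.7 mmol/g (biosynthetic accounting at 52.4%
protein), mean residue mass 110 g/mol, biomass carbon content 0.45.
The anabolic cellobiose and base ATP numbers are cited constants from
network accounting; recomputing them from a genome-scale model is a
non-goal.

The lysis calculation exposes the specific cell volume as a parameter
defaulting to 2.0 ml/g, which reproduces the 334 µl volume of the
published argument; with it the implied intracellular amino-acid
concentration is 2.7 M (0.9 mmol / 0.33 ml). The source text prints
2.4 M for the same quantity without stating its volume assumption; the
unambiguous 167 mg cell-mass intermediate is what tests pin.

## Synthetic data generator

The generator inverts the steady-state relation: concentrations from a
ground-truth flux vector, feed cellobiose set so the noise-free carbon
recovery is exactly 100·(1−f) for a chosen missing-carbon fraction f,
cell carbon from a fixed biomass C/N ratio. Measurement error is
multiplicative lognormal with mean 1 and a given CV, applied per
replicate to product concentrations — chosen because concentrations
are strictly positive and chemostat measurement scatter scales with the
signal. Defaults emulate the carbon-limited reference condition
(D = 0.1 h⁻¹, 102 mg cell N/liter, C/N 3.31, the measured mixed-acid
product spectrum, f = 0.16, CV = 0.02). One child RNG per replicate is
seeded from (seed, replicate index), so any subset of replicates is
reproducible.

What the generator does **not** emulate: correlated errors between
species measured on the same HPLC run, systematic calibration bias,
drift between biological duplicates, amino-acid/protein excretion, and
any real biological flux variation. Passing parameter-recovery tests
therefore demonstrates the correctness of the accounting arithmetic
under the stated error model, not robustness to structured measurement
error in real cultures.

Test problem sizes: statistical checks run 50 replicates at CV 0.02,
where the 3·CV/√n band on the mean is ±0.85% — small enough to detect
real arithmetic errors, large enough that the checks are not flaky.
The whole suite is desk-scale and completes in seconds.

## Known limitations

* The published cellobiose uptake flux (4.66 mmol/g N/h) cannot be
  re-derived from the packaged feed concentration under any molar-mass
  convention (a naive recomputation gives ≈13.6); the reference-flux
  fixture flags the row `irreconcilable` and nothing validates against
  it.
* The nitrogen-limited and mutant flux columns ship without their
  underlying concentration tables; only ratios to the carbon-limited
  column (e.g. the 20-fold valine and 50-fold pyruvate increases) are
  meaningful.
* No degree-of-reduction (electron) balance, no thermodynamic (ΔG)
  evaluation, no intracellular flux estimation or flux-balance
  optimization, and no charge/pH speciation — exchange fluxes and
  linear stoichiometric accounting only.
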