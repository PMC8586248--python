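# Methods

`qconpath` models the two computational halves of a QconCAT-guided
strain-balancing study: (1) absolute quantification of pathway enzymes
by targeted MRM proteomics against a ¹³C-labeled concatamer standard,
and (2) a kinetic whole-cell model that relates the resulting P450/CDH
abundance ratio to (−)-carvone titer. This note records the models,
their assumptions, the defaults, and what the synthetic data do and do
not emulate.

## In-silico digestion and peptide selection

Trypsin is modeled by the Keil rule: cleavage C-terminal to K or R,
suppressed before proline. Missed-cleavage products up to a
configurable count (default 1) are enumerated as all unions of adjacent
fully-cleaved intervals. This is the community-default rule; it
reproduces the persistent junction-spanning peptide central to the
quantification workflow (see below).

Quantification-peptide ("Q-peptide") selection applies standard
proteotypic filters: length 6–25; no Met or Cys (oxidation/alkylation
liabilities); no N-followed-by-G (deamidation); no ragged ends (a
second K/R adjacent to a cleavage site); uniqueness across the target
protein set. Real selection uses empirical LC–MS detection strength,
which has no desk equivalent, so candidates are ranked by a
deterministic, documented proxy: prefer 8–15 residues, penalize
histidines (charge-state dispersion) and extreme Kyte–Doolittle
hydropathy. The score is overridable and only its ordering is used.

## Concatamer design and junction audit

A concatamer standard is valid only if every designed peptide is
released intact by trypsin. Each junction is audited:

- **blocked** — left segment does not end in K/R or the right segment
  starts with P; neither flank can be released intact.
- **acidic_neighbor** — the residue entering the P1′ position is D/E,
  which slows tryptic cleavage; a junction-spanning missed-cleavage
  product is predicted to persist.
- **miscleavage_collision** — that spanning product overlaps a designed
  quantification peptide. Because the persistent miscleavage depletes
  the released heavy standard for the upstream peptide, the audit
  recommends excluding the peptide on the left of the junction.

In the fixture design the ATR2 peptide VVDDILVEQGAQR sits immediately
before the acidic-starting EDTVLGGEYPLEK; the audit reports the
spanning product VVDDILVEQGAQREDTVLGGEYPLEK and excludes the ATR2
peptide from quantification, matching the documented workflow decision.

Masses are computed from the pyteomics residue tables (monoisotopic or
average) plus one water. The fixture concatamer is padded with an inert
tryptic filler behind the designed peptides so that its average mass
matches the 19.82 kDa implied by spiking 2 µg as 100.9 pmol. The real
standard and target sequences are not redistributable; all fixture
framework sequences are synthetic and labeled as such.

## Isotopologue model and labeling deficit

The standard is expressed on [U-¹³C₆] glucose of purity p = 0.99, so
each of a peptide's n_C carbons is modeled as independently ¹³C with
probability p (metabolic label scrambling ignored). Only carbon is
enriched; H/N/O/S stay at IUPAC 2013 natural abundances. Isotopologues
are binned at unit resolution (triple-quadrupole regime; exact-mass
fine structure is out of scope) and combined by discrete convolution,
truncated at cumulative abundance 1 − 10⁻⁶ and renormalized.

The fully labeled fraction is p^n_C; for VLDPNFADR (n_C = 46) at
p = 0.99 this is 0.99⁴⁶ ≈ 0.630, i.e. ~37% of the standard appears as
labeling-deficit isotopologues at smaller m/z. When only the heavy
monoisotopic peak is integrated, the raw light/heavy ratio therefore
overestimates the sample amount by 1/p^n_C.

## Quantification pipeline

Per peptide and sample:

    amount [pmol] = (light / heavy) × spiked_pmol × p^n_C
    copies/cell   = amount × 10⁻¹² × N_A / cells_in_digest

with negative-control light areas (mean over control replicates)
subtracted first and clamped at zero. The deficit correction p^n_C is
exposed explicitly and is ON by default for synthetic data; control
subtraction and deficit correction address different biases (additive
background vs multiplicative standard loss), so both are available and
switchable. Protein abundance is the mean over non-excluded peptides;
replicates are quantified independently and the SD is across
replicates, never across peptides.

`cells_in_digest` cannot be derived from a harvest expressed as
OD·mL alone; it is a required metadata field, with a helper assuming
8×10⁸ cells per OD·mL (a standard E. coli rule of thumb) scaled by the
digested aliquot fraction (defaults: 50 of 500 µg extracted → 4×10⁹
cells per digest).

QC operations: external calibration fits an (optionally 1/x-weighted)
least-squares line over the 0.25 pmol–2.5 nmol range and reports R² and
the residual-validated range; digestion time courses are scanned for
the earliest point whose relative gain drops below 5% (default),
returning the last point flagged "no plateau" otherwise.

## Kinetic bioconversion model

Species: limonene, trans-carveol, carvone, dihydrocarveol,
dihydrocarvone (molar masses 136.23, 152.23, 150.22, 154.25,
152.23 g/mol). Reactions are mass-action, first order in substrate,
with rate = k × E × OD × [S], where E is the catalyst's copies/cell and
OD the cell density — the simplest kinetics able to express the
observed ratio–titer trade-off. The hydroxylation step uses
min(P450, CPR) since electron transfer requires both; CPR is kept in
excess in every scenario. The by-product branches are: CDH reduces
trans-carveol to dihydrocarveol, and an unidentified endogenous
reductase (unit level in all strains) converts trans-carveol and
carvone to dihydrocarvone. Volatilization/partitioning losses are
ignored (ice-cooled sealed vials treated as effective).

Integration is fixed-step classical Runge–Kutta with step ≤ 0.01 h, in
mmol/L so that the 1:1 stoichiometry conserves total moles (checked to
10⁻⁶ relative in tests); halving the step moves endpoints by far less
than 0.1%.

Rate coefficients (units (copies/cell)⁻¹ OD⁻¹ h⁻¹) are not measurable
at desk scale; the shipped defaults are calibrated by least squares
(log-space, relative endpoint residuals) against four measured
endpoints: MpaLc and MpaHc carvone titers (44 and 2.9 mg/L at 16 h,
OD 20, 100 mg/L limonene) and the two whole-cell activity assays
(2.4 mg·L⁻¹·h⁻¹·OD⁻¹ trans-carveol for Mpa; 4.9 for carvone with Hc).
Four observations cannot identify five coefficients, so
k_endo_carveol is fixed at 2×10⁻⁴ (a minor flux that reproduces the
trace dihydrocarvone seen without CDH) and the other four are fitted;
the fit is exact (residuals ~10⁻¹⁵). `scripts/calibrate_defaults.py`
regenerates the constants.

## Scenarios and synthetic data

Scenario ground truths pin each condition's P450/CDH ratio to its
measured value: MpaHc 0.004, MpaLc 12, and the Mpa:Hc mixtures 0.388
(100:100), 3.4 (100:10), 16 (100:1). Absolute copy numbers are
synthetic choices (reported magnitudes are graphical only): CDH in the
high-copy Hc strain is set to 10⁴ copies/cell, MpaLc to
P450 = 1.2×10³ / CDH = 10², MpaHc to P450 = 40 / CDH = 10⁴. The three
printed mixture ratios are mutually inconsistent with proportional OD
mixing of one strain pair, so each mixture carries independent
profiles; their magnitudes additionally encode the induction
variability of co-incubated cultures and were chosen once so the
simulated titers reproduce the observed production ordering (maximum
at ratio 16, collapse at 0.004). Paper-anchored tests therefore use
ratios and pipeline-relative recovery, never absolute copy numbers.

Activity-assay scenarios carry their own substrate loads (1000 mg/L
limonene for Mpa, 2000 mg/L carveol for Hc, both OD 20 / 16 h) because
the printed activities over the bioconversion conditions imply product
far above a 100 mg/L feed; an activity assay is run in substrate
excess.

Synthetic peak tables follow
heavy = gain·spiked·p^n_C·release_efficiency and
light = gain·true_pmol + background, with mean-preserving lognormal
noise at a given CV (default 5%), background 0.5% of the median heavy
area, and release efficiency 0.7 for the miscleavage-affected ATR2
peptide. With noise off and deficit correction on, the pipeline inverts
this model exactly; tests verify recovery to 10⁻⁹ relative. What the
generator does **not** emulate: chromatographic interference, transition
selectivity, retention-time drift, digestion kinetics differing between
sample and standard (beyond the single release-efficiency factor), or
ionization suppression — so passing tests demonstrate the correctness
of the quantification arithmetic and workflow logic, not robustness to
real matrix effects.

## Numerical choices and limitations

- Isotope patterns: truncation at cumulative 1 − 10⁻⁶, then
  renormalization; convolution order over elements is immaterial
  (tested).
- Calibration R² is computed on unweighted residuals even under 1/x
  weighting, so the weighting choice changes the fit, not the metric.
- Optimum-ratio ties break toward the larger ratio (excess CDH is the
  documented harm).
- Control subtraction clamps at zero: negative corrected signal is
  noise, at the cost of a small positive bias near the detection floor.
- The kinetic model is deliberately minimal: no Michaelis–Menten
  saturation, no substrate uptake limitation, no product inhibition,
  no enzyme inactivation over the 16 h reaction. Its calibrated
  defaults interpolate the four anchoring endpoints and should not be
  extrapolated far outside OD ~20, 14 °C, or ~10³-fold enzyme ranges.
- Problem sizes used throughout (3 replicates, 7 peptides, 1600
  integration steps per 16 h simulation) mirror the study's scale and
  keep every analysis deterministic and fast.
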