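# Methods

This note documents the models, conventions and design choices behind the
package, what the synthetic benchmark does and does not emulate, and the
known discrepancies in the published reference values.

## Peptide chemistry and mass conventions

Residue masses are derived from elemental compositions (via pyteomics) in
three kinds: monoisotopic, average, and *nominal* (integer atomic masses
H=1, C=12, N=14, O=16, S=32).  Pyroglutamate (`Z`) is glutamine minus NH₃
(−17.0265 Da monoisotopic) and carries no free α-amine.  Intact mass is

    M = Σ residues + H₂O − 2·H per disulfide + adduct per alkylated Cys
        (+ proton for [M+H]⁺),

with CAM (carbamidomethyl, +57.0215) and NEM (N-ethylmaleimide, +125.0477)
as the two alkylation adducts.  Under the nominal convention the full
reduction/carbamidomethylation shift of an 8-Cys/4-SS peptide is exactly
8 × (57 + 1) = 464 Da, which is why the cysteine count can be read off a
MALDI-TOF mass difference; `cys_count_from_shift` inverts the shift by
rounding and reports the residual (rounding bounds the residual by half an
increment, so the residual flag engages only with a user-supplied, tighter
tolerance).

The published calculated-mass column mixes conventions: the monoisotopic
[M+H]⁺ of the oxidized species reproduces cC1c (3633.4) but not cC1a
(printed 3873.1 vs 3873.5 computed) or cC1b (3764.3 vs 3762.4); some
printed values are evidently observed rather than calculated masses.  The
package adopts the single convention above and reports mismatches rather
than reconciling them.

## Net charge and isoelectric point

Net charge is the formal count (#K + #R) − (#D + #E).  The published table
footnote nominally includes histidine among the positives, but the printed
charges are reproduced only with histidine excluded (e.g. cL1c, two His,
prints −1 = 2 − 3); the default therefore excludes His and an
`include_his` flag restores the literal footnote rule.  One printed row
(cL4) is internally inconsistent: cL4 and cL5 differ only by a Ser→Pro
substitution (identical ionizable content) yet print different charges
(−2 vs 0) and pI (4.36 vs 6.70), so no counting rule can match both; the
tests assert the charge column for the other 33 rows and document cL4 as a
typesetting-level error in the source table.

The isoelectric point is the unique root of the Henderson–Hasselbalch net
fractional charge, found by bisection on pH ∈ [0, 14] to |charge| < 10⁻⁴,
with the Bjellqvist (ProtParam) pKa set: side chains C 9.0, D 4.05, E 4.45,
H 5.98, K 10.0, R 12.0, Y 10.0; C-terminus 3.55; N-terminus residue-specific
(A 7.59, M 7.00, S 6.93, P 8.36, T 6.82, V 7.44, E 7.70) with 7.50
otherwise.  Disulfide-paired and alkylated cysteines are non-ionizable, and
a pyroglutamate N-terminus contributes no amine.  Two systematic
observations on the published pI column: (i) it is reproduced to ±0.01 for
every non-pyroglutamate row except cL4 *when all eight cysteines are
treated as free thiols*, i.e. the published values were computed on the
reduced sequence (the distinction only matters above pH ≈ 6, which is why
the acidic rows, including the pinned cC1c = 4.14, agree under either
state); compute with `n_disulfides=0` to match that convention exactly.
(ii) The pyroglutamate rows (cC1a, cL1a) were published with a free
N-terminal amine assumed — under the no-amine rule cC1a computes to ≈ 3.50,
not the printed 4.00.

The apolar alphabet is {G, A, V, L, I, P, F, M, W, C, N, Q} — uncharged,
non-hydroxyl, non-phenolic — the smallest standard-ish set under which the
prototype's N-terminal-to-core apolar run is 19 residues (positions 11–29);
it is overridable per call.

## Topology, loops and classification

The topology scanner slots the eight cysteines into the pattern with the
CC adjacency required exactly at slots III–IV; every other inter-cysteine
spacer must be ≥ 1 (this is what makes the all-cysteine degenerate string
unmatchable).  Loops are numbered L1..L6 skipping the zero-length III–IV
gap — the only numbering under which the contracted motif occupies "loops
3 and 4" (L3 = 2, L4 = 1) and loop 5 ranges 6–11 across the embedded
table.  The default per-loop bounds (L1 3–8, L2 3–8, L3 1–4, L4 1–2,
L5 4–15, L6 2–5) are derived from the observed ranges in the table and are
configuration, not constants.

Classification runs the scanner with bounds *disabled*: the table-derived
bounds would exclude genuine chitin-binding heveins, whose loops 3/4 carry
the >11-residue chitin-binding domain, from ever being labeled.  The
chitin-binding call requires both an S-X-Φ-X-Φ match (Φ ∈ {F, W, Y};
histidine excluded) in the CysIV→CysVI region and an aromatic strictly
between CysV and CysVI.  Labels: chitin hit → `chitin-binding-8C-Hev`;
otherwise contracted loops → `ginsentide-like-NCB-8C`; otherwise
`other-8C`; no topology → `not-8C`.  By default the scanner demands
exactly eight cysteines; an opt-in flag enumerates slottings over
sequences with more, reporting all and taking the lexicographically first
as primary.

## Precursor partitioning and mining

Homology search is replaced by exhaustive six-frame translation plus motif
mining: at desk scale the discriminating signal is the cysteine topology
and loop-3/4 content, not an alignment score, and this avoids an external
aligner.  ORFs are maximal ATG→stop spans (standard codon table); minus
frames report forward-strand 0-based half-open coordinates, and
stop-less ORFs at the record end are included only on request.

Partitioning scans Gly|Gln, Gly|Lys, Gly|Cys junction candidates right to
left and accepts the rightmost whose suffix (the mature) carries a full
bounded topology and lies in the 30–45-residue window; rightmost wins
because N-terminally ragged mature variants (the b/c truncation series)
arise downstream of the true cut and the window caps the suffix.  The
signal/pro split of the remaining prefix is an explicitly labeled
heuristic — cut after the most C-terminal small residue (A/G/S/C) in the
20–30 window, confidence-flagged — standing in for a dedicated
signal-peptide predictor; only the mature boundary is scientifically
load-bearing and it uses nothing but the stated junction rules.  Mining
composes ORF extraction → partitioning → classification → a
physicochemical summary; the bounded scan acts as the selectivity filter
at partition time while classification itself uses the unbounded scan.
`filter_hits` applies the 2–6 kDa oxidized-monoisotopic window of the MS
screen and deduplicates identical matures.

## Disulfide mapping

Cysteines are indexed by sequence ordinal (I..VIII).  Forward simulation
opens the true bonds one at a time in a given order; after j openings the
species carries 2j NEM labels and mass `oxidized + 2j·(H + NEM)`.  The
inverse problem is solved two ways: `deduce_nested` takes the strictly
nested label series, reads one bond per set difference (differences larger
than two enumerate their internal pairings and clear the uniqueness flag)
and completes the matching with the never-labeled pair; and
`deduce_constraints` filters all (n−1)!! = 105 perfect matchings, keeping
those for which every observed NEM set is a union of complete bonds and
every observed intact mass matches its expectation within tolerance
(default ±0.2 Da, reflector-MALDI level).  The nested answer is always a
subset of the constraint answer, and on complete noiseless series the two
agree and are unique — verified over all 105 truths with random reduction
orders.  Disulfide scrambling during partial reduction is not modeled:
the first alkylation runs under acid, which suppresses thiol-disulfide
exchange; this is a model assumption, not a simulated process.

## One-site isotherm

The forward model is the standard single-site (Wiseman) equilibrium with
per-injection displacement mixing: each injection of dV into cell volume
V₀ scales cell concentrations by (1 − dV/V₀) before delivering titrant,
the bound-complex concentration follows the quadratic root with n·Mt
binding sites, and the per-injection heat is the increment of V₀·ΔH·[MX]
corrected for displaced heat, normalized per mole of injectant.  Defaults
mirror the published protocol: twenty 2.5 µL injections, 40 µM cell,
400 µM syringe, 298 K.  The fit runs bounded least squares over
(n, log₁₀K_D, ΔH) from a seven-point logarithmic K_D grid of starts; flat
isotherms raise an explicit failure rather than returning an
unidentifiable optimum.  ΔG = RT ln K_D (standard state 1 M,
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹) and −TΔS = ΔG − ΔH.  The published ΔG
values (−9.35 kcal/mol for Mg²⁺, −6.43 for Fe³⁺) are mutually inconsistent
with this definition at the published K_D values (which give ≈ −8.9 and
−7.9 kcal/mol at 293 K); the package computes from the definition and the
test suite checks parameter *recovery* (noiseless round-trip to <0.1%,
median K_D error <10% at 2%-of-maximum-heat noise over 50 seeds) rather
than the printed thermodynamics.

## Synthetic benchmark: what it emulates and what it does not

The EST generator emulates the statistical structure of the search
problem: three-domain precursors (fixed 25-residue hydrophobic-core signal
scaffold; pro-peptide of length ~N(38.7, 2) clamped to 34–43, ending in
Gly; mature drawn from the embedded table, restricted to rows whose
sequence starts Gln/pyroGlu) reverse-translated with uniform synonymous
codons, flanked by random UTRs (20–150 nt) and placed on a random strand,
among three decoy classes — random ORFs (60–300 codons, cysteine-free),
chitin-binding hevein-like precursors (planted S-X-Φ-X-Φ plus inter-V/VI
aromatic), and seven-cysteine near-misses (one Cys→Ser).  A configurable
fraction of planted matures is loop-5-mutated (length resampled in 6–11,
keeping the mature inside the 30–45 window) and a fraction takes a
Gly|Lys junction (leading Gln→Lys).

Two generator guarantees are design properties, not sampled luck: random
decoys are rejection-sampled against the miner itself so that decoy purity
holds by construction, and planted matures are restricted to
junction-unambiguous sequences — one table row (cR5) begins
Gln-Glu-Gly-Lys, so its precursor contains a second, interior Gly|Lys cut
that the rightmost-junction rule cannot distinguish from the true one, and
it is excluded from planting.  Consequently, the 100%-recall /
0-false-positive mining result certifies the pipeline's behavior on
motif-bearing, junction-identifiable precursors; it says nothing about
sequencing error, chimeric ESTs, codon bias, introns, or signal peptides
that a trained predictor would be needed to delimit — none of which are
modeled.  The label reads in the reduction-series generator are likewise
error-free (only intact masses carry noise), matching what MS/MS
sequencing contributes in practice but idealizing its reliability.

## Numerical choices

* pI bisection: charge tolerance 10⁻⁴ (the charge curve is strictly
  decreasing, so the root is unique); near-flat curves map that tolerance
  to a few millipH of slack.
* Mass comparisons in tests: printed-precision tolerances (±0.1 Da for the
  pinned [M+H]⁺, ±0.01–0.02 pH for pI).
* Topology slotting ties: lexicographic order of the chosen cysteine
  positions, first is primary.
* Junction ties at the same position are impossible (the follower residue
  selects the rule); among positions, rightmost wins.
* ITC fit: K_D on a log scale, bounds n ∈ [10⁻³, 100], K_D ∈ [10⁻¹², 1] M;
  degenerate (flat or <3-injection) isotherms fail loudly.
* All stochastic components take a single seeded NumPy generator per call;
  identical config and seed give byte-identical outputs.

## Known limitations

* The signal/pro split is heuristic and confidence-flagged; only the
  mature boundary is validated against ground truth.
* The published calculated-mass column cannot be reproduced row-for-row
  under any single convention (see above); the package does not attempt
  per-row reconciliation.
* Isotherm fitting assumes integrated, baseline-corrected heats; raw
  power traces, baseline drift and dilution-control subtraction are out of
  scope, as are multi-site and sequential binding models.
* The miner's exhaustive six-frame scan is appropriate at EST scale
  (thousands of records); it makes no attempt at the indexing a
  genome-scale search would need.
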