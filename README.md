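# coffeetide

Discovery and characterization of **ginsentide-like eight-cysteine
microproteins** from transcript sequence data.

Plant hevein-like peptides (8C-Hevs) share a conserved cysteine scaffold,
`C Xn C Xn CC Xn C Xn C Xn C Xn C` — eight cysteines with one adjacent CC
pair — but split into two functional families: classical chitin-binding
heveins carry an `S-X-Φ-X-Φ` motif (Φ aromatic) between CysIV and CysVI,
while the ginsentide-like, non-chitin-binding members contract that region
to three residues (`CC x x C x C`) and adopt a distinct disulfide
connectivity, CysI–IV, CysII–VI, CysIII–VII, CysV–VIII.  Coffeetides,
~3.6–4.4 kDa microproteins from *Coffea* husk, are such a family: acidic,
amphipathic (a 19-residue apolar stretch in the prototype cC1a), heat- and
protease-resistant, cell-penetrating, and Mg²⁺/Fe³⁺-binding.

This package implements, as a tested library, the computational side of
that characterization:

* **`coffeetide.physchem`** — peptide parsing (pyroglutamate `Z`,
  alignment gaps, per-cysteine CAM/NEM alkylation states) and
  monoisotopic/average/nominal mass, net charge, isoelectric point
  (Bjellqvist pKa set, bisection on the Henderson–Hasselbalch charge
  curve), and apolar-stretch arithmetic.  The nominal-mass convention makes
  the classic MS screen exact: full reduction plus carbamidomethylation of
  an 8-Cys/4-SS peptide shifts the mass by 8 × 58 = **464 Da**.
* **`coffeetide.motif`** — eight-cysteine topology scan with configurable
  inter-cysteine loop bounds, chitin-binding-motif detection, contracted-motif
  detection, and the four-way classifier (`ginsentide-like-NCB-8C`,
  `chitin-binding-8C-Hev`, `other-8C`, `not-8C`).
* **`coffeetide.mining`** — six-frame translation, maximal ATG→stop ORF
  extraction, three-domain precursor partitioning at Gly|Gln / Gly|Lys /
  Gly|Cys junctions (rightmost topology-bearing cut wins), and end-to-end
  mining of EST libraries with a 2–6 kDa mass filter.
* **`coffeetide.ssmap`** — the partial-reduction / differential-alkylation
  disulfide-mapping experiment: forward simulation of nested NEM-labeled
  intermediates and inverse deduction of the connectivity, either by nested
  set differences or by constraint filtering over all 105 perfect
  matchings of eight cysteines.
* **`coffeetide.itc`** — the one-site (Wiseman) titration-calorimetry
  model with per-injection displacement mixing, multi-start nonlinear
  least-squares fitting of (n, K_D, ΔH), and derived ΔG = RT ln K_D and
  −TΔS = ΔG − ΔH.
* **`coffeetide.synthdata`** — seeded generators for every input: EST
  libraries with planted three-domain precursors among decoys, nested
  reduction-label observations with Gaussian mass noise, and noisy
  isotherms — each paired with machine-readable ground truth.

The 34 published mature sequences ship as an embedded table
(`coffeetide.datasets.load_table()`).

## Worked example

Mining a synthetic EST library (`examples/mine_est_library.py`):

```text
library: 220 records (20 planted, 200 decoys)
mined hits: 20 | recovered 20/20 planted, 0 false positives
mature sequences exactly matching ground truth: 20/20
after 2-6 kDa mass filter and deduplication: 13 unique matures
example hit: planted_0000 frame +2, junction G|Q, mature QEGECSPFGKPC... (4263.6 Da, charge -2)
```

Every planted precursor is recovered from the correct strand and frame with
its exact mature sequence, and none of the 200 decoys (random ORFs,
chitin-binding hevein-like sequences, seven-cysteine near-misses) leaks
through.  Disulfide mapping (`examples/map_disulfides.py`):

```text
cC1a oxidized monoisotopic mass: 3872.47 Da
  3-SS intermediate: NEM on Cys 1,4               mass  4124.58 Da
  2-SS intermediate: NEM on Cys 1,3,4,7           mass  4376.70 Da
  1-SS intermediate: NEM on Cys 1,2,3,4,6,7       mass  4628.81 Da
  0-SS intermediate: NEM on Cys 1,2,3,4,5,6,7,8   mass  4880.92 Da

nested deduction: CysI-IV, CysII-VI, CysIII-VII, CysV-VIII | unique: True
constraint filtering: 1 of 105 matchings survive
```

Each opened bond adds two hydrogens and two NEM adducts (+252.11 Da); the
three observed label sets pin three bonds and the never-labeled pair
(CysV–VIII) follows by deduction — the ginsentide pattern, uniquely, out of
all 105 possible pairings.  The other examples (`characterize_peptides.py`,
`classify_sequences.py`, `fit_binding_isotherm.py`) print the per-peptide
physicochemical table, the topology/classification evidence, and a
simulate-and-refit of the magnesium-binding isotherm.

A thin CLI wraps the same functions: `coffeetide characterize|classify|
mine|ssmap|simulate --help`.

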