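"""Seeded generators for every input the pipeline consumes.

Three experiment types are emulated, each paired with machine-readable
ground truth:

* EST libraries: nucleotide records carrying planted three-domain
  precursors (signal + pro + mature, the mature with the eight-cysteine
  topology) among decoy ORFs, chitin-binding hevein-like decoys, and
  seven-cysteine near-misses;
* partial-reduction label series with Gaussian mass noise for disulfide
  mapping;
* one-site titration isotherms with injection noise.

Reverse translation uses uniform synonymous codon choice (codon bias is
irrelevant to the pipeline under test).  The signal peptide is a fixed
hydrophobic-core scaffold, not a calibrated signal-peptide sample — the
pipeline's signal/pro split is an explicit heuristic anyway.  All
randomness flows from one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from . import itc as _itc
from . import mining as _mining
from . import ssmap as _ssmap
from .datasets import load_table
from .mining import MiningConfig, NucleotideRecord, mine_records
from .motif import scan_cysteine_topology
from .physchem import Peptide
from .ssmap import Connectivity, LabelObservation, simulate_reduction_series

__all__ = [
    "SyntheticConfig",
    "PlantedPrecursor",
    "EstGroundTruth",
    "generate_est_library",
    "generate_reduction_observations",
    "generate_isotherm",
]

# amino acid -> synonymous codons (standard table)
_CODONS: Dict[str, Tuple[str, ...]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, tuple())
    _CODONS[aa] = _CODONS[aa] + (codon,)
_STOP_CODONS = tuple(standard_dna_table.stop_codons)

#: 25-residue hydrophobic-core signal-peptide scaffold ending in a small
#: residue (signal-peptidase compatible).
SIGNAL_TEMPLATE = "MAKLSLVFLVLFLALSLTQVEAVGS"

_NON_CYS = "ADEFGHIKLMNPQRSTVWY"
_LOOP_FILL = "ADEGHIKLNPQSTV"  # non-Cys, non-aromatic filler for loop rebuilds


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic EST benchmark."""

    seed: int = 7
    n_planted: int = 20
    n_decoys: int = 200
    #: fractions of (random ORF, chitin-binding hevein-like, 7-Cys near-miss)
    decoy_mix: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    utr_length_range: Tuple[int, int] = (20, 150)
    decoy_orf_codons: Tuple[int, int] = (60, 300)
    loop5_mutation_rate: float = 0.3
    gk_junction_rate: float = 0.25
    mass_noise_sd: float = 0.05  # Da
    isotherm_noise_sd: float = 0.02  # kcal/mol of injectant

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.decoy_mix), 1.0):
            raise ValueError("decoy mix fractions must sum to 1")
        if any(not 0 <= p <= 1 for p in self.decoy_mix):
            raise ValueError("decoy mix fractions must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedPrecursor:
    record_id: str
    signal: str
    pro: str
    mature: str
    junction_rule: str
    source_id: str  # table row the mature derives from
    strand: int  # +1 / -1


@dataclass
class EstGroundTruth:
    planted: Dict[str, PlantedPrecursor] = field(default_factory=dict)
    decoy_kinds: Dict[str, str] = field(default_factory=dict)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _random_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _mutate_loop5(mature: str, rng: np.random.Generator) -> str:
    """Resample loop 5 (CysVI..CysVII spacer) to a random length in [6, 11],
    keeping the mature length inside the mining window."""
    pep = Peptide(mature)
    scan = scan_cysteine_topology(pep, spacer_bounds=None)
    if not scan:
        return mature
    topo = scan.topology
    p6, p7 = topo.position(6), topo.position(7)
    current = p7 - p6 - 1
    lengths = [
        l
        for l in range(6, 12)
        if 30 <= len(mature) - current + l <= 45
    ]
    new_len = int(lengths[rng.integers(len(lengths))])
    filler = "".join(_LOOP_FILL[i] for i in rng.integers(0, len(_LOOP_FILL), size=new_len))
    return mature[:p6] + filler + mature[p7 - 1 :]


def _junction_unambiguous(mature: str) -> bool:
    """True when the rightmost-junction rule recovers exactly this mature
    from a precursor cut at Gly|mature.  Matures whose own N-terminal region
    contains a second valid junction (e.g. a Gln-Glu-Gly-Lys start) are not
    identifiable under the stated cleavage rules and are excluded from
    planting."""
    model = _mining.partition_precursor("G" + mature)
    return model is not None and model.mature == mature


def _planted_matures() -> List[Tuple[str, str]]:
    """(id, gapless mature starting with Q) rows usable for a G|Q junction,
    restricted to junction-unambiguous sequences."""
    out = []
    for row in load_table().itertuples():
        seq = row.aligned_sequence.replace("-", "")
        if seq[0] in "ZQ" and _junction_unambiguous("Q" + seq[1:]):
            out.append((row.id, "Q" + seq[1:]))
    return out


def _build_record(
    rec_id: str,
    protein: str,
    rng: np.random.Generator,
    utr_range: Tuple[int, int],
) -> Tuple[NucleotideRecord, int]:
    """Embed a protein CDS (with stop) between random UTRs, random strand."""
    cds = (
        _reverse_translate(protein, rng)
        + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    )
    seq = _random_utr(rng, *utr_range) + cds + _random_utr(rng, *utr_range)
    strand = +1 if rng.random() < 0.5 else -1
    if strand == -1:
        seq = str(Seq(seq).reverse_complement())
    return NucleotideRecord(rec_id, seq), strand


def _chitin_mature(rng: np.random.Generator) -> str:
    """A hevein-like mature: eight-Cys topology with an S-X-Phi-X-Phi motif
    between CysIV and CysV and an aromatic between CysV and CysVI."""
    def fill(k: int) -> str:
        return "".join(_LOOP_FILL[i] for i in rng.integers(0, len(_LOOP_FILL), size=k))

    loop3 = fill(1) + "S" + fill(1) + "F" + fill(1) + "F" + fill(2)  # SxFxF inside
    loop4 = fill(1) + "W" + fill(1)
    return (
        "Q"  # junction-compatible N-terminus
        + fill(4)
        + "C" + fill(5)
        + "C" + fill(4)
        + "CC" + loop3
        + "C" + loop4
        + "C" + fill(5)
        + "C" + fill(3)
        + "C"
    )


def _seven_cys_mature(mature: str) -> str:
    """Near-miss decoy: last cysteine mutated to serine (7 Cys)."""
    idx = mature.rfind("C")
    return mature[:idx] + "S" + mature[idx + 1 :]


def _random_decoy_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    body = "".join(_NON_CYS[i] for i in rng.integers(0, len(_NON_CYS), size=length - 1))
    return "M" + body


def generate_est_library(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> Tuple[List[NucleotideRecord], EstGroundTruth]:
    """Generate an EST library with planted precursors and decoys.

    Planted precursors are signal (fixed 25-residue scaffold) + pro
    (random, length sampled near 38.7, ending in Gly) + mature (a table row,
    optionally loop-5-mutated, at a G|Q or G|K junction), reverse-translated
    with uniform synonymous codons and placed on a random strand between
    random UTRs.  Random-ORF decoys are rejection-sampled against the miner
    itself, so decoy purity is a property of the generator, not a lucky
    draw.  Identical config implies byte-identical records.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = EstGroundTruth()
    records: List[NucleotideRecord] = []
    pool = _planted_matures()

    for i in range(cfg.n_planted):
        rec_id = f"planted_{i:04d}"
        while True:
            src_id, mature = pool[rng.integers(len(pool))]
            if rng.random() < cfg.loop5_mutation_rate:
                mature = _mutate_loop5(mature, rng)
            rule = "G|Q"
            if rng.random() < cfg.gk_junction_rate:
                mature = "K" + mature[1:]
                rule = "G|K"
            if _junction_unambiguous(mature):
                break
        pro_len = int(np.clip(round(rng.normal(38.7, 2.0)), 34, 43))
        pro = (
            "".join(_LOOP_FILL[j] for j in rng.integers(0, len(_LOOP_FILL), size=pro_len - 1))
            + "G"
        )
        protein = SIGNAL_TEMPLATE + pro + mature
        rec, strand = _build_record(rec_id, protein, rng, cfg.utr_length_range)
        records.append(rec)
        truth.planted[rec_id] = PlantedPrecursor(
            record_id=rec_id,
            signal=SIGNAL_TEMPLATE,
            pro=pro,
            mature=mature,
            junction_rule=rule,
            source_id=src_id,
            strand=strand,
        )

    n_rand = int(round(cfg.decoy_mix[0] * cfg.n_decoys))
    n_chitin = int(round(cfg.decoy_mix[1] * cfg.n_decoys))
    n_seven = cfg.n_decoys - n_rand - n_chitin
    miner_cfg = MiningConfig()

    for i in range(n_rand):
        rec_id = f"decoy_rand_{i:04d}"
        while True:
            protein = _random_decoy_protein(rng, *cfg.decoy_orf_codons)
            rec, _ = _build_record(rec_id, protein, rng, cfg.utr_length_range)
            if not mine_records([rec], miner_cfg):
                break
        records.append(rec)
        truth.decoy_kinds[rec_id] = "random_orf"

    for i in range(n_chitin):
        rec_id = f"decoy_chitin_{i:04d}"
        mature = _chitin_mature(rng)
        pro = (
            "".join(_LOOP_FILL[j] for j in rng.integers(0, len(_LOOP_FILL), size=37))
            + "G"
        )
        protein = SIGNAL_TEMPLATE + pro + mature
        rec, _ = _build_record(rec_id, protein, rng, cfg.utr_length_range)
        records.append(rec)
        truth.decoy_kinds[rec_id] = "chitin_hevein"

    for i in range(n_seven):
        rec_id = f"decoy_7cys_{i:04d}"
        src_id, mature = pool[rng.integers(len(pool))]
        mature = _seven_cys_mature(mature)
        pro = (
            "".join(_LOOP_FILL[j] for j in rng.integers(0, len(_LOOP_FILL), size=37))
            + "G"
        )
        protein = SIGNAL_TEMPLATE + pro + mature
        rec, _ = _build_record(rec_id, protein, rng, cfg.utr_length_range)
        records.append(rec)
        truth.decoy_kinds[rec_id] = "seven_cys"

    return records, truth


def generate_reduction_observations(
    p: Peptide,
    truth: Connectivity,
    sigma_mass: float = 0.0,
    seed: Optional[int] = None,
    dropout: Optional[int] = None,
) -> Tuple[List[LabelObservation], List]:
    """Simulate a nested partial-reduction label series under a random bond
    order with Gaussian mass noise.

    Label sets are exact (MS/MS reads treated as error-free); ``dropout``
    removes the intermediate at that index (0-based) to emulate a species
    lost in purification.  Returns (observations, bond order used).
    """
    rng = np.random.default_rng(seed)
    bonds = sorted(tuple(sorted(b)) for b in truth)
    order = [bonds[i] for i in rng.permutation(len(bonds))]
    series = simulate_reduction_series(p, truth, [frozenset(b) for b in order])
    # the partially reduced intermediates only (3-SS .. 1-SS for 4 bonds)
    intermediates = [s for s in series if s.n_intact > 0]
    obs = []
    for s in intermediates:
        obs.append(
            LabelObservation(
                nem_ordinals=s.nem_ordinals,
                observed_mass=s.expected_mass + float(rng.normal(0.0, sigma_mass))
                if sigma_mass >= 0
                else s.expected_mass,
                n_cys=p.n_cys,
            )
        )
    if dropout is not None:
        obs = [o for i, o in enumerate(obs) if i != dropout]
    return obs, [frozenset(b) for b in order]


def generate_isotherm(
    proto: _itc.TitrationProtocol,
    n: float = 1.0,
    kd: float = 4.19e-6,
    dh: float = -0.695,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Tuple[_itc.Isotherm, Dict[str, float]]:
    """Simulate a titration and record the true parameters.

    Defaults are the magnesium-binding study conditions (one site,
    Kd 4.19 uM, dH -0.695 kcal/mol).
    """
    iso = _itc.simulate_isotherm(proto, n=n, kd=kd, dh=dh, noise_sd=noise_sd, seed=seed)
    return iso, {"n": n, "kd": kd, "dh": dh}
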