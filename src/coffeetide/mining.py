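"""Six-frame ORF extraction, precursor partitioning, and motif-based mining
of ginsentide-like precursors from nucleotide (EST) records.

The biosynthetic precursor of a ginsentide-like microprotein is a
three-domain protein — signal peptide, pro-peptide, mature peptide — and the
mature domain is released at a conserved Gly|Gln (or Gly|Lys; Gly|Cys in
ginsentides) junction.  Mining therefore proceeds as: translate every record
in all six frames, take every ATG-to-stop open reading frame, partition it
at the rightmost junction whose suffix carries a complete eight-cysteine
topology, and keep records whose mature domain classifies as
ginsentide-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from . import motif as _motif
from . import physchem as _pc
from .motif import DEFAULT_SPACER_BOUNDS, LABEL_GINSENTIDE, classify_8c, scan_cysteine_topology

logger = logging.getLogger(__name__)

__all__ = [
    "NucleotideRecord",
    "OpenReadingFrame",
    "PrecursorModel",
    "MiningConfig",
    "MiningHit",
    "six_frame_orfs",
    "partition_precursor",
    "mine_records",
    "filter_hits",
]

_NUCLEOTIDES = frozenset("ACGTN")
_SMALL_RESIDUES = frozenset("AGSC")


@dataclass(frozen=True)
class NucleotideRecord:
    """A transcript/EST record (A/C/G/T/N alphabet)."""

    id: str
    sequence: str
    description: str = ""
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _NUCLEOTIDES
        if bad:
            raise ValueError(f"record {self.id!r}: non-nucleotide characters {sorted(bad)}")
        if seq.count("N") > self.max_n_fraction * len(seq):
            raise ValueError(f"record {self.id!r}: N fraction exceeds {self.max_n_fraction}")
        object.__setattr__(self, "sequence", seq)

    def reverse_complement(self) -> "NucleotideRecord":
        return NucleotideRecord(
            self.id, str(Seq(self.sequence).reverse_complement()), self.description
        )


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ATG-to-stop ORF.

    ``span`` is 0-based half-open on the forward strand and includes the
    stop codon when one terminates the frame; minus-frame ORFs report the
    forward-strand coordinates of the reverse-complement hit.
    """

    frame: int  # +1,+2,+3,-1,-2,-3
    span: Tuple[int, int]
    protein: str
    has_stop: bool = True


def _scan_frame(seq: str, offset: int, min_len: int, include_truncated: bool):
    """Yield (codon_start_index, protein, has_stop) ORFs in one frame."""
    n_codons = (len(seq) - offset) // 3
    codons = [seq[offset + 3 * i : offset + 3 * i + 3] for i in range(n_codons)]
    proteins = str(Seq("".join(codons)).translate()) if codons else ""
    start: Optional[int] = None
    for i, aa in enumerate(proteins):
        if aa == "*":
            if start is not None:
                protein = proteins[start:i]
                if len(protein) >= min_len:
                    yield start, protein, True
                start = None
        elif aa == "M" and start is None:
            start = i
    if start is not None and include_truncated:
        protein = proteins[start:]
        if len(protein) >= min_len and "X" not in protein:
            yield start, protein, False


def six_frame_orfs(
    rec: NucleotideRecord,
    min_protein_length: int = 60,
    include_truncated: bool = False,
) -> List[OpenReadingFrame]:
    """All maximal ATG-to-stop ORFs in all six frames (standard codon table).

    Maximal: each stop-delimited segment contributes at most one ORF,
    starting at its first ATG.  ORFs running off the record end without a
    stop are included only when ``include_truncated`` is set.
    """
    seq = rec.sequence
    length = len(seq)
    if length < 3:
        return []
    orfs: List[OpenReadingFrame] = []
    rc = str(Seq(seq).reverse_complement())
    for strand, s in ((+1, seq), (-1, rc)):
        for offset in range(3):
            for start_codon, protein, has_stop in _scan_frame(
                s, offset, min_protein_length, include_truncated
            ):
                n_codons = len(protein) + (1 if has_stop else 0)
                lo = offset + 3 * start_codon
                hi = lo + 3 * n_codons
                if strand == -1:
                    lo, hi = length - hi, length - lo
                orfs.append(
                    OpenReadingFrame(
                        frame=strand * (offset + 1),
                        span=(lo, hi),
                        protein=protein,
                        has_stop=has_stop,
                    )
                )
    return orfs


@dataclass(frozen=True)
class PrecursorModel:
    """Signal/pro/mature partition of an ORF protein.

    ``signal + pro + mature`` concatenate to the full protein; the mature
    segment starts immediately after the fired junction.  The signal/pro
    split is an explicit heuristic (small residue at the signal-peptidase
    position) and carries a confidence flag; the mature boundary is the
    scientifically load-bearing cut and uses only the junction rules.
    """

    signal: str
    pro: str
    mature: str
    junction_rule: str  # e.g. "G|Q"
    signal_confident: bool = False

    @property
    def protein(self) -> str:
        return self.signal + self.pro + self.mature

    @property
    def mature_start(self) -> int:
        """0-based index of the first mature residue in the full protein."""
        return len(self.signal) + len(self.pro)


DEFAULT_JUNCTION_RULES: Tuple[str, ...] = ("G|Q", "G|K", "G|C")


def partition_precursor(
    protein: str,
    rules: Sequence[str] = DEFAULT_JUNCTION_RULES,
    spacer_bounds: Optional[Dict[str, Tuple[int, int]]] = DEFAULT_SPACER_BOUNDS,
    mature_window: Tuple[int, int] = (30, 45),
    signal_window: Tuple[int, int] = (20, 30),
) -> Optional[PrecursorModel]:
    """Partition an ORF protein into signal/pro/mature domains.

    Junction candidates (e.g. Gly|Gln) are scanned right to left; the mature
    segment is the suffix after the rightmost junction whose suffix carries
    a complete eight-cysteine topology and whose length lies in
    ``mature_window``.  Rightmost wins because N-terminally ragged mature
    variants arise downstream of the true cut.  Returns ``None`` when no
    junction yields a topology-bearing suffix.
    """
    followers = {}
    for rule in rules:
        left, right = rule.split("|")
        if left != "G":
            raise ValueError(f"junction rule {rule!r} must cut after Gly")
        followers.setdefault(right, rule)
    lo, hi = mature_window
    for i in range(len(protein) - 2, -1, -1):
        if protein[i] != "G" or protein[i + 1] not in followers:
            continue
        mature = protein[i + 1 :]
        if not lo <= len(mature) <= hi:
            continue
        try:
            pep = _pc.Peptide(mature)
        except ValueError:
            continue
        if not scan_cysteine_topology(pep, spacer_bounds=spacer_bounds):
            continue
        prefix = protein[: i + 1]
        signal, pro, confident = _split_signal(prefix, signal_window)
        return PrecursorModel(
            signal=signal,
            pro=pro,
            mature=mature,
            junction_rule=followers[protein[i + 1]],
            signal_confident=confident,
        )
    return None


def _split_signal(prefix: str, window: Tuple[int, int]) -> Tuple[str, str, bool]:
    """Heuristic signal/pro split: cut after the most C-terminal small
    residue (A/G/S/C) within the signal-length window."""
    lo, hi = window
    hi = min(hi, len(prefix))
    for k in range(hi, lo - 1, -1):
        if k >= 1 and prefix[k - 1] in _SMALL_RESIDUES:
            return prefix[:k], prefix[k:], True
    k = min(25, len(prefix))
    return prefix[:k], prefix[k:], False


@dataclass(frozen=True)
class MiningConfig:
    min_protein_length: int = 60
    include_truncated: bool = False
    junction_rules: Tuple[str, ...] = DEFAULT_JUNCTION_RULES
    spacer_bounds: Optional[Dict[str, Tuple[int, int]]] = None
    mature_window: Tuple[int, int] = (30, 45)
    mass_window: Tuple[float, float] = (2000.0, 6000.0)
    required_label: str = LABEL_GINSENTIDE

    def __post_init__(self) -> None:
        if self.spacer_bounds is None:
            object.__setattr__(self, "spacer_bounds", dict(DEFAULT_SPACER_BOUNDS))


@dataclass(frozen=True)
class MiningHit:
    record_id: str
    orf: OpenReadingFrame
    precursor: PrecursorModel
    classification: _motif.ClassificationResult
    mature_peptide: _pc.Peptide
    mass_mono_neutral: float
    charge: int
    pi: Optional[float]


def _summarize(record_id: str, orf, precursor, classification) -> MiningHit:
    mature = precursor.mature
    pep = _pc.Peptide(mature, n_disulfides=mature.count("C") // 2)
    return MiningHit(
        record_id=record_id,
        orf=orf,
        precursor=precursor,
        classification=classification,
        mature_peptide=pep,
        mass_mono_neutral=_pc.peptide_mass(pep, "mono", "neutral"),
        charge=_pc.net_charge(pep),
        pi=_pc.isoelectric_point(pep),
    )


def mine_records(
    library: Iterable[NucleotideRecord],
    config: MiningConfig = MiningConfig(),
    provenance: Optional[List[dict]] = None,
) -> List[MiningHit]:
    """Mine a library of nucleotide records for ginsentide-like precursors.

    Composition of :func:`six_frame_orfs`, :func:`partition_precursor` and
    :func:`~coffeetide.motif.classify_8c`; deterministic given the config.
    Individual record failures are logged and skipped, never fatal.
    """
    hits: List[MiningHit] = []
    for rec in library:
        try:
            orfs = six_frame_orfs(
                rec,
                min_protein_length=config.min_protein_length,
                include_truncated=config.include_truncated,
            )
            record_hits = []
            for orf in orfs:
                precursor = partition_precursor(
                    orf.protein,
                    rules=config.junction_rules,
                    spacer_bounds=config.spacer_bounds,
                    mature_window=config.mature_window,
                )
                if precursor is None:
                    continue
                classification = classify_8c(_pc.Peptide(precursor.mature))
                if provenance is not None:
                    provenance.append(
                        {
                            "record_id": rec.id,
                            "frame": orf.frame,
                            "span": orf.span,
                            "junction_rule": precursor.junction_rule,
                            "label": classification.label,
                        }
                    )
                if classification.label == config.required_label:
                    record_hits.append(_summarize(rec.id, orf, precursor, classification))
            # one hit per record: keep the first (lowest-frame) occurrence
            if record_hits:
                hits.append(record_hits[0])
        except Exception:  # noqa: BLE001 - per-record robustness is the contract
            logger.exception("record %s failed; skipped", rec.id)
    return hits


def filter_hits(
    hits: Sequence[MiningHit],
    mass_window: Tuple[float, float] = (2000.0, 6000.0),
) -> List[MiningHit]:
    """Keep hits whose oxidized monoisotopic neutral mature mass lies in the
    window; deduplicate identical mature sequences (first occurrence wins)."""
    lo, hi = mass_window
    seen = set()
    kept: List[MiningHit] = []
    for hit in hits:
        if not lo <= hit.mass_mono_neutral <= hi:
            continue
        if hit.precursor.mature in seen:
            continue
        seen.add(hit.precursor.mature)
        kept.append(hit)
    return kept
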