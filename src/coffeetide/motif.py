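"""Cysteine-topology scanning and hevein-family classification.

Eight-cysteine hevein-like peptides share the spacing pattern
``C Xn C Xn CC Xn C Xn C Xn C Xn C`` — eight cysteines with one adjacent
pair in the third and fourth slots.  The six inter-cysteine spacers are
numbered L1..L6, skipping the zero-length gap between CysIII and CysIV:

    L1 = CysI..CysII,   L2 = CysII..CysIII,  L3 = CysIV..CysV,
    L4 = CysV..CysVI,   L5 = CysVI..CysVII,  L6 = CysVII..CysVIII.

Chitin-binding members carry an S-X-Phi-X-Phi motif (Phi aromatic) between
CysIV and CysV plus a conserved aromatic between CysV and CysVI; the
non-chitin-binding (ginsentide-like) members instead contract loops 3 and 4
to the three-residue ``CC x x C x C`` arrangement (L3 = 2, L4 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Tuple

from .physchem import Peptide

__all__ = [
    "CysteineTopology",
    "TopologyScan",
    "ClassificationResult",
    "DEFAULT_SPACER_BOUNDS",
    "AROMATIC_SET",
    "scan_cysteine_topology",
    "detect_chitin_binding",
    "detect_contracted_motif",
    "classify_8c",
]

#: Aromatic triad used for the Phi slots of the chitin-binding motif.
AROMATIC_SET = frozenset("FWY")

#: Per-loop (min, max) spacer bounds observed across the coffeetide table.
#: Configuration, not constants of the pattern.
DEFAULT_SPACER_BOUNDS: Dict[str, Tuple[int, int]] = {
    "L1": (3, 8),
    "L2": (3, 8),
    "L3": (1, 4),
    "L4": (1, 2),
    "L5": (4, 15),
    "L6": (2, 5),
}

LOOP_NAMES = ("L1", "L2", "L3", "L4", "L5", "L6")


@dataclass(frozen=True)
class CysteineTopology:
    """Eight ascending 1-based cysteine positions with CysIII/CysIV adjacent."""

    positions: Tuple[int, ...]  # CysI..CysVIII

    def __post_init__(self) -> None:
        pos = self.positions
        if len(pos) != 8:
            raise ValueError("topology requires exactly eight cysteine positions")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("cysteine positions must be strictly increasing")
        if pos[3] != pos[2] + 1:
            raise ValueError("CysIII and CysIV must be adjacent")

    @property
    def loops(self) -> Tuple[int, int, int, int, int, int]:
        """Spacer lengths L1..L6 (the CysIII–CysIV zero gap is unnumbered)."""
        p = self.positions
        gaps = [p[i + 1] - p[i] - 1 for i in range(7)]
        # gaps[2] is the zero CysIII-CysIV gap
        return (gaps[0], gaps[1], gaps[3], gaps[4], gaps[5], gaps[6])

    def loop(self, k: int) -> int:
        return self.loops[k - 1]

    def position(self, ordinal: int) -> int:
        """Residue position of cysteine ordinal 1..8 (I..VIII)."""
        return self.positions[ordinal - 1]


@dataclass(frozen=True)
class TopologyScan:
    """Outcome of a topology scan: a topology or a reason for its absence."""

    topology: Optional[CysteineTopology]
    reason: Optional[str] = None
    #: All valid slottings when more than one exists (first is primary).
    alternatives: Tuple[CysteineTopology, ...] = ()

    def __bool__(self) -> bool:
        return self.topology is not None


def _check_slotting(
    positions: Tuple[int, ...], bounds: Optional[Dict[str, Tuple[int, int]]]
) -> bool:
    if positions[3] != positions[2] + 1:
        return False
    gaps = [positions[i + 1] - positions[i] - 1 for i in range(7)]
    loops = (gaps[0], gaps[1], gaps[3], gaps[4], gaps[5], gaps[6])
    if any(l < 1 for l in loops):
        # adjacency is permitted only at CysIII-CysIV
        return False
    if bounds is not None:
        for name, l in zip(LOOP_NAMES, loops):
            lo, hi = bounds[name]
            if not lo <= l <= hi:
                return False
    return True


def scan_cysteine_topology(
    p: Peptide,
    spacer_bounds: Optional[Dict[str, Tuple[int, int]]] = DEFAULT_SPACER_BOUNDS,
    allow_extra_cys: bool = False,
) -> TopologyScan:
    """Find the eight-cysteine topology of a peptide, if present.

    With ``spacer_bounds=None`` the bounds are disabled and any slotting with
    the CysIII–CysIV adjacency and strictly positive spacers elsewhere
    matches.  By default the sequence must contain exactly eight cysteines;
    ``allow_extra_cys`` enables slotting enumeration over sequences with
    more, reporting all valid slottings (lexicographically first is primary).
    """
    cys = p.cys_positions
    if len(cys) < 8:
        return TopologyScan(None, reason=f"cysteine count {len(cys)} != 8")
    if len(cys) > 8 and not allow_extra_cys:
        return TopologyScan(None, reason=f"cysteine count {len(cys)} != 8")

    candidates: List[CysteineTopology] = []
    for combo in combinations(cys, 8):
        if _check_slotting(combo, spacer_bounds):
            candidates.append(CysteineTopology(combo))
    if not candidates:
        return TopologyScan(None, reason="no valid cysteine slotting")
    return TopologyScan(candidates[0], alternatives=tuple(candidates))


@dataclass(frozen=True)
class MotifHit:
    """Span of an S-X-Phi-X-Phi hit plus the inter-CysV/VI aromatic position."""

    span: Tuple[int, int]  # 1-based inclusive
    aromatic_position: int


def detect_chitin_binding(
    p: Peptide,
    topo: CysteineTopology,
    aromatic_set: Iterable[str] = AROMATIC_SET,
) -> Optional[MotifHit]:
    """Chitin-binding motif: S-X-Phi-X-Phi between CysIV and CysVI plus a
    conserved aromatic strictly between CysV and CysVI.  Both are required.
    """
    aromatic = frozenset(aromatic_set)
    seq = p.sequence
    lo = topo.position(4) + 1  # first residue after CysIV
    hi = topo.position(6) - 1  # last residue before CysVI
    hit_span = None
    for start in range(lo, hi - 3):  # start..start+4 must fit inside [lo, hi]
        if (
            seq[start - 1] == "S"
            and seq[start + 1] in aromatic
            and seq[start + 3] in aromatic
        ):
            hit_span = (start, start + 4)
            break
    arom_pos = None
    for i in range(topo.position(5) + 1, topo.position(6)):
        if seq[i - 1] in aromatic:
            arom_pos = i
            break
    if hit_span is not None and arom_pos is not None:
        return MotifHit(span=hit_span, aromatic_position=arom_pos)
    return None


def detect_contracted_motif(p: Peptide, topo: CysteineTopology) -> bool:
    """True for the contracted ``CC x x C x C`` arrangement: L3 = 2, L4 = 1."""
    loops = topo.loops
    return loops[2] == 2 and loops[3] == 1


LABEL_GINSENTIDE = "ginsentide-like-NCB-8C"
LABEL_CHITIN = "chitin-binding-8C-Hev"
LABEL_OTHER = "other-8C"
LABEL_NOT = "not-8C"


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    topology: Optional[CysteineTopology] = None
    chitin_hit: Optional[MotifHit] = None
    contracted: bool = False
    reason: Optional[str] = None

    @property
    def loops(self) -> Optional[Tuple[int, ...]]:
        return self.topology.loops if self.topology else None

    @property
    def l3_l4_sum(self) -> Optional[int]:
        return None if self.topology is None else self.loops[2] + self.loops[3]


def classify_8c(
    p: Peptide,
    spacer_bounds: Optional[Dict[str, Tuple[int, int]]] = None,
    aromatic_set: Iterable[str] = AROMATIC_SET,
) -> ClassificationResult:
    """Classify a peptide by cysteine topology and loop-3/4 motif content.

    Labels: ``not-8C`` (no topology), ``chitin-binding-8C-Hev`` (S-X-Phi-X-Phi
    hit), ``ginsentide-like-NCB-8C`` (contracted loops, no chitin motif), or
    ``other-8C``.  The topology scan runs with bounds disabled by default so
    that long-loop chitin-binding members are classifiable; pass bounds to
    restrict.  A pure function of the sequence.
    """
    scan = scan_cysteine_topology(p, spacer_bounds=spacer_bounds)
    if not scan:
        return ClassificationResult(LABEL_NOT, reason=scan.reason)
    topo = scan.topology
    hit = detect_chitin_binding(p, topo, aromatic_set)
    contracted = detect_contracted_motif(p, topo)
    if hit is not None:
        label = LABEL_CHITIN
    elif contracted:
        label = LABEL_GINSENTIDE
    else:
        label = LABEL_OTHER
    return ClassificationResult(label, topology=topo, chitin_hit=hit, contracted=contracted)
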