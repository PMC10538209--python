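"""Peptide parsing and mass/charge/pI/hydropathy arithmetic for cysteine-rich
microproteins.

The module models mature eight-cysteine peptides in the states the wet-lab
workflow produces: fully oxidized (disulfide-bonded), partially or fully
reduced, and S-alkylated with iodoacetamide (carbamidomethyl, CAM) or
N-ethylmaleimide (NEM).  An N-terminal glutamine that has cyclized to
pyroglutamate is written ``Z`` and handled as its own monomer (Gln minus
ammonia, with no free alpha-amine).

Masses come in three kinds:

``mono``
    monoisotopic residue masses (Da), for high-resolution MS work;
``average``
    average isotopic masses (Da);
``nominal``
    integer atomic masses, the convention under which a full
    reduction/carbamidomethylation of eight cysteines shifts the intact mass
    by exactly 8 x 58 = 464 Da.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Tuple

from pyteomics import mass as _ptmass

__all__ = [
    "MonomerTable",
    "MONOMERS",
    "Peptide",
    "DEFAULT_APOLAR_SET",
    "parse_peptide",
    "peptide_mass",
    "reduction_alkylation_shift",
    "cys_count_from_shift",
    "net_charge",
    "isoelectric_point",
    "longest_apolar_stretch",
    "ApolarStretch",
    "CysCountResult",
]

GAP = "-"

# integer atomic masses for the nominal-mass convention
_NOMINAL_ELEMENT = {"H": 1, "C": 12, "N": 14, "O": 16, "S": 32}

_POSITIVE = frozenset("KRH")
_NEGATIVE = frozenset("DE")

#: Uncharged, non-hydroxyl, non-phenolic residues used for the apolar-stretch
#: scan.  Overridable per call.
DEFAULT_APOLAR_SET = frozenset("GAVLIPFMWCNQ")

# Bjellqvist (ProtParam) pKa values.
_SIDECHAIN_PKA = {"C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0}
_NTERM_PKA = {"A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.70}
_NTERM_PKA_DEFAULT = 7.50
_CTERM_PKA = 3.55


def _composition_masses(comp: _ptmass.Composition) -> Tuple[float, float, int]:
    """(monoisotopic, average, nominal) mass of an elemental composition."""
    mono = _ptmass.calculate_mass(composition=comp)
    avg = _ptmass.calculate_mass(composition=comp, average=True)
    nominal = sum(n * _NOMINAL_ELEMENT[el] for el, n in comp.items())
    return mono, avg, nominal


@dataclass(frozen=True)
class _Monomer:
    code: str
    mono: float
    average: float
    nominal: int
    charge_class: str  # "positive" | "negative" | "neutral"
    apolar: bool
    sidechain_pka: Optional[float]


class MonomerTable:
    """Per-residue masses, charge classes and pKa values.

    Covers the 20 standard residues plus ``Z`` (pyroglutamate).  Residue
    masses are elemental-composition derived; ``Z`` is glutamine minus NH3.
    """

    def __init__(self) -> None:
        comps = {aa: _ptmass.std_aa_comp[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}
        comps["Z"] = comps["Q"] - _ptmass.Composition(formula="NH3")
        self._monomers = {}
        for aa, comp in comps.items():
            mono, avg, nominal = _composition_masses(comp)
            cls = (
                "positive" if aa in _POSITIVE
                else "negative" if aa in _NEGATIVE
                else "neutral"
            )
            self._monomers[aa] = _Monomer(
                code=aa,
                mono=mono,
                average=avg,
                nominal=int(nominal),
                charge_class=cls,
                apolar=aa in DEFAULT_APOLAR_SET,
                sidechain_pka=_SIDECHAIN_PKA.get(aa),
            )
        self.water = _composition_masses(_ptmass.Composition(formula="H2O"))
        self.hydrogen = _composition_masses(_ptmass.Composition(formula="H"))
        # proton (hydrogen minus electron mass); nominal 1
        self.proton = (1.00727646688, 1.00739, 1)
        # S-alkylation adducts: CAM = carbamidomethyl (iodoacetamide),
        # NEM = N-ethylmaleimide (succinimide adduct)
        self.adducts = {
            "CAM": _composition_masses(_ptmass.Composition(formula="C2H3NO")),
            "NEM": _composition_masses(_ptmass.Composition(formula="C6H7NO2")),
        }

    def __getitem__(self, code: str) -> _Monomer:
        return self._monomers[code]

    def __contains__(self, code: str) -> bool:
        return code in self._monomers

    @property
    def alphabet(self) -> frozenset:
        return frozenset(self._monomers)

    @staticmethod
    def kind_index(kind: str) -> int:
        try:
            return ("mono", "average", "nominal").index(kind)
        except ValueError:
            raise ValueError(f"unknown mass kind: {kind!r}") from None

    def residue_mass(self, code: str, kind: str = "mono") -> float:
        return (self[code].mono, self[code].average, self[code].nominal)[self.kind_index(kind)]

    def adduct_mass(self, adduct: str, kind: str = "mono") -> float:
        if adduct not in self.adducts:
            raise ValueError(f"unknown adduct: {adduct!r} (expected 'CAM' or 'NEM')")
        return self.adducts[adduct][self.kind_index(kind)]


#: Shared default table.
MONOMERS = MonomerTable()


@dataclass(frozen=True)
class Peptide:
    """A mature peptide with its oxidation/alkylation state.

    Parameters
    ----------
    sequence:
        Gapless one-letter sequence; ``Z`` (pyroglutamate) is only legal at
        position 1.
    n_disulfides:
        Number of intact disulfide bonds (each removes 2 H relative to the
        free-thiol form).
    alkylation:
        Mapping of 1-based cysteine positions to ``"CAM"`` or ``"NEM"``.
    """

    sequence: str
    n_disulfides: int = 0
    alkylation: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq:
            raise ValueError("empty peptide sequence")
        for i, aa in enumerate(seq, start=1):
            if aa not in MONOMERS:
                raise ValueError(f"unknown residue {aa!r} at position {i}")
            if aa == "Z" and i != 1:
                raise ValueError(f"pyroglutamate (Z) only permitted at position 1, found at {i}")
        n_cys = seq.count("C")
        if self.n_disulfides < 0:
            raise ValueError("negative disulfide count")
        if self.n_disulfides > n_cys // 2:
            raise ValueError(
                f"{self.n_disulfides} disulfides impossible with {n_cys} cysteines"
            )
        for pos, adduct in self.alkylation.items():
            if not (1 <= pos <= len(seq)) or seq[pos - 1] != "C":
                raise ValueError(f"alkylation position {pos} is not a cysteine")
            if adduct not in ("CAM", "NEM"):
                raise ValueError(f"unknown adduct {adduct!r} at position {pos}")
        if 2 * self.n_disulfides + len(self.alkylation) > n_cys:
            raise ValueError("disulfide plus alkylated cysteines exceed cysteine count")
        object.__setattr__(self, "alkylation", dict(self.alkylation))

    # -- derived attributes -------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def cys_positions(self) -> Tuple[int, ...]:
        return tuple(i for i, aa in enumerate(self.sequence, start=1) if aa == "C")

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    @property
    def pyroglutamate(self) -> bool:
        """True when the N-terminus is cyclized (no free alpha-amine)."""
        return self.sequence[0] == "Z"

    @property
    def n_free_cys(self) -> int:
        return self.n_cys - 2 * self.n_disulfides - len(self.alkylation)

    @property
    def oxidized(self) -> bool:
        """All cysteines paired in disulfides."""
        return self.n_cys > 0 and 2 * self.n_disulfides == self.n_cys

    # -- state transitions --------------------------------------------------

    def reduced_alkylated(self, adduct: str = "CAM") -> "Peptide":
        """Fully reduced species with every cysteine carrying *adduct*."""
        return Peptide(
            self.sequence,
            n_disulfides=0,
            alkylation={pos: adduct for pos in self.cys_positions},
        )

    def with_alkylation(self, alkylation: Mapping[int, str], n_disulfides: int) -> "Peptide":
        return Peptide(self.sequence, n_disulfides=n_disulfides, alkylation=alkylation)


def parse_peptide(raw: str, n_disulfides: int = 0) -> Peptide:
    """Parse an aligned-sequence string into a :class:`Peptide`.

    Alignment gap characters (``-``) are stripped; all downstream
    coordinates refer to the gapless sequence.  A leading ``Z`` marks a
    pyroglutamate N-terminus.
    """
    if raw is None:
        raise ValueError("empty peptide sequence")
    stripped = []
    for i, ch in enumerate(raw.strip().upper(), start=1):
        if ch == GAP:
            continue
        if ch not in MONOMERS:
            raise ValueError(f"unknown residue {ch!r} at position {i}")
        stripped.append(ch)
    if not stripped:
        raise ValueError("empty peptide sequence after gap stripping")
    return Peptide("".join(stripped), n_disulfides=n_disulfides)


def peptide_mass(p: Peptide, kind: str = "mono", ion: str = "neutral") -> float:
    """Intact mass of a peptide in its current redox/alkylation state.

    mass = sum(residues) + water - 2 H per disulfide + adduct per alkylated
    Cys (+ proton for the ``[M+H]+`` ion).
    """
    k = MONOMERS.kind_index(kind)
    total = sum(MONOMERS.residue_mass(aa, kind) for aa in p.sequence)
    total += MONOMERS.water[k]
    total -= 2 * p.n_disulfides * MONOMERS.hydrogen[k]
    for adduct in p.alkylation.values():
        total += MONOMERS.adducts[adduct][k]
    if ion == "protonated":
        total += MONOMERS.proton[k]
    elif ion != "neutral":
        raise ValueError(f"unknown ion state: {ion!r}")
    return total


def reduction_alkylation_shift(p: Peptide, adduct: str = "CAM", kind: str = "mono") -> float:
    """Mass shift from full reduction plus alkylation of every cysteine.

    For an oxidized peptide with *n* cysteines the shift is
    ``n * (adduct + H)``: each cysteine gains the adduct, and each broken
    disulfide returns two hydrogens.
    """
    if p.n_cys == 0:
        warnings.warn("peptide has no cysteines; reduction/alkylation shift is 0")
        return 0 if kind == "nominal" else 0.0
    if not p.oxidized:
        raise ValueError("reduction_alkylation_shift expects a fully oxidized peptide")
    k = MONOMERS.kind_index(kind)
    shift = p.n_cys * (MONOMERS.adducts[adduct][k] + MONOMERS.hydrogen[k])
    return int(round(shift)) if kind == "nominal" else shift


class CysCountResult(NamedTuple):
    count: int
    residual: float
    flagged: bool


def cys_count_from_shift(
    observed_shift: float,
    adduct: str = "CAM",
    kind: str = "mono",
    tolerance: Optional[float] = None,
) -> CysCountResult:
    """Infer the cysteine count from an observed reduction/alkylation shift.

    Divides by the per-cysteine increment (adduct + H) and rounds to the
    nearest integer; the residual is flagged when it exceeds *tolerance*
    (default: half the per-cysteine increment).
    """
    if observed_shift < 0:
        raise ValueError("observed shift must be non-negative")
    k = MONOMERS.kind_index(kind)
    increment = MONOMERS.adducts[adduct][k] + MONOMERS.hydrogen[k]
    count = int(round(observed_shift / increment))
    residual = observed_shift - count * increment
    if tolerance is None:
        tolerance = 0.5 * increment
    return CysCountResult(count, residual, abs(residual) > tolerance)


def net_charge(p: Peptide, include_his: bool = False) -> int:
    """Formal net charge: (#K + #R [+ #H]) - (#D + #E).

    Histidine is excluded by default; pyroglutamate contributes nothing.
    """
    seq = p.sequence
    positive = seq.count("K") + seq.count("R")
    if include_his:
        positive += seq.count("H")
    return positive - (seq.count("D") + seq.count("E"))


def _ionizable_groups(p: Peptide) -> list:
    """(pKa, sign) pairs for every ionizable group of the peptide.

    Cystines (disulfide-paired) and alkylated cysteines are non-ionizable;
    a pyroglutamate N-terminus has no free alpha-amine.
    """
    groups = []
    if not p.pyroglutamate:
        groups.append((_NTERM_PKA.get(p.sequence[0], _NTERM_PKA_DEFAULT), +1))
    groups.append((_CTERM_PKA, -1))
    free_cys = p.n_free_cys
    for aa in p.sequence:
        if aa == "C":
            if free_cys > 0:
                groups.append((_SIDECHAIN_PKA["C"], -1))
                free_cys -= 1
        elif aa in _SIDECHAIN_PKA:
            groups.append((_SIDECHAIN_PKA[aa], +1 if aa in _POSITIVE else -1))
    return groups


def charge_at_ph(p: Peptide, ph: float) -> float:
    """Net fractional charge at a given pH (Henderson–Hasselbalch).

    Strictly decreasing in pH, so the isoelectric point is a unique root.
    """
    total = 0.0
    for pka, sign in _ionizable_groups(p):
        if sign > 0:
            total += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return total


def isoelectric_point(p: Peptide, tol: float = 1e-4) -> Optional[float]:
    """pH at which the net fractional charge vanishes (Bjellqvist pKa set).

    Bisection on pH in [0, 14] until ``|charge| < tol``.  Returns ``None``
    when the peptide carries no ionizable group at all.
    """
    if not _ionizable_groups(p):
        return None
    lo, hi = 0.0, 14.0
    if charge_at_ph(p, lo) < 0:
        return lo
    if charge_at_ph(p, hi) > 0:
        return hi
    while True:
        mid = 0.5 * (lo + hi)
        c = charge_at_ph(p, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            return mid


class ApolarStretch(NamedTuple):
    length: int
    start: Optional[int]  # 1-based inclusive
    end: Optional[int]


def longest_apolar_stretch(
    p: Peptide, apolar_set: Iterable[str] = DEFAULT_APOLAR_SET
) -> ApolarStretch:
    """Longest contiguous run of apolar residues (ties: earliest start)."""
    apolar = frozenset(apolar_set)
    best_len, best_start = 0, None
    run_len, run_start = 0, None
    for i, aa in enumerate(p.sequence, start=1):
        if aa in apolar:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_len == 0:
        return ApolarStretch(0, None, None)
    return ApolarStretch(best_len, best_start, best_start + best_len - 1)
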