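"""Disulfide-connectivity mapping by partial reduction and differential
alkylation.

The experiment: an oxidized peptide is partially reduced (TCEP, acid) and
the newly freed thiols are alkylated with N-ethylmaleimide (NEM).  Each
partially reduced intermediate (3-SS, 2-SS, 1-SS for a four-disulfide
peptide) is then fully reduced (DTT, base) and the remaining thiols
alkylated with iodoacetamide (CAM), so MS/MS reads out which cysteines
carry NEM in each intermediate.  Because reduction is nested, successive
NEM sets differ by exactly one bond, and the final unobserved pair follows
by deduction.

Cysteines are indexed by sequence ordinal 1..8 (CysI..CysVIII); conversion
to residue positions is delegated to the topology scanner.  Disulfide
scrambling during partial reduction is not modeled (the acidic first
alkylation suppresses it).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .physchem import MONOMERS, Peptide, peptide_mass

__all__ = [
    "Bond",
    "Connectivity",
    "ReductionIntermediate",
    "LabelObservation",
    "DeductionResult",
    "enumerate_connectivities",
    "simulate_reduction_series",
    "deduce_nested",
    "deduce_constraints",
]

Bond = FrozenSet[int]
Connectivity = FrozenSet[Bond]

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII", 8: "VIII"}


def bond(a: int, b: int) -> Bond:
    return frozenset({a, b})


def connectivity(*pairs: Tuple[int, int]) -> Connectivity:
    """Build a connectivity from ordinal pairs, validating the matching."""
    conn = frozenset(frozenset(p) for p in pairs)
    seen = [o for pair in conn for o in pair]
    if len(seen) != len(set(seen)) or any(len(p) != 2 for p in conn):
        raise ValueError("bonds must form a perfect matching of distinct ordinals")
    return conn


def format_connectivity(conn: Connectivity) -> str:
    pairs = sorted(tuple(sorted(p)) for p in conn)
    return ", ".join(f"Cys{ROMAN[a]}-{ROMAN[b]}" for a, b in pairs)


def enumerate_connectivities(n_cys: int) -> List[Connectivity]:
    """All perfect matchings of ``n_cys`` ordinals: (n_cys - 1)!! of them,
    in canonical (lexicographic by sorted pairs) order."""
    if n_cys < 2 or n_cys % 2:
        raise ValueError("cysteine count must be even and >= 2")

    def _match(ordinals: Tuple[int, ...]):
        if not ordinals:
            yield frozenset()
            return
        first, rest = ordinals[0], ordinals[1:]
        for i, partner in enumerate(rest):
            pair = bond(first, partner)
            remaining = rest[:i] + rest[i + 1 :]
            for sub in _match(remaining):
                yield sub | {pair}

    matchings = list(_match(tuple(range(1, n_cys + 1))))
    return sorted(matchings, key=lambda m: sorted(tuple(sorted(p)) for p in m))


@dataclass(frozen=True)
class ReductionIntermediate:
    """A partially reduced, NEM-labeled species.

    ``reduced_bonds`` have been opened and their cysteines alkylated with
    NEM; the remaining bonds are intact.  The expected intact monoisotopic
    mass is ``oxidized + |labels| * (H + NEM)``.
    """

    n_intact: int
    reduced_bonds: Connectivity
    nem_ordinals: FrozenSet[int]
    expected_mass: float

    def __post_init__(self) -> None:
        labelled = frozenset(o for pair in self.reduced_bonds for o in pair)
        if labelled != self.nem_ordinals:
            raise ValueError("NEM label set must equal the cysteines of the reduced bonds")


def simulate_reduction_series(
    p: Peptide,
    truth: Connectivity,
    order: Sequence[Bond],
) -> List[ReductionIntermediate]:
    """Forward-simulate the nested partial-reduction series.

    Bonds open one at a time in ``order`` (a permutation of the true bonds);
    after the j-th opening the species retains ``len(truth) - j`` disulfides
    and carries 2j NEM labels.  The final element is the fully reduced,
    all-NEM endpoint.
    """
    if not p.oxidized or p.n_disulfides != len(truth):
        raise ValueError("peptide must be oxidized with one disulfide per bond of the truth")
    if frozenset(frozenset(b) for b in order) != truth or len(order) != len(truth):
        raise ValueError("reduction order must be a permutation of the true bonds")
    k = MONOMERS.kind_index("mono")
    oxidized_mass = peptide_mass(p, "mono", "neutral")
    per_label = MONOMERS.hydrogen[k] + MONOMERS.adducts["NEM"][k]
    series: List[ReductionIntermediate] = []
    reduced: set = set()
    for j, b in enumerate(order, start=1):
        reduced.add(frozenset(b))
        labels = frozenset(o for pair in reduced for o in pair)
        series.append(
            ReductionIntermediate(
                n_intact=len(truth) - j,
                reduced_bonds=frozenset(reduced),
                nem_ordinals=labels,
                expected_mass=oxidized_mass + len(labels) * per_label,
            )
        )
    return series


@dataclass(frozen=True)
class LabelObservation:
    """NEM-bearing cysteine ordinals of one intermediate, as read by MS/MS
    after full reduction and CAM alkylation of the remainder."""

    nem_ordinals: FrozenSet[int]
    observed_mass: Optional[float] = None
    mass_tolerance: float = 0.2  # Da
    n_cys: int = 8

    def __post_init__(self) -> None:
        if len(self.nem_ordinals) % 2:
            raise ValueError("NEM label set must have even size (whole bonds reduce)")
        if not all(1 <= o <= self.n_cys for o in self.nem_ordinals):
            raise ValueError("NEM ordinals out of range")

    @property
    def iam_ordinals(self) -> FrozenSet[int]:
        return frozenset(range(1, self.n_cys + 1)) - self.nem_ordinals


@dataclass(frozen=True)
class DeductionResult:
    candidates: Tuple[Connectivity, ...]
    unique: bool

    @property
    def connectivity(self) -> Optional[Connectivity]:
        return self.candidates[0] if self.unique else None


def _pairings(ordinals: Tuple[int, ...]) -> List[Connectivity]:
    if not ordinals:
        return [frozenset()]
    first, rest = ordinals[0], ordinals[1:]
    out = []
    for i, partner in enumerate(rest):
        for sub in _pairings(rest[:i] + rest[i + 1 :]):
            out.append(sub | {bond(first, partner)})
    return out


def deduce_nested(obs: Sequence[LabelObservation], nested: bool = True) -> DeductionResult:
    """Deduce connectivity from a nested label series.

    Observations are sorted by NEM-set size; each successive set must
    strictly contain the previous.  A set difference of size two fixes one
    bond; larger (even) differences enumerate their internal pairings.  The
    cysteines never observed with NEM form the final deduced group.
    """
    if not nested:
        raise ValueError("non-nested data: use deduce_constraints")
    ordered = sorted(obs, key=lambda o: len(o.nem_ordinals))
    if not ordered:
        raise ValueError("no observations")
    n_cys = ordered[0].n_cys
    prev: FrozenSet[int] = frozenset()
    groups: List[Tuple[int, ...]] = []
    for o in ordered:
        if not prev < o.nem_ordinals:
            raise ValueError(
                "observations are not strictly nested; use deduce_constraints"
            )
        diff = o.nem_ordinals - prev
        if len(diff) % 2:
            raise ValueError(f"odd-size label difference {sorted(diff)}: inconsistent series")
        groups.append(tuple(sorted(diff)))
        prev = o.nem_ordinals
    remainder = tuple(sorted(frozenset(range(1, n_cys + 1)) - prev))
    if len(remainder) % 2:
        raise ValueError("odd number of never-labelled cysteines: inconsistent series")
    if remainder:
        groups.append(remainder)
    candidate_sets = [_pairings(g) for g in groups]
    candidates = [
        frozenset().union(*parts) for parts in product(*candidate_sets)
    ]
    unique = len(candidates) == 1
    candidates.sort(key=lambda m: sorted(tuple(sorted(p)) for p in m))
    return DeductionResult(tuple(candidates), unique)


def deduce_constraints(
    obs: Sequence[LabelObservation],
    tolerance: Optional[float] = None,
    peptide: Optional[Peptide] = None,
    n_cys: int = 8,
) -> DeductionResult:
    """Deduce connectivity by exhaustive constraint filtering.

    Every perfect matching of the ordinals is kept iff each observed NEM set
    is a union of complete bonds and (when an intact mass and a peptide are
    supplied) the expected intermediate mass matches within tolerance.
    Generalizes the nested deduction to dropout or non-nested data.
    """
    candidates = enumerate_connectivities(n_cys)
    if peptide is not None:
        k = MONOMERS.kind_index("mono")
        per_label = MONOMERS.hydrogen[k] + MONOMERS.adducts["NEM"][k]
        oxidized_mass = peptide_mass(peptide, "mono", "neutral")
    surviving: List[Connectivity] = []
    for cand in candidates:
        ok = True
        for o in obs:
            covered = frozenset(
                x for pair in cand if pair <= o.nem_ordinals for x in pair
            )
            if covered != o.nem_ordinals:
                ok = False
                break
            if o.observed_mass is not None and peptide is not None:
                expected = oxidized_mass + len(o.nem_ordinals) * per_label
                tol = tolerance if tolerance is not None else o.mass_tolerance
                if abs(o.observed_mass - expected) > tol:
                    ok = False
                    break
        if ok:
            surviving.append(cand)
    if not surviving:
        raise ValueError("no connectivity is consistent with the observations")
    return DeductionResult(tuple(surviving), len(surviving) == 1)
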