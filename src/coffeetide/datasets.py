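"""Embedded reference data: the mature coffeetide sequence table.

The table ships with the package as a TSV with one row per mature peptide
(id, species, aligned sequence with gap characters, the printed calculated
mass, formal charge, isoelectric point, and the sequencing approach —
transcriptomic ``T`` and/or proteomic ``P``).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import pandas as pd

from .physchem import Peptide, parse_peptide

__all__ = ["load_table", "table_peptides", "FIG3_CONNECTIVITY"]

#: Disulfide connectivity of the prototypic coffeetide (cysteine ordinals
#: I..VIII, sequence order): the ginsentide pattern.
FIG3_CONNECTIVITY = frozenset(
    {frozenset({1, 4}), frozenset({2, 6}), frozenset({3, 7}), frozenset({5, 8})}
)


def load_table() -> pd.DataFrame:
    """The embedded coffeetide table as a DataFrame (one row per peptide)."""
    with resources.files("coffeetide.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"printed_charge": str})
    df["printed_charge"] = df["printed_charge"].astype(int)
    return df


def table_peptides(n_disulfides: int = 4) -> Dict[str, Peptide]:
    """All mature peptides of the embedded table, parsed in the oxidized state."""
    df = load_table()
    return {
        row.id: parse_peptide(row.aligned_sequence, n_disulfides=n_disulfides)
        for row in df.itertuples()
    }
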