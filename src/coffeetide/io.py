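"""FASTA / TSV / JSON input-output for the pipeline.

Peptide and nucleotide FASTA go through Biopython; tables through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import MiningHit, NucleotideRecord
from .physchem import Peptide, parse_peptide
from .ssmap import LabelObservation

__all__ = [
    "read_peptide_fasta",
    "read_nucleotide_fasta",
    "write_nucleotide_fasta",
    "read_observations",
    "write_observations",
    "hits_to_frame",
    "write_hits",
]


def read_peptide_fasta(path, n_disulfides: int = 4) -> Dict[str, Peptide]:
    """One mature peptide per record; gap characters are stripped."""
    return {
        rec.id: parse_peptide(str(rec.seq), n_disulfides=n_disulfides)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_nucleotide_fasta(path) -> List[NucleotideRecord]:
    return [
        NucleotideRecord(rec.id, str(rec.seq), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_nucleotide_fasta(records: Iterable[NucleotideRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records),
        str(path),
        "fasta",
    )


def read_observations(path) -> List[LabelObservation]:
    """TSV with columns: intermediate, nem_ordinals (comma-separated),
    observed_mass (optional), tolerance (optional)."""
    df = pd.read_csv(path, sep="\t")
    obs = []
    for row in df.itertuples():
        ordinals = frozenset(int(x) for x in str(row.nem_ordinals).split(","))
        mass = getattr(row, "observed_mass", None)
        mass = None if mass is None or pd.isna(mass) else float(mass)
        tol = getattr(row, "tolerance", 0.2)
        tol = 0.2 if tol is None or pd.isna(tol) else float(tol)
        obs.append(
            LabelObservation(nem_ordinals=ordinals, observed_mass=mass, mass_tolerance=tol)
        )
    return obs


def write_observations(obs: Sequence[LabelObservation], path) -> None:
    rows = [
        {
            "intermediate": f"{o.n_cys // 2 - len(o.nem_ordinals) // 2}-SS",
            "nem_ordinals": ",".join(str(x) for x in sorted(o.nem_ordinals)),
            "observed_mass": o.observed_mass,
            "tolerance": o.mass_tolerance,
        }
        for o in obs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def hits_to_frame(hits: Sequence[MiningHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "record_id": h.record_id,
                "frame": h.orf.frame,
                "orf_start": h.orf.span[0],
                "orf_end": h.orf.span[1],
                "junction_rule": h.precursor.junction_rule,
                "label": h.classification.label,
                "mature": h.precursor.mature,
                "mass_mono_neutral": round(h.mass_mono_neutral, 4),
                "charge": h.charge,
                "pI": None if h.pi is None else round(h.pi, 2),
            }
        )
    return pd.DataFrame(rows)


def write_hits(hits: Sequence[MiningHit], path, provenance: Optional[list] = None) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
    if provenance is not None:
        Path(str(path)).with_suffix(".provenance.json").write_text(
            json.dumps(provenance, indent=1, default=str)
        )
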