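"""Topology scanning and hevein-family classification.

The scanner finds the eight-cysteine spacing pattern (with the adjacent CC
pair in slots three and four) and measures the six inter-cysteine loops.
Classification then separates chitin-binding members (S-X-Phi-X-Phi motif
between CysIV and CysVI) from ginsentide-like members (contracted CCxxCxC
loops 3/4, no chitin motif).
"""

from coffeetide.datasets import table_peptides
from coffeetide.motif import classify_8c, scan_cysteine_topology
from coffeetide.physchem import Peptide

peptides = table_peptides()

print("Prototype cC1a:")
scan = scan_cysteine_topology(peptides["cC1a"])
print("  Cys positions:", scan.topology.positions)
print("  loops L1..L6: ", scan.topology.loops)
res = classify_8c(peptides["cC1a"])
print("  label:", res.label, "| contracted CCxxCxC:", res.contracted)

labels = {pid: classify_8c(p).label for pid, p in peptides.items()}
print(f"\nAll {len(labels)} table sequences classify as:", set(labels.values()))

l5 = [scan_cysteine_topology(p, spacer_bounds=None).topology.loops[4] for p in peptides.values()]
print(f"Loop-5 lengths range {min(l5)}..{max(l5)} — the hypervariable loop.")

# a planted chitin-binding toy: SxFxF between CysIV and CysV, W after CysV
hevein_toy = Peptide("CAAAACAAAACCAAASAFAFAACAWACAAAACAAC")
print("\nHevein-like toy classifies as:", classify_8c(hevein_toy).label)
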