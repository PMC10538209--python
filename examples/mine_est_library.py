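"""End-to-end mining of a synthetic EST library.

The generator plants three-domain precursors (25-residue signal, ~39-residue
pro-peptide ending in Gly, mature released at a Gly|Gln or Gly|Lys junction)
among random-ORF decoys, chitin-binding hevein-like decoys and
seven-cysteine near-misses.  The miner translates every record in six
frames, partitions each ORF at the rightmost topology-bearing junction, and
keeps matures that classify as ginsentide-like.
"""

from coffeetide.mining import filter_hits, mine_records
from coffeetide.synthdata import SyntheticConfig, generate_est_library

cfg = SyntheticConfig(seed=7, n_planted=20, n_decoys=200)
records, truth = generate_est_library(cfg)
print(f"library: {len(records)} records ({cfg.n_planted} planted, {cfg.n_decoys} decoys)")

hits = mine_records(records)
recovered = {h.record_id for h in hits} & set(truth.planted)
false_pos = {h.record_id for h in hits} - set(truth.planted)
print(f"mined hits: {len(hits)} | recovered {len(recovered)}/{cfg.n_planted} planted, "
      f"{len(false_pos)} false positives")

exact = sum(
    truth.planted[h.record_id].mature == h.precursor.mature for h in hits
)
print(f"mature sequences exactly matching ground truth: {exact}/{len(hits)}")

unique = filter_hits(hits, mass_window=(2000.0, 6000.0))
print(f"after 2-6 kDa mass filter and deduplication: {len(unique)} unique matures")
h = unique[0]
print(f"example hit: {h.record_id} frame {h.orf.frame:+d}, junction {h.precursor.junction_rule}, "
      f"mature {h.precursor.mature[:12]}... ({h.mass_mono_neutral:.1f} Da, charge {h.charge:+d})")
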