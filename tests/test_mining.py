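"""Six-frame ORF extraction, precursor partitioning, and EST mining."""

import pytest
from Bio.Seq import Seq

from coffeetide.mining import (
    MiningConfig,
    NucleotideRecord,
    filter_hits,
    mine_records,
    partition_precursor,
    six_frame_orfs,
)
from coffeetide.motif import LABEL_GINSENTIDE
from coffeetide.synthdata import SIGNAL_TEMPLATE, SyntheticConfig, generate_est_library


class TestRecordValidation:
    def test_rejects_non_nucleotide(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            NucleotideRecord("r", "ACGU")

    def test_rejects_excess_n(self):
        with pytest.raises(ValueError, match="N fraction"):
            NucleotideRecord("r", "ANNN")


class TestSixFrameOrfs:
    def test_simple_forward_orf(self):
        orfs = six_frame_orfs(NucleotideRecord("r", "ATGGGTTAA"), min_protein_length=1)
        forward = [o for o in orfs if o.frame > 0]
        assert len(forward) == 1
        assert forward[0].frame == 1
        assert forward[0].protein == "MG"
        assert forward[0].span == (0, 9)  # includes the stop codon

    def test_strand_symmetry(self):
        rc = str(Seq("ATGGGTTAA").reverse_complement())
        orfs = six_frame_orfs(NucleotideRecord("r", rc), min_protein_length=1)
        minus = [o for o in orfs if o.frame < 0]
        assert len(minus) == 1
        assert minus[0].protein == "MG"

    def test_too_short_record(self):
        assert six_frame_orfs(NucleotideRecord("r", "AC")) == []

    def test_truncated_orf_requires_flag(self):
        rec = NucleotideRecord("r", "ATGGGTGGT")  # no stop codon
        assert six_frame_orfs(rec, min_protein_length=1) == []
        orfs = six_frame_orfs(rec, min_protein_length=1, include_truncated=True)
        assert any(o.protein == "MGG" and not o.has_stop for o in orfs)

    def test_span_translation_reproduces_protein(self):
        """Invariant: translating the reported span (reverse-complemented for
        minus frames) gives the protein followed by a stop."""
        cfg = SyntheticConfig(seed=3, n_planted=5, n_decoys=5)
        records, _ = generate_est_library(cfg)
        checked = 0
        for rec in records:
            for orf in six_frame_orfs(rec):
                lo, hi = orf.span
                assert (hi - lo) % 3 == 0
                nt = rec.sequence[lo:hi]
                if orf.frame < 0:
                    nt = str(Seq(nt).reverse_complement())
                translated = str(Seq(nt).translate())
                assert translated == orf.protein + ("*" if orf.has_stop else "")
                assert orf.protein.startswith("M")
                checked += 1
        assert checked >= 5

    def test_planted_precursor_orf_recovered(self, peptides):
        cfg = SyntheticConfig(seed=11, n_planted=3, n_decoys=0)
        records, truth = generate_est_library(cfg)
        for rec in records:
            planted = truth.planted[rec.id]
            proteins = {o.protein for o in six_frame_orfs(rec)}
            assert any(p.endswith(planted.mature) for p in proteins)


class TestPartitionPrecursor:
    def _mature(self, peptides):
        return "Q" + peptides["cC4"].sequence[1:]

    def test_gq_junction_fires(self, peptides):
        mature = self._mature(peptides)
        protein = SIGNAL_TEMPLATE + "A" * 37 + "G" + mature
        model = partition_precursor(protein)
        assert model is not None
        assert model.mature == mature
        assert model.junction_rule == "G|Q"
        assert model.signal + model.pro + model.mature == protein

    def test_no_glycine_no_junction(self):
        assert partition_precursor("MAAAAQCCCCCCCCAAAA") is None

    def test_ginsentide_style_gc_junction(self):
        # mature beginning directly with CysI, released at a Gly|Cys junction
        mature = "CAAAACAAAACCAACACAAAAAACAAAAAAC"
        protein = SIGNAL_TEMPLATE + "A" * 30 + "G" + mature
        model = partition_precursor(protein, spacer_bounds=None)
        assert model is not None
        assert model.junction_rule == "G|C"
        assert model.mature.startswith("C")

    def test_rightmost_junction_wins(self, peptides):
        mature = self._mature(peptides)
        # two candidate G|Q junctions; only the rightmost yields a
        # window-compatible topology-bearing suffix
        protein = SIGNAL_TEMPLATE + "GQ" + "A" * 35 + "G" + mature
        model = partition_precursor(protein)
        assert model.mature == mature


class TestMineRecords:
    def test_default_library_recovers_all_planted(self):
        cfg = SyntheticConfig(seed=7)
        records, truth = generate_est_library(cfg)
        assert len(records) == cfg.n_planted + cfg.n_decoys
        hits = mine_records(records)
        assert {h.record_id for h in hits} == set(truth.planted)
        by_id = {h.record_id: h for h in hits}
        for rec_id, planted in truth.planted.items():
            assert by_id[rec_id].precursor.mature == planted.mature
            assert by_id[rec_id].precursor.junction_rule == planted.junction_rule

    def test_empty_library(self):
        assert mine_records([]) == []

    def test_chitin_decoy_library_yields_no_hits(self):
        cfg = SyntheticConfig(seed=5, n_planted=0, n_decoys=20, decoy_mix=(0.0, 1.0, 0.0))
        records, truth = generate_est_library(cfg)
        assert set(truth.decoy_kinds.values()) == {"chitin_hevein"}
        assert mine_records(records) == []

    def test_strand_symmetry_of_mining(self):
        cfg = SyntheticConfig(seed=13, n_planted=5, n_decoys=10)
        records, _ = generate_est_library(cfg)
        flipped = [r.reverse_complement() for r in records]
        matures = sorted(h.precursor.mature for h in mine_records(records))
        matures_rc = sorted(h.precursor.mature for h in mine_records(flipped))
        assert matures == matures_rc

    def test_hit_matures_reclassify_identically(self):
        from coffeetide.motif import classify_8c
        from coffeetide.physchem import Peptide

        cfg = SyntheticConfig(seed=2, n_planted=8, n_decoys=0)
        records, _ = generate_est_library(cfg)
        for hit in mine_records(records):
            assert classify_8c(Peptide(hit.precursor.mature)).label == LABEL_GINSENTIDE
            assert hit.classification.label == LABEL_GINSENTIDE

    def test_broken_record_is_skipped_not_fatal(self):
        class Exploding:
            id = "boom"
            sequence = property(lambda self: (_ for _ in ()).throw(RuntimeError))

        cfg = SyntheticConfig(seed=4, n_planted=2, n_decoys=0)
        records, _ = generate_est_library(cfg)
        hits = mine_records(records + [Exploding()])
        assert len(hits) == 2


class TestFilterHits:
    def test_table_matures_all_pass_mass_window(self, peptides):
        cfg = SyntheticConfig(seed=1, n_planted=10, n_decoys=0)
        records, _ = generate_est_library(cfg)
        hits = mine_records(records)
        assert filter_hits(hits, mass_window=(2000.0, 6000.0)) == [
            h for i, h in enumerate(hits) if h.precursor.mature not in
            {g.precursor.mature for g in hits[:i]}
        ]

    def test_mass_window_and_dedup(self, peptides):
        cfg = SyntheticConfig(seed=1, n_planted=10, n_decoys=0)
        records, _ = generate_est_library(cfg)
        hits = mine_records(records)
        # absurd window removes everything
        assert filter_hits(hits, mass_window=(100.0, 1200.0)) == []
        kept = filter_hits(hits + hits)
        assert len(kept) == len({h.precursor.mature for h in hits})
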