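"""Six-frame translation and anchor translate-and-extend."""

import pytest

from asmqc import fixtures
from asmqc.io_formats import AlignmentHit, Contig
from asmqc.orf_translate import (
    TranslatedContig,
    anchor_translate_extend,
    translate_assembly,
    translate_frame,
)


def _anchor_hit(qid, q_iv, qframe, sid="ref", slen=None):
    return AlignmentHit(
        qid=qid, sid=sid, pident=1.0, aln_len=(q_iv[1] - q_iv[0]) // 3,
        q_iv=q_iv, s_iv=(0, max(1, (q_iv[1] - q_iv[0]) // 3)),
        evalue=1e-30, bitscore=50.0, qframe=qframe, slen=slen,
    )


class TestTranslateFrame:
    @pytest.mark.parametrize(
        "seq,frame,expected",
        [
            ("ATGGCC", 1, "MA"),
            ("GGCCAT", -1, "MA"),
            ("TATGGCC", 2, "MA"),
            ("ATGTAA", 1, "M*"),
            ("ATGNCC", 1, "MX"),          # codon with N -> X
            ("ATGGC", 1, "M"),            # trailing partial codon dropped
            ("AAATGGCC", 3, "MA"),        # frame +3 offset
        ],
    )
    def test_examples(self, seq, frame, expected):
        assert translate_frame(seq, frame) == expected

    def test_all_six_frames_cover_reverse_complement(self):
        seq = "ATGGCTGCTTGA"
        assert translate_frame(seq, 1) == "MAA*"
        from Bio.Seq import reverse_complement

        for f in (1, 2, 3):
            assert translate_frame(seq, -f) == translate_frame(reverse_complement(seq), f)

    def test_too_short_after_offset_is_empty(self):
        assert translate_frame("ATG", 2) == ""
        assert translate_frame("ATG", 3) == ""

    def test_invalid_frame(self):
        with pytest.raises(ValueError, match="frame"):
            translate_frame("ATGGCC", 0)


class TestAnchorTranslateExtend:
    def test_worked_example_extends_to_stops(self):
        contig = Contig("c", "GGTAAATGGCTGCTTGAGG")
        t = anchor_translate_extend(contig, _anchor_hit("c", (8, 14), 3))
        assert t.peptide == "MAA"
        assert (t.q_start_nt, t.q_end_nt) == (5, 14)
        assert t.frame == 3

    def test_anchor_spanning_whole_contig_no_extension(self):
        contig = Contig("c", "ATGGCTGCT")
        t = anchor_translate_extend(contig, _anchor_hit("c", (0, 9), 1))
        assert t.peptide == translate_frame(contig.seq, 1) == "MAA"

    def test_no_flanking_stops_extends_to_outermost_codons(self):
        contig = Contig("c", "G" + "ATGGCTGCT" + "GG")
        t = anchor_translate_extend(contig, _anchor_hit("c", (4, 7), 2))
        assert t.peptide == translate_frame(contig.seq, 2)
        assert (t.q_start_nt, t.q_end_nt) == (1, 10)

    def test_negative_frame_worked_example(self):
        # reverse complement of the worked-example contig; frame flips sign
        from Bio.Seq import reverse_complement

        fwd = "GGTAAATGGCTGCTTGAGG"
        contig = Contig("c", reverse_complement(fwd))
        t = anchor_translate_extend(contig, _anchor_hit("c", (5, 11), -3))
        assert t.peptide == "MAA"
        assert (t.q_start_nt, t.q_end_nt) == (5, 14)

    def test_frame_required(self):
        contig = Contig("c", "ATGGCTGCT")
        hit = _anchor_hit("c", (0, 9), 1)
        hit = AlignmentHit(**{**hit.__dict__, "qframe": None})
        with pytest.raises(ValueError, match="frame required"):
            anchor_translate_extend(contig, hit)

    def test_anchor_outside_contig_rejected(self):
        contig = Contig("c", "ATGGCT")
        with pytest.raises(ValueError, match="outside contig"):
            anchor_translate_extend(contig, _anchor_hit("c", (0, 9), 1))

    def test_non_congruent_anchor_snapped(self):
        # anchor [9,13) is off the frame-3 codon grid; snapping outward
        # must not lose the anchored residues
        contig = Contig("c", "GGTAAATGGCTGCTTGAGG")
        t = anchor_translate_extend(contig, _anchor_hit("c", (9, 13), 3))
        assert t.peptide == "MAA"

    def test_non_congruent_anchor_strict_errors(self):
        contig = Contig("c", "GGTAAATGGCTGCTTGAGG")
        with pytest.raises(ValueError, match="not congruent"):
            anchor_translate_extend(contig, _anchor_hit("c", (9, 13), 3), strict=True)

    def test_stop_inside_anchor_truncates(self):
        #                 M  A  *  C
        contig = Contig("c", "ATGGCTTGATGC")
        t = anchor_translate_extend(contig, _anchor_hit("c", (0, 12), 1))
        assert t.peptide == "MA"
        assert (t.q_start_nt, t.q_end_nt) == (0, 6)

    def test_stop_inside_anchor_strict_errors(self):
        contig = Contig("c", "ATGGCTTGATGC")
        with pytest.raises(ValueError, match="stop codon inside anchor"):
            anchor_translate_extend(contig, _anchor_hit("c", (0, 12), 1), strict=True)

    def test_containment_and_stop_flanks_on_random_fixtures(self):
        """Every output peptide is a stop-free substring of the full-frame
        translation, and its flanking characters (when present) are '*'."""
        n_checked = 0
        for seed in range(25):
            truth = fixtures.make_reference(4, min_aa=30, max_aa=100, seed=seed)
            contigs, hits, _ = fixtures.fragment_assembly(truth, fragments_per_gene=2, seed=seed)
            by_id = {c.id: c for c in contigs}
            for h in hits:
                c = by_id[h.qid]
                t = anchor_translate_extend(c, h)
                full = translate_frame(c.seq, t.frame)
                off = abs(t.frame) - 1
                if t.frame > 0:
                    aa_pos = (t.q_start_nt - off) // 3
                else:
                    aa_pos = (len(c.seq) - t.q_end_nt - off) // 3
                assert full[aa_pos : aa_pos + len(t.peptide)] == t.peptide
                assert "*" not in t.peptide
                if aa_pos > 0:
                    assert full[aa_pos - 1] == "*"
                if aa_pos + len(t.peptide) < len(full):
                    assert full[aa_pos + len(t.peptide)] == "*"
                n_checked += 1
        assert n_checked >= 100


class TestTranslateAssembly:
    def test_recovers_planted_peptides(self, small_truth):
        contigs, hits, _ = fixtures.fragment_assembly(small_truth, full_length=True, seed=2)
        translated, stats = translate_assembly(contigs, hits, min_aa=1)
        recovered = {t.contig_id.rsplit("_", 1)[0]: t.peptide for t in translated}
        assert recovered == small_truth.proteins
        assert stats.n_contigs == len(small_truth.proteins)

    def test_identical_peptides_deduplicated(self):
        seq = "TAAATGGCTGCTAAATAA"  # *MAAK... frame1: "*MAAK*"? keep simple
        c1, c2 = Contig("a", seq), Contig("b", seq)
        hits = [_anchor_hit("a", (3, 12), 1), _anchor_hit("b", (3, 12), 1)]
        translated, stats = translate_assembly([c1, c2], hits, min_aa=1)
        assert len(translated) == 1
        assert stats.redundancy == pytest.approx(0.5)

    def test_min_aa_filter_excludes_short_peptides(self, small_truth):
        contigs, hits, _ = fixtures.fragment_assembly(small_truth, full_length=True, seed=2)
        lengths = sorted(len(p) for p in small_truth.proteins.values())
        cutoff = lengths[len(lengths) // 2]
        translated, _ = translate_assembly(contigs, hits, min_aa=cutoff)
        assert all(len(t.peptide) >= cutoff for t in translated)
        assert len(translated) == sum(1 for n in lengths if n >= cutoff)

    def test_best_hit_chosen_per_contig(self):
        contig = Contig("c", "GGTAAATGGCTGCTTGAGG")
        good = _anchor_hit("c", (8, 14), 3)
        bad = AlignmentHit(**{**_anchor_hit("c", (0, 6), 1).__dict__, "bitscore": 1.0})
        translated, _ = translate_assembly([contig], [bad, good], min_aa=1)
        assert translated[0].peptide == "MAA"

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            translate_assembly([Contig("a", "ATGGCT")], [_anchor_hit("zz", (0, 6), 1)])

    def test_determinism(self, small_truth):
        contigs, hits, _ = fixtures.fragment_assembly(small_truth, seed=4)
        a = translate_assembly(contigs, hits, min_aa=1)
        b = translate_assembly(contigs, hits, min_aa=1)
        assert a == b


class TestTranslatedContigInvariants:
    def test_interval_must_be_three_times_peptide(self):
        with pytest.raises(ValueError, match="3 x peptide"):
            TranslatedContig("c", 1, "MA", 0, 5)

    def test_no_internal_stop_allowed(self):
        with pytest.raises(ValueError, match="internal stop"):
            TranslatedContig("c", 1, "M*A", 0, 9)
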