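"""ORF enumeration, architecture inference and layout arithmetic."""

import numpy as np
import pytest

from polycipi.orf_layout import (
    STOP_CODONS,
    find_orfs,
    five_prime_signature,
    infer_layout,
    layout_stats,
    strip_polya,
)
from polycipi.seqio import GenomeRecord
from polycipi.synthetic import GenomeSpec, generate_genome, generate_decoys

from conftest import compact_spec


def _record(seq: str, gid: str = "g") -> GenomeRecord:
    return GenomeRecord(id=gid, description="", seq=seq)


class TestStripPolya:
    def test_long_tail_removed(self):
        rec = strip_polya(_record("ATGGCT" + "A" * 25))
        assert rec.seq == "ATGGCT"
        assert rec.polya_trimmed_len == 25
        assert rec.extends_to_polya

    def test_short_run_untouched(self):
        rec = strip_polya(_record("ATGGCT" + "A" * 5))
        assert rec.seq.endswith("A" * 5)
        assert not rec.extends_to_polya

    def test_planted_tail_recovers_body_length(self):
        spec = compact_spec(seed=3, polya_len=30)
        rec, layout, _ = generate_genome(spec)
        stripped = strip_polya(rec)
        assert len(stripped.seq) == layout.seq_len
        assert stripped.polya_trimmed_len == 30

    def test_original_length_recoverable(self):
        rec = strip_polya(_record("ATGGCT" + "A" * 12))
        assert len(rec.seq) + rec.polya_trimmed_len == 18


def _brute_force_orfs(seq: str, min_len: int):
    """Quadratic reference: all (ATG, first in-frame stop) spans."""
    out = set()
    n = len(seq)
    for frame in range(3):
        starts = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] == "ATG"]
        stops = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        for stop in stops:
            cands = [
                a
                for a in starts
                if a < stop and not any(a < x < stop for x in stops)
            ]
            if cands:
                a = min(cands)  # 5'-most ATG for this stop
                if stop + 3 - a >= min_len:
                    out.add((a + 1, stop + 3))
    return out


class TestFindOrfs:
    def test_minimal_orf(self):
        (orf,) = find_orfs("ATGAAATAA", min_len_nt=9)
        assert (orf.start, orf.end) == (1, 9)
        assert orf.peptide == "MK"

    def test_no_atg_empty(self):
        assert find_orfs("CCCCCCCCCTAACCC", min_len_nt=9) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        got = {(o.start, o.end) for o in find_orfs(seq, min_len_nt=90)}
        assert got == _brute_force_orfs(seq, 90)

    def test_rejects_non_multiple_of_three_min_len(self):
        with pytest.raises(ValueError):
            find_orfs("ATGAAATAA", min_len_nt=100)


class TestFivePrimeSignature:
    def test_au_rich_ttt_start(self):
        assert five_prime_signature("TTT" + "AT" * 11 + "GGGG")

    def test_gc_start_false(self):
        assert not five_prime_signature("GGG" + "AT" * 20)

    def test_generator_flag_round_trip(self):
        with_sig, _, _ = generate_genome(compact_spec(seed=5, five_prime_signature=True))
        without, _, _ = generate_genome(compact_spec(seed=5, five_prime_signature=False))
        assert five_prime_signature(with_sig.seq)
        assert not five_prime_signature(without.seq)


class TestInferLayout:
    def test_round_trip_on_generated_genome(self, sinv2_like):
        rec, layout, _ = sinv2_like
        inf = infer_layout(rec)
        assert inf.polycipivirus_like
        got = {o.orf_id: (o.start, o.end) for o in inf.layout.orfs}
        want = {o.orf_id: (o.start, o.end) for o in layout.orfs}
        assert got == want

    def test_sinv2_junction_overlap_within_constraints(self, table_rows):
        row = next(r for r in table_rows if r.name == "SINV-2")
        stats = layout_stats(row)
        assert stats.junction_gaps["ORF1->ORF2"] == -4
        assert all(-20 <= g <= 60 for g in stats.junction_gaps.values())

    def test_dicistro_decoy_not_polycipivirus_like(self):
        (decoy,) = generate_decoys("dicistro_like", 1, seed=11)
        inf = infer_layout(decoy)
        assert not inf.polycipivirus_like
        assert any("upstream_chain_missing" in e for e in inf.evidence)

    def test_invariant_to_polya_tail(self):
        spec = compact_spec(seed=9)
        rec, _, _ = generate_genome(spec)
        body = rec.seq[: len(rec.seq) - spec.polya_len]
        for tail in (0, 15, 80):
            inf = infer_layout(_record(body + "A" * tail))
            assert inf.polycipivirus_like
            assert inf.layout.seq_len == len(body)
            assert inf.layout.utr3_len == spec.utr3_len

    def test_orf_annotations_satisfy_frame_invariants(self, sinv2_like):
        rec, _, _ = sinv2_like
        inf = infer_layout(rec)
        seq = strip_polya(rec).seq
        for o in inf.layout.orfs:
            assert (o.end - o.start + 1) % 3 == 0
            assert seq[o.start - 1 : o.start + 2] == "ATG"
            assert seq[o.end - 3 : o.end] in STOP_CODONS
            assert len(o.peptide) == (o.end - o.start + 1) // 3 - 1

    def test_orf3a_bridging(self):
        from polycipi.synthetic import Orf3aSpec

        spec = compact_spec(seed=13, orf3a=Orf3aSpec(length=210, gap_before=-4, gap_after=-4))
        rec, layout, _ = generate_genome(spec)
        inf = infer_layout(rec)
        assert inf.polycipivirus_like
        assert "orf3a_bridge" in inf.evidence
        assert (inf.layout.orf("ORF3a").start, inf.layout.orf("ORF3a").end) == (
            layout.orf("ORF3a").start,
            layout.orf("ORF3a").end,
        )


class TestDetectOrf2b:
    def test_planted_hydrophobic_core_detected(self):
        rec, layout, _ = generate_genome(compact_spec(seed=21))
        inf = infer_layout(rec)
        got = inf.layout.orf("ORF2b")
        want = layout.orf("ORF2b")
        assert got is not None and (got.start, got.end) == (want.start, want.end)
        assert got.frame_offset_vs_orf5 == want.frame_offset_vs_orf5

    def test_scrambled_core_not_detected(self):
        from polycipi.synthetic import Orf2bSpec

        spec = compact_spec(seed=21, orf2b=Orf2bSpec(offset=4, length=210, hydrophobic_core=False))
        rec, _, _ = generate_genome(spec)
        inf = infer_layout(rec)
        assert inf.layout.orf("ORF2b") is None

    def test_wrong_frame_rejected(self):
        from polycipi.orf_layout import OrfAnnotation, GenomeLayout, detect_orf2b

        layout = GenomeLayout(genome_id="g", seq_len=3000, orfs=[OrfAnnotation("ORF2", 100, 700)])
        # candidate in frame +2 relative to ORF2 (offset ≡ 2 mod 3)
        cand = OrfAnnotation("", 105, 404, peptide="I" * 99)
        assert detect_orf2b(layout, "", candidates=[cand], tm_predictor=lambda p: True) is None
        # same offset but ≡ 1 mod 3 is accepted
        cand_ok = OrfAnnotation("", 104, 403, peptide="I" * 99)
        got = detect_orf2b(layout, "", candidates=[cand_ok], tm_predictor=lambda p: True)
        assert got is not None and got.orf_id == "ORF2b"


class TestLayoutStats:
    def test_sinv2_printed_values(self, table_rows):
        row = next(r for r in table_rows if r.name == "SINV-2")
        stats = layout_stats(row)
        assert (stats.utr5_len, stats.igr_len, stats.utr3_len) == (301, 662, 387)

    def test_orf1_at_position_one_gives_zero_utr5(self):
        from polycipi.orf_layout import GenomeLayout, OrfAnnotation

        layout = GenomeLayout(
            genome_id="g",
            seq_len=9000,
            orfs=[
                OrfAnnotation("ORF1", 1, 300),
                OrfAnnotation("ORF4", 1200, 2000 - 2),
                OrfAnnotation("ORF5", 2500, 8500),
            ],
        )
        assert layout_stats(layout).utr5_len == 0

    def test_every_printed_cell_reproduced(self, table_rows):
        for row in table_rows:
            stats = layout_stats(row)
            assert stats.igr_len == row.igr_len, row.name
            assert stats.utr5_len == row.utr5_len, row.name
            assert stats.utr3_len == row.utr3_len, row.name

    def test_negative_igr_is_error(self):
        from polycipi.orf_layout import GenomeLayout, OrfAnnotation

        layout = GenomeLayout(
            genome_id="g",
            seq_len=9000,
            orfs=[OrfAnnotation("ORF4", 100, 399), OrfAnnotation("ORF5", 300, 8999)],
        )
        with pytest.raises(ValueError, match="negative intergenic"):
            layout_stats(layout)

    def test_frame_offsets_match_figure_convention(self, table_rows):
        row = next(r for r in table_rows if r.name == "SINV-2")
        offsets = layout_stats(row).frame_offsets
        assert offsets["ORF5"] == 0
        assert set(offsets.values()) <= {-1, 0, +1}
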