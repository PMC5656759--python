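"""Translation, alignment (with brute-force oracle), E-values, search, RBH."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from polycipi.homology import (
    evalue,
    global_align,
    local_align,
    longest_orf_peptide,
    rbh_filter,
    search,
    six_frame_translate,
    translate,
)
from polycipi.seqio import GenomeRecord
from polycipi.synthetic import generate_decoys, generate_genome, mutate_genome

from conftest import compact_spec

AA = "ACDEFGHIKLMNPQRSTVWY"
B62 = substitution_matrices.load("BLOSUM62")


def brute_global(q: str, s: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Exhaustive affine-gap global optimum (gap of length L costs open+L·extend)."""
    OPEN, EXT = -(gap_open + gap_extend), -gap_extend

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == len(q) and j == len(s):
            return 0.0
        out = -math.inf
        if i < len(q) and j < len(s):
            out = max(out, B62[q[i], s[j]] + best(i + 1, j + 1, 0))
        if i < len(q):
            out = max(out, (EXT if state == 1 else OPEN) + best(i + 1, j, 1))
        if j < len(s):
            out = max(out, (EXT if state == 2 else OPEN) + best(i, j + 1, 2))
        return out

    return best(0, 0, 0)


def brute_local(q: str, s: str) -> float:
    """Local optimum as the best global score over all substring pairs."""
    best = 0.0
    for i, j in itertools.product(range(len(q)), range(len(s))):
        for k, l in itertools.product(range(i + 1, len(q) + 1), range(j + 1, len(s) + 1)):
            best = max(best, brute_global(q[i:k], s[j:l]))
    return best


class TestTranslate:
    def test_simple_frame1(self):
        assert translate("ATGAAATAA", 1) == "MK*"

    def test_partial_codon_dropped(self):
        assert translate("ATGAAAT", 1) == "MK"

    @pytest.mark.parametrize("frame", [1, 2, 3])
    def test_reverse_frames_equal_forward_of_revcomp(self, frame):
        rng = np.random.default_rng(frame)
        seq = "".join(rng.choice(list("ACGT"), size=99))
        rc = str(Seq(seq).reverse_complement())
        assert translate(seq, -frame) == translate(rc, frame)

    def test_all_64_codons_against_hardcoded_table(self):
        # independent oracle: the standard genetic code written out
        code = {}
        bases, aas = "TCAG", "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        for i, (b1, b2, b3) in enumerate(itertools.product(bases, repeat=3)):
            code[b1 + b2 + b3] = aas[i]
        for codon, aa in code.items():
            assert translate(codon, 1) == aa

    def test_six_frames_present(self):
        frames = six_frame_translate("ATGAAATAA")
        assert set(frames) == {1, 2, 3, -1, -2, -3}


class TestLongestOrfPeptide:
    def test_minimal(self):
        assert longest_orf_peptide("ATGTAA") == "M"

    def test_forward_preferred_on_tie(self):
        fwd = "ATGAAATAA"  # MK, and its reverse complement has an equal-length ORF
        seq = fwd + "CC" + str(Seq("ATGCCCTAA").reverse_complement())
        pep = longest_orf_peptide(seq)
        assert pep in ("MK", "MP")
        # explicit tie: forward MK vs reverse MK of same length
        assert longest_orf_peptide("ATGAAATAACCTTATTTCAT") == "MK"

    def test_generator_longest_is_orf5(self):
        rec, layout, _ = generate_genome(compact_spec(seed=51))
        assert longest_orf_peptide(rec.seq) == layout.orf("ORF5").peptide

    def test_no_orf_empty(self):
        assert longest_orf_peptide("CCCCCCCC") == ""


class TestAlignment:
    def test_identical_peptides(self):
        pep = "MKWVTFISLLLLFSSAYS"
        res = global_align(pep, pep)
        assert res.pct_identity == 100.0
        assert res.score == pytest.approx(sum(B62[a, a] for a in pep))
        assert res.columns == len(pep)

    def test_identity_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = "".join(rng.choice(list(AA), size=30))
            b = "".join(rng.choice(list(AA), size=25))
            assert global_align(a, b).pct_identity == pytest.approx(global_align(b, a).pct_identity)

    @pytest.mark.parametrize("seed", range(20))
    def test_scores_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        q = "".join(rng.choice(list(AA), size=rng.integers(2, 7)))
        s = "".join(rng.choice(list(AA), size=rng.integers(2, 7)))
        assert global_align(q, s).score == pytest.approx(brute_global(q, s))
        assert local_align(q, s).score == pytest.approx(brute_local(q, s))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MK")


class TestEvalue:
    def test_zero_score_closed_form(self):
        assert evalue(0, 100, 1000) == pytest.approx(0.041 * 100 * 1000)

    def test_linear_in_n(self):
        assert evalue(50, 100, 2000) == pytest.approx(2 * evalue(50, 100, 1000))

    def test_threshold_inversion(self):
        m, n = 500, 2_000_000
        s_crit = math.log(0.041 * m * n * 1e6) / 0.267
        assert evalue(s_crit + 1e-6, m, n) < 1e-6 < evalue(s_crit - 1e-6, m, n)

    def test_monotone_decreasing(self):
        es = [evalue(s, 200, 1000) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestSearch:
    def test_exact_member_ranks_first(self):
        rng = np.random.default_rng(1)
        panel = [(f"p{i}", "".join(rng.choice(list(AA), size=50))) for i in range(4)]
        hits = search(panel[2][1], panel)
        assert hits[0].subject_id == "p2"
        assert hits[0].pct_identity == 100.0

    def test_ranking_invariant_under_panel_permutation(self):
        rng = np.random.default_rng(2)
        panel = [(f"p{i}", "".join(rng.choice(list(AA), size=40))) for i in range(6)]
        query = "".join(rng.choice(list(AA), size=40))
        ranked = [h.subject_id for h in search(query, panel)]
        for seed in range(5):
            perm = list(np.random.default_rng(seed).permutation(len(panel)))
            assert [h.subject_id for h in search(query, [panel[i] for i in perm])] == ranked

    def test_empty_panel_error(self):
        with pytest.raises(ValueError):
            search("MK", [])


@pytest.fixture(scope="module")
def rbh_world():
    """A reference genome, dicistro-like decoys, and a shared panel."""
    from polycipi.homology import longest_orf_peptide
    from polycipi.synthetic import GenomeSpec

    ref, _, truth = generate_genome(GenomeSpec(seed=61), genome_id="REF")
    decoys, decoy_truths = generate_decoys("dicistro_like", 2, seed=62, with_truth=True)
    panel = [("REF", longest_orf_peptide(ref.seq))] + [
        (d.id, longest_orf_peptide(d.seq)) for d in decoys
    ]
    return ref, truth, decoys, decoy_truths, panel


class TestRbhFilter:
    def test_reference_derived_candidate_retained(self, rbh_world):
        ref, truth, _, _, panel = rbh_world
        rng = np.random.default_rng(63)
        cand = mutate_genome(ref, 0.03, rng, truth=truth, new_id="cand")
        (dec,) = rbh_filter([cand], {"REF"}, panel)
        assert dec.retained and dec.reason == "reciprocal_best"
        assert dec.fwd_best.subject_id == "REF"

    def test_decoy_derived_candidate_discarded(self, rbh_world):
        _, _, decoys, decoy_truths, panel = rbh_world
        rng = np.random.default_rng(64)
        cand = mutate_genome(decoys[0], 0.03, rng, truth=decoy_truths[0], new_id="cand_decoy")
        (dec,) = rbh_filter([cand], {"REF"}, panel)
        assert not dec.retained and dec.reason == "wrong_best_target"

    def test_short_candidate_discarded(self, rbh_world):
        _, _, _, _, panel = rbh_world
        (short,) = generate_decoys("random", 1, seed=65, length=8000)
        (dec,) = rbh_filter([short], {"REF"}, panel)
        assert not dec.retained and dec.reason == "too_short"

    def test_verdicts_invariant_under_candidate_order(self, rbh_world):
        ref, truth, decoys, decoy_truths, panel = rbh_world
        rng = np.random.default_rng(66)
        cands = [
            mutate_genome(ref, 0.03, rng, truth=truth, new_id="good"),
            mutate_genome(decoys[1], 0.03, rng, truth=decoy_truths[1], new_id="bad"),
        ]
        fwd = {d.candidate_id: (d.retained, d.reason) for d in rbh_filter(cands, {"REF"}, panel)}
        rev = {d.candidate_id: (d.retained, d.reason) for d in rbh_filter(cands[::-1], {"REF"}, panel)}
        assert fwd == rev

    def test_empty_panel_error(self):
        with pytest.raises(ValueError):
            rbh_filter([GenomeRecord(id="c", description="", seq="ATG")], {"REF"}, [])
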