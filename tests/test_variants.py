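"""SNP filtering/classification and coverage summarization."""

import itertools

import numpy as np
import pytest

from polycipi.orf_layout import strip_polya
from polycipi.seqio import GenomeRecord, PileupPosition
from polycipi.synthetic import generate_genome, simulate_pileup
from polycipi.variants import (
    SnpRecord,
    aggregate_counts,
    classify_snp,
    coverage_windows,
    filter_snps,
    mean_coverage,
)

from conftest import compact_spec

# independent oracle: the standard genetic code written out
_BASES_TCAG = "TCAG"
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = {
    b1 + b2 + b3: _AA_STRING[i]
    for i, (b1, b2, b3) in enumerate(itertools.product(_BASES_TCAG, repeat=3))
}


@pytest.fixture(scope="module")
def genome_world():
    rec, layout, _ = generate_genome(compact_spec(seed=91))
    return strip_polya(rec), layout


def _pileup_row(gid, pos, depth, **counts):
    c = {"A": 0, "C": 0, "G": 0, "T": 0}
    c.update(counts)
    return {(gid, pos): PileupPosition(depth=depth, counts=c)}


class TestFilterSnps:
    def test_strict_threshold(self, genome_world):
        genome, _ = genome_world
        ref = genome.seq[9]  # position 10
        alt = next(b for b in "ACGT" if b != ref)
        at_009 = _pileup_row(genome.id, 10, 1000, **{ref: 910, alt: 90})
        at_101 = _pileup_row(genome.id, 10, 1000, **{ref: 899, alt: 101})
        assert filter_snps(at_009, genome) == []
        (snp,) = filter_snps(at_101, genome)
        assert (snp.pos, snp.alt, snp.alt_frac) == (10, alt, pytest.approx(0.101))

    def test_id_mismatch_error(self, genome_world):
        genome, _ = genome_world
        with pytest.raises(ValueError, match="does not match"):
            filter_snps(_pileup_row("other", 10, 10, A=10), genome)

    def test_simulated_snps_recovered_exactly(self, genome_world):
        genome, _ = genome_world
        rng = np.random.default_rng(92)
        positions = sorted(int(p) for p in rng.choice(np.arange(50, len(genome.seq) - 50), 12, replace=False))
        snps = []
        for p in positions:
            ref = genome.seq[p - 1]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            snps.append((p, alt, 0.25))
        pileup, _ = simulate_pileup(genome, mean_depth=500, snps=snps, seed=93)
        recovered = filter_snps(pileup, genome)
        assert [(r.pos, r.alt) for r in recovered] == [(p, a) for p, a, _ in snps]

    def test_order_independent(self, genome_world):
        genome, _ = genome_world
        ref = genome.seq[0]
        alt = next(b for b in "ACGT" if b != ref)
        pile = {}
        pile.update(_pileup_row(genome.id, 1, 100, **{ref: 50, alt: 50}))
        ref2 = genome.seq[4]
        alt2 = next(b for b in "ACGT" if b != ref2)
        pile.update(_pileup_row(genome.id, 5, 100, **{ref2: 50, alt2: 50}))
        fwd = filter_snps(pile, genome)
        rev = filter_snps(dict(reversed(list(pile.items()))), genome)
        assert fwd == rev


class TestClassifySnp:
    def test_third_position_synonymous(self, genome_world):
        genome, layout = genome_world
        orf5 = layout.orf("ORF5")
        # find a GGN codon (glycine is fourfold degenerate) inside ORF5
        for ci in range((orf5.length_nt // 3) - 1):
            cs = orf5.start + 3 * ci
            if genome.seq[cs - 1 : cs + 1] == "GG":
                pos = cs + 2
                ref = genome.seq[pos - 1]
                alt = next(b for b in "ACGT" if b != ref)
                (call,) = classify_snp(SnpRecord(genome.id, pos, ref, alt, 100, 0.2), layout, genome)
                assert call.effect == "synonymous"
                assert call.orf_id == "ORF5"
                return
        pytest.skip("no glycine codon found (not expected)")

    def test_overlap_yields_one_call_per_orf(self, genome_world):
        genome, layout = genome_world
        o1, o2 = layout.orf("ORF1"), layout.orf("ORF2")
        assert o2.start < o1.end  # 4-nt overlap by construction
        pos = o2.start  # inside both ORFs
        ref = genome.seq[pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        calls = classify_snp(SnpRecord(genome.id, pos, ref, alt, 100, 0.2), layout, genome)
        assert sorted(c.orf_id for c in calls) == ["ORF1", "ORF2"]

    def test_noncoding_position(self, genome_world):
        genome, layout = genome_world
        pos = 5  # inside the 5'UTR
        ref = genome.seq[pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        (call,) = classify_snp(SnpRecord(genome.id, pos, ref, alt, 100, 0.2), layout, genome)
        assert call.effect == "noncoding" and call.orf_id == ""

    def test_all_576_codon_substitutions_match_oracle(self):
        """Exhaustive 64-codon × 9-substitution check against the code table."""
        from polycipi.orf_layout import GenomeLayout, OrfAnnotation

        for codon in GENETIC_CODE:
            if GENETIC_CODE[codon] == "*":
                continue  # a stop cannot be an internal reference codon
            seq = "ATG" + codon + "TAA"
            genome = GenomeRecord(id="g", description="", seq=seq)
            layout = GenomeLayout(genome_id="g", seq_len=9, orfs=[OrfAnnotation("ORF1", 1, 9)])
            for offset, alt in itertools.product(range(3), "ACGT"):
                if codon[offset] == alt:
                    continue
                pos = 4 + offset
                mutated = codon[:offset] + alt + codon[offset + 1 :]
                (call,) = classify_snp(
                    SnpRecord("g", pos, codon[offset], alt, 100, 0.5), layout, genome
                )
                aa_ref, aa_alt = GENETIC_CODE[codon], GENETIC_CODE[mutated]
                if aa_ref == aa_alt:
                    expected = "synonymous"
                elif "*" in (aa_ref, aa_alt):
                    expected = "stop_affecting"
                else:
                    expected = "nonsynonymous"
                assert call.effect == expected, (codon, pos, alt)

    def test_ref_equals_alt_error(self, genome_world):
        genome, layout = genome_world
        with pytest.raises(ValueError):
            SnpRecord(genome.id, 10, "A", "A", 100, 0.5)


class TestAggregateCounts:
    def test_published_per_orf_pairs_sum(self):
        pairs = {"ORF1": (5, 22), "ORF2": (3, 3), "ORF3": (7, 7), "ORF4": (8, 8), "ORF5": (39, 47)}
        agg = aggregate_counts(pairs)
        assert (agg.synonymous, agg.total) == (62, 87)

    def test_empty_calls_all_zero(self):
        agg = aggregate_counts([])
        assert (agg.synonymous, agg.total, agg.noncoding) == (0, 0, 0)

    def test_totals_equal_sum_of_pairs_random_calls(self, genome_world):
        genome, layout = genome_world
        rng = np.random.default_rng(94)
        calls = []
        for _ in range(200):
            pos = int(rng.integers(1, len(genome.seq) + 1))
            ref = genome.seq[pos - 1]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            calls.extend(classify_snp(SnpRecord(genome.id, pos, ref, alt, 100, 0.2), layout, genome))
        agg = aggregate_counts(calls)
        assert agg.synonymous == sum(s for s, _ in agg.per_orf.values())
        assert agg.total == sum(t for _, t in agg.per_orf.values())
        assert agg.total + agg.noncoding == len(calls)


class TestCoverage:
    def test_uniform_depth(self):
        pile = {("g", p): PileupPosition(depth=50, counts={"A": 50, "C": 0, "G": 0, "T": 0}) for p in range(1, 501)}
        cw = coverage_windows(pile, 500, window=100)
        assert np.allclose(cw, 50.0)
        assert mean_coverage(pile, 500) == pytest.approx(50.0)

    def test_window_means_match_naive(self):
        rng = np.random.default_rng(95)
        depths = rng.integers(0, 100, size=400)
        pile = {("g", p + 1): PileupPosition(depth=int(d), counts={"A": int(d), "C": 0, "G": 0, "T": 0}) for p, d in enumerate(depths)}
        window = 51
        got = coverage_windows(pile, 400, window=window)
        h = window // 2
        naive = [depths[max(0, i - h) : min(400, i + h + 1)].mean() for i in range(400)]
        assert np.allclose(got, naive)

    def test_simulator_hits_target_mean_depth(self, genome_world):
        genome, _ = genome_world
        pileup, _ = simulate_pileup(genome, mean_depth=1348, snps=[], seed=96)
        assert mean_coverage(pileup, len(genome.seq)) == pytest.approx(1348, rel=0.03)
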