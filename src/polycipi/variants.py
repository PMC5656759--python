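"""Coverage summarization and SNP filtering/classification from pileups.

Read mapping itself is out of scope; the per-position pileup TSV is the
contract (any mapper's output can be converted, and the packaged simulator
produces it directly). Variants present in strictly more than ``min_frac``
of reads are kept — the threshold is deliberately strict, matching a
">10 % of reads" rule. A SNP falling inside overlapping ORFs gets one
synonymous/nonsynonymous call per containing main ORF; the overlapping
accessory ORFs (ORF2b, ORF3a) are excluded from the per-ORF tallies by
default and can be opted in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio.Seq import Seq

from .orf_layout import GenomeLayout
from .seqio import GenomeRecord, PileupPosition

MAIN_ORFS = ("ORF1", "ORF2", "ORF3", "ORF4", "ORF5")
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SnpRecord:
    genome_id: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_frac: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not 0.0 < self.alt_frac <= 1.0:
            raise ValueError("alt_frac must be in (0, 1]")


@dataclass(frozen=True)
class SnpCall:
    snp: SnpRecord
    orf_id: str  # "" for noncoding
    codon_index: int  # 0-based codon within the ORF; -1 for noncoding
    effect: str  # synonymous | nonsynonymous | stop_affecting | noncoding


def filter_snps(
    pileup: Mapping[tuple[str, int], PileupPosition],
    ref_genome: GenomeRecord,
    min_frac: float = 0.10,
    min_depth: int = 1,
) -> list[SnpRecord]:
    """Call SNPs with alternative-allele fraction strictly above ``min_frac``.

    One record per (position, alternative base); the reference base comes
    from the genome. Pileup entries for a different genome id are an error.
    """
    records: list[SnpRecord] = []
    for (gid, pos), p in pileup.items():
        if gid != ref_genome.id:
            raise ValueError(f"pileup genome id {gid!r} does not match genome {ref_genome.id!r}")
        if not 1 <= pos <= len(ref_genome.seq):
            raise ValueError(f"pileup position {pos} outside genome of length {len(ref_genome.seq)}")
        if p.depth < min_depth or p.depth == 0:
            continue
        ref = ref_genome.seq[pos - 1]
        for alt in _BASES:
            if alt == ref:
                continue
            frac = p.counts.get(alt, 0) / p.depth
            if frac > min_frac:
                records.append(SnpRecord(ref_genome.id, pos, ref, alt, p.depth, frac))
    records.sort(key=lambda r: (r.pos, r.alt))
    return records


def classify_snp(
    snp: SnpRecord,
    layout: GenomeLayout,
    genome: GenomeRecord,
    include_accessory: bool = False,
) -> list[SnpCall]:
    """Synonymous/nonsynonymous classification, one call per containing ORF.

    The codon is identified from each ORF's own frame; substitutions
    preserving the encoded amino acid are synonymous, ones creating or
    destroying a stop codon are ``stop_affecting``, anything else is
    nonsynonymous. A position outside every considered ORF yields a single
    ``noncoding`` call.
    """
    if snp.ref == snp.alt:
        raise ValueError("ref and alt must differ")
    if genome.seq[snp.pos - 1] != snp.ref:
        raise ValueError(f"reference base mismatch at {snp.pos}: genome has {genome.seq[snp.pos - 1]}")
    orf_ids = set(MAIN_ORFS) | ({"ORF2b", "ORF3a"} if include_accessory else set())
    calls: list[SnpCall] = []
    for orf in layout.orfs:
        if orf.orf_id not in orf_ids:
            continue
        if not orf.start <= snp.pos <= orf.end:
            continue
        offset = snp.pos - orf.start
        codon_index = offset // 3
        codon_start = orf.start + 3 * codon_index
        codon = genome.seq[codon_start - 1 : codon_start + 2]
        mutated = list(codon)
        mutated[offset % 3] = snp.alt
        mutated = "".join(mutated)
        aa_ref = str(Seq(codon).translate(table=1))
        aa_alt = str(Seq(mutated).translate(table=1))
        if aa_ref == aa_alt:
            effect = "synonymous"
        elif "*" in (aa_ref, aa_alt):
            effect = "stop_affecting"
        else:
            effect = "nonsynonymous"
        calls.append(SnpCall(snp, orf.orf_id, codon_index, effect))
    if not calls:
        calls.append(SnpCall(snp, "", -1, "noncoding"))
    return calls


@dataclass
class SnpCounts:
    per_orf: dict[str, tuple[int, int]]  # orf -> (synonymous, total coding calls)
    synonymous: int
    total: int
    noncoding: int

    def pair(self, orf_id: str) -> tuple[int, int]:
        return self.per_orf.get(orf_id, (0, 0))


def aggregate_counts(
    calls: Iterable[SnpCall] | Mapping[str, tuple[int, int]],
) -> SnpCounts:
    """Per-ORF (synonymous, total) pairs and grand totals.

    Accepts either classified calls or an already-tallied mapping of
    per-ORF ``(synonymous, total)`` pairs (e.g. a published table), which
    is then just summed. Noncoding calls are counted separately and do not
    enter the coding totals.
    """
    if isinstance(calls, Mapping):
        per_orf = {k: (int(s), int(t)) for k, (s, t) in calls.items()}
        noncoding = 0
    else:
        per_orf_syn: dict[str, int] = {}
        per_orf_tot: dict[str, int] = {}
        noncoding = 0
        for call in calls:
            if call.effect == "noncoding":
                noncoding += 1
                continue
            per_orf_tot[call.orf_id] = per_orf_tot.get(call.orf_id, 0) + 1
            if call.effect == "synonymous":
                per_orf_syn[call.orf_id] = per_orf_syn.get(call.orf_id, 0) + 1
        per_orf = {o: (per_orf_syn.get(o, 0), per_orf_tot[o]) for o in per_orf_tot}
    synonymous = sum(s for s, _ in per_orf.values())
    total = sum(t for _, t in per_orf.values())
    return SnpCounts(per_orf=per_orf, synonymous=synonymous, total=total, noncoding=noncoding)


def _depth_array(
    pileup: Mapping[tuple[str, int], PileupPosition],
    genome_len: int,
) -> np.ndarray:
    depth = np.zeros(genome_len)
    for (_, pos), p in pileup.items():
        if 1 <= pos <= genome_len:
            depth[pos - 1] = p.depth
    return depth


def coverage_windows(
    pileup: Mapping[tuple[str, int], PileupPosition],
    genome_len: int,
    window: int = 1000,
) -> np.ndarray:
    """Centered sliding-window mean depth, windows truncated at the ends.

    Position ``i`` (1-based) averages depth over
    ``[max(1, i-window//2), min(genome_len, i+window//2)]``; positions
    absent from the pileup count as depth 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    depth = _depth_array(pileup, genome_len)
    h = window // 2
    csum = np.concatenate([[0.0], np.cumsum(depth)])
    idx = np.arange(genome_len)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, genome_len - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def mean_coverage(
    pileup: Mapping[tuple[str, int], PileupPosition],
    genome_len: int,
) -> float:
    """Overall mean depth = total mapped depth / genome length."""
    return float(_depth_array(pileup, genome_len).sum() / genome_len)
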