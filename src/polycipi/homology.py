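"""Translated search, pairwise alignment and the reciprocal-best-hit filter.

This module provides the discovery machinery used to mine assembled
transcriptome contigs for family members: six-frame translation,
longest-ORF extraction, affine-gap Smith–Waterman / Needleman–Wunsch
alignment under BLOSUM62, a Karlin–Altschul E-value used purely as a
thresholding device, ranked search against a user-supplied protein panel,
and the retention rule — a candidate contig is kept only when it is long
enough and its best panel match and that match's best hit point back at
each other.

Percent identity is reported over all alignment columns of the global
alignment, gaps included; this convention is deliberately explicit because
different aligners disagree about the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .orf_layout import find_orfs
from .seqio import GenomeRecord, HitRecord

#: Karlin–Altschul constants for gapped BLOSUM62 (11/1) searches.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass
class AlignmentResult:
    score: float
    identities: int
    columns: int
    pct_identity: float
    q_span: tuple[int, int]  # 1-based inclusive aa coordinates
    s_span: tuple[int, int]


def translate(seq: str, frame: int = 1) -> str:
    """Translate one reading frame (NCBI table 1); stops rendered ``*``.

    Frames +1..+3 read the forward strand from offsets 0..2; −1..−3 read
    the reverse complement the same way. A trailing partial codon is
    dropped.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError("frame must be one of +1,+2,+3,-1,-2,-3")
    s = seq if frame > 0 else str(Seq(seq).reverse_complement())
    off = abs(frame) - 1
    sub = s[off:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate(table=1))


def six_frame_translate(seq: str) -> dict[int, str]:
    return {f: translate(seq, f) for f in (1, 2, 3, -1, -2, -3)}


def longest_orf_peptide(seq: str) -> str:
    """Peptide of the single longest ATG-initiated ORF over all six frames.

    Exact length ties prefer the forward strand, then the 5'-most start.
    Returns the empty string when no ATG..stop ORF exists.
    """
    best_pep = ""
    best_key: tuple[int, int, int] | None = None  # (-len, strand_rank, start)
    for strand_rank, s in enumerate([seq, str(Seq(seq).reverse_complement())]):
        for orf in find_orfs(s, min_len_nt=6):
            key = (-orf.length_nt, strand_rank, orf.start)
            if best_key is None or key < best_key:
                best_key = key
                best_pep = orf.peptide
    return best_pep


def _aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _result_from_alignment(alignment, score: float) -> AlignmentResult:
    counts = alignment.counts()
    columns = alignment.length
    identities = counts.identities
    pct = 100.0 * identities / columns if columns else 0.0
    q_aln, s_aln = alignment.aligned
    if len(q_aln):
        q_span = (int(q_aln[0][0]) + 1, int(q_aln[-1][1]))
        s_span = (int(s_aln[0][0]) + 1, int(s_aln[-1][1]))
    else:
        q_span = s_span = (0, 0)
    return AlignmentResult(
        score=float(score),
        identities=int(identities),
        columns=int(columns),
        pct_identity=pct,
        q_span=q_span,
        s_span=s_span,
    )


def local_align(
    q: str,
    s: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> AlignmentResult:
    """Affine-gap Smith–Waterman optimum (first alignment, deterministic)."""
    if not q or not s:
        raise ValueError("peptides must be non-empty")
    aligner = _aligner("local", matrix, gap_open, gap_extend)
    alignments = aligner.align(q, s)
    if alignments.score <= 0:
        # the optimal local alignment is empty
        return AlignmentResult(score=0.0, identities=0, columns=1, pct_identity=0.0, q_span=(0, 0), s_span=(0, 0))
    return _result_from_alignment(alignments[0], alignments.score)


def global_align(
    q: str,
    s: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> AlignmentResult:
    """Affine-gap Needleman–Wunsch optimum over full sequences."""
    if not q or not s:
        raise ValueError("peptides must be non-empty")
    aligner = _aligner("global", matrix, gap_open, gap_extend)
    alignments = aligner.align(q, s)
    return _result_from_alignment(alignments[0], alignments.score)


def evalue(
    score: float,
    m: int,
    n: int,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−lambda·score).

    A thresholding device with fixed gapped-BLOSUM62 constants, not a
    calibrated statistic.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return K * m * n * math.exp(-lam * score)


def search(
    query_peptide: str,
    panel: Sequence[tuple[str, str]],
    query_id: str = "query",
) -> list[HitRecord]:
    """Rank a peptide against a panel by local alignment score.

    One hit per panel entry, sorted by score (desc), then percent identity
    (desc), then subject id (asc) — a ranking invariant to panel order.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    hits = []
    for sid, pep in panel:
        aln = local_align(query_peptide, pep)
        hits.append(
            HitRecord(
                query_id=query_id,
                subject_id=sid,
                pct_identity=aln.pct_identity,
                aln_len=aln.columns,
                score=aln.score,
                evalue=evalue(aln.score, len(query_peptide), len(pep)),
            )
        )
    hits.sort(key=lambda h: (-h.score, -h.pct_identity, h.subject_id))
    return hits


@dataclass
class RbhDecision:
    candidate_id: str
    fwd_best: HitRecord | None
    rev_best: HitRecord | None
    retained: bool
    reason: str  # reciprocal_best | wrong_best_target | no_hit | too_short


def rbh_filter(
    candidates: Sequence[GenomeRecord],
    reference_set: set[str],
    panel: Sequence[tuple[str, str]],
    min_len_nt: int = 10_000,
    evalue_max: float = 1e-6,
    min_cds_nt: int = 300,
) -> list[RbhDecision]:
    """Reciprocal-best-hit retention filter for candidate contigs.

    Per candidate: (i) contigs below ``min_len_nt`` are discarded
    (``too_short``); (ii) the longest-ORF peptide is searched against the
    panel — a best hit outside ``reference_set``, or one failing the
    E-value / aligned-length (≥ ``min_cds_nt``/3 columns) thresholds,
    discards the candidate (``wrong_best_target`` / ``no_hit``); (iii) the
    best reference's peptide is searched back against the candidate
    peptides plus the panel, and the candidate is retained only when it
    outranks every non-reference entry (``reciprocal_best``).

    Verdicts are per-candidate and independent of input order.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    panel_ids = {sid for sid, _ in panel}
    missing = reference_set - panel_ids
    if missing:
        raise ValueError(f"reference ids not in panel: {sorted(missing)}")
    panel_map: Mapping[str, str] = dict(panel)
    candidate_peps = {c.id: longest_orf_peptide(c.seq) for c in candidates}

    decisions = []
    for cand in candidates:
        if len(cand.seq) < min_len_nt:
            decisions.append(RbhDecision(cand.id, None, None, False, "too_short"))
            continue
        pep = candidate_peps[cand.id]
        if not pep:
            decisions.append(RbhDecision(cand.id, None, None, False, "no_hit"))
            continue
        fwd = search(pep, panel, query_id=cand.id)
        fwd_best = fwd[0]
        if fwd_best.evalue > evalue_max or fwd_best.aln_len < min_cds_nt // 3:
            decisions.append(RbhDecision(cand.id, fwd_best, None, False, "no_hit"))
            continue
        if fwd_best.subject_id not in reference_set:
            decisions.append(RbhDecision(cand.id, fwd_best, None, False, "wrong_best_target"))
            continue
        # reciprocal search: the matched reference queries the candidate set
        # plus the panel, so it is free to "choose" a decoy instead
        rev_targets = [(cid, p) for cid, p in candidate_peps.items() if p] + list(panel)
        rev = search(panel_map[fwd_best.subject_id], rev_targets, query_id=fwd_best.subject_id)
        rev_top = next((h for h in rev if h.subject_id not in reference_set), None)
        retained = rev_top is not None and rev_top.subject_id == cand.id
        decisions.append(
            RbhDecision(
                cand.id,
                fwd_best,
                rev_top,
                retained,
                "reciprocal_best" if retained else "wrong_best_target",
            )
        )
    return decisions
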