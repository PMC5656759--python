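"""Inference of the polycistronic genome architecture.

Polycipivirus-type genomes are ~11–12 kb polyadenylated positive-sense RNAs
with four closely spaced (often overlapping) 5'-proximal ORFs, an
intergenic region, and one long 3' ORF encoding the Hel/Pro/RdRp
non-structural polyprotein. This module enumerates candidate ORFs, picks
the long 3' ORF by its motif complement, selects the upstream four-ORF
chain under junction-spacing constraints, detects the +1-frame overlapping
ORF2b by its central transmembrane helix, and computes the UTR/IGR summary
statistics.

Coordinates are 1-based, inclusive, with the stop codon included in every
ORF. Only the forward strand is considered: the family's genomes are
positive-sense, and reverse-complement database deposits are expected to be
normalized at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from . import motif_scan
from .motif_scan import DomainScanResult, MotifPattern
from .seqio import GenomeRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: display convention for reading-frame offsets relative to the long 3' ORF
FRAME_OFFSET_LABELS = {0: 0, 1: +1, 2: -1}


@dataclass
class OrfAnnotation:
    orf_id: str
    start: int  # 1-based, inclusive
    end: int  # inclusive, stop codon included
    frame_offset_vs_orf5: int = 0  # one of {-1, 0, +1}
    peptide: str = ""

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeLayout:
    """The inferred polycistronic architecture of one genome."""

    genome_id: str
    seq_len: int  # poly(A) excluded
    orfs: list[OrfAnnotation] = field(default_factory=list)
    utr5_len: int | None = None
    utr3_len: int | None = None
    igr_len: int | None = None
    junction_gaps: list[int] = field(default_factory=list)  # ORF1->2->3->4; negative = overlap
    five_prime_signature: bool = False
    extends_to_polya: bool = False

    def orf(self, orf_id: str) -> OrfAnnotation | None:
        for o in self.orfs:
            if o.orf_id == orf_id:
                return o
        return None


@dataclass
class LayoutInference:
    """Outcome of layout inference: a verdict plus the supporting evidence.

    A genome that does not fit the family architecture yields
    ``polycipivirus_like == False`` with the partial evidence, not an
    exception.
    """

    genome_id: str
    polycipivirus_like: bool
    layout: GenomeLayout | None
    scan: DomainScanResult | None
    evidence: list[str] = field(default_factory=list)


@dataclass
class LayoutStats:
    utr5_len: int | None
    utr3_len: int | None
    igr_len: int | None
    junction_gaps: dict[str, int]
    frame_offsets: dict[str, int]


def strip_polya(record: GenomeRecord, min_run: int = 10) -> GenomeRecord:
    """Remove a trailing poly(A) run of at least ``min_run`` nucleotides.

    The whole trailing A-run is removed when it reaches the threshold;
    shorter runs are left untouched. ``polya_trimmed_len`` records what was
    removed so the original length stays recoverable.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    seq = record.seq
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    run = n - i
    if run >= min_run:
        return GenomeRecord(
            id=record.id,
            description=record.description,
            seq=seq[:i],
            polya_trimmed_len=record.polya_trimmed_len + run,
        )
    return record


def _translate_cds(seq: str) -> str:
    """Peptide of a stop-terminated CDS, stop symbol removed."""
    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate(table=1))[:-1]


def find_orfs(seq: str, min_len_nt: int = 150) -> list[OrfAnnotation]:
    """Enumerate forward-strand ATG..stop ORFs of at least ``min_len_nt``.

    For each (frame, stop codon) pair only the 5'-most ATG (the longest
    span) is kept. Results are sorted by start, then end. ``min_len_nt``
    counts the stop codon and must be a multiple of 3.
    """
    if min_len_nt % 3 != 0:
        raise ValueError("min_len_nt must be a multiple of 3")
    n = len(seq)
    orfs: list[OrfAnnotation] = []
    for frame in range(3):
        atg_pos: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and atg_pos is None:
                atg_pos = i
            elif codon in STOP_CODONS:
                if atg_pos is not None:
                    length = i + 3 - atg_pos
                    if length >= min_len_nt:
                        cds = seq[atg_pos : i + 3]
                        orfs.append(
                            OrfAnnotation(
                                orf_id="",
                                start=atg_pos + 1,
                                end=i + 3,
                                peptide=_translate_cds(cds),
                            )
                        )
                atg_pos = None
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def five_prime_signature(seq: str, window: int = 25, au_frac: float = 0.7) -> bool:
    """5'-completeness signature: terminal TTT followed by an AU-rich tract.

    True iff the sequence starts with ``TTT`` and the A+T fraction of the
    first ``window`` nucleotides is at least ``au_frac``.
    """
    if len(seq) < window:
        return False
    head = seq[:window]
    at = sum(1 for b in head if b in "AT") / window
    return seq.startswith("TTT") and at >= au_frac


def _frame_offset(start: int, orf5_start: int) -> int:
    return FRAME_OFFSET_LABELS[(start - orf5_start) % 3]


def _chain_gap(prev: OrfAnnotation, nxt: OrfAnnotation) -> int:
    return nxt.start - prev.end - 1


def _select_chain(
    candidates: Sequence[OrfAnnotation],
    max_gap: int,
    max_overlap: int,
    extra_orf_allowed: bool,
) -> tuple[list[OrfAnnotation], OrfAnnotation | None] | None:
    """Pick the 4-ORF chain maximizing total coding length.

    Consecutive chain members must satisfy ``-max_overlap <= gap <= max_gap``.
    At most one junction may exceed ``max_gap`` provided an intervening
    short ORF bridges it with both sub-junctions within constraints; the
    bridging ORF is returned separately (reported as ORF3a).
    """
    nodes = sorted(candidates, key=lambda o: (o.start, o.end))
    n = len(nodes)
    if n < 4:
        return None

    def edge(i: int, j: int) -> tuple[bool, OrfAnnotation | None] | None:
        a, b = nodes[i], nodes[j]
        if b.start <= a.start or b.end <= a.end:
            return None  # keep the chain ordered and non-nested
        gap = _chain_gap(a, b)
        if -max_overlap <= gap <= max_gap:
            return (False, None)
        if extra_orf_allowed and gap > max_gap:
            bridge = None
            for m in nodes:
                if m is a or m is b:
                    continue
                if not (a.start < m.start and a.end < m.end and m.start < b.start and m.end < b.end):
                    continue
                if -max_overlap <= _chain_gap(a, m) <= max_gap and -max_overlap <= _chain_gap(m, b) <= max_gap:
                    if bridge is None or m.length_nt > bridge.length_nt:
                        bridge = m
            if bridge is not None:
                return (True, bridge)
        return None

    NEG = -1
    # dp[k][i][b]: max total length of a k-ORF chain ending at node i having
    # used b bridged junctions; parent pointers reconstruct the chain.
    dp = [[[NEG, NEG] for _ in range(n)] for _ in range(5)]
    parent: dict[tuple[int, int, int], tuple[int, int, OrfAnnotation | None]] = {}
    for i in range(n):
        dp[1][i][0] = nodes[i].length_nt
    for k in range(2, 5):
        for j in range(n):
            for i in range(j):
                e = edge(i, j)
                if e is None:
                    continue
                bridged, bridge_orf = e
                for b in (0, 1):
                    if dp[k - 1][i][b] == NEG:
                        continue
                    nb = b + (1 if bridged else 0)
                    if nb > 1:
                        continue
                    total = dp[k - 1][i][b] + nodes[j].length_nt
                    if total > dp[k][j][nb]:
                        dp[k][j][nb] = total
                        parent[(k, j, nb)] = (i, b, bridge_orf if bridged else None)
    best: tuple[int, int, int] | None = None
    for i in range(n):
        for b in (0, 1):
            if dp[4][i][b] > (dp[4][best[1]][best[2]] if best else NEG):
                best = (4, i, b)
    if best is None:
        return None
    chain: list[OrfAnnotation] = []
    bridge_used: OrfAnnotation | None = None
    k, i, b = best
    while k >= 1:
        chain.append(nodes[i])
        if k == 1:
            break
        i, b, br = parent[(k, i, b)]
        if br is not None:
            bridge_used = br
        k -= 1
    chain.reverse()
    return chain, bridge_used


def detect_orf2b(
    layout: GenomeLayout,
    seq: str,
    candidates: Sequence[OrfAnnotation] | None = None,
    max_start_offset: int = 120,
    min_len_nt: int = 200,
    max_gap: int = 60,
    tm_predictor=motif_scan.has_central_tm,
) -> OrfAnnotation | None:
    """Detect the overlapping ORF2b by frame, position and membrane helix.

    ORF2b starts within ``max_start_offset`` nt of ORF2's start in the +1
    frame relative to ORF2 (``(start - ORF2.start) mod 3 == 1``), is at
    least ``min_len_nt`` long, ends at or before ``ORF2.end + max_gap``,
    and its peptide must carry a predicted transmembrane helix centered in
    the middle half of the protein. Returns ``None`` when no candidate
    qualifies.
    """
    orf2 = layout.orf("ORF2")
    if orf2 is None:
        return None
    if candidates is None:
        candidates = find_orfs(seq, min_len_nt=150)
    best: OrfAnnotation | None = None
    for cand in candidates:
        if cand.start == orf2.start and cand.end == orf2.end:
            continue
        offset = cand.start - orf2.start
        if not (0 <= offset <= max_start_offset):
            continue
        if offset % 3 != 1:
            continue
        if cand.length_nt < min_len_nt:
            continue
        if cand.end > orf2.end + max_gap:
            continue
        if not tm_predictor(cand.peptide):
            continue
        if best is None or cand.length_nt > best.length_nt:
            best = cand
    if best is None:
        return None
    return OrfAnnotation(orf_id="ORF2b", start=best.start, end=best.end, peptide=best.peptide)


def infer_layout(
    record: GenomeRecord,
    library: list[MotifPattern] | None = None,
    min_orf_nt: int = 150,
    max_gap: int = 60,
    max_overlap: int = 20,
    extra_orf_allowed: bool = True,
    with_orf2b: bool = True,
) -> LayoutInference:
    """Infer the family-characteristic five-ORF architecture of a genome.

    The long 3' ORF (ORF5) is the longest candidate whose polypeptide
    carries the Hel, Pro and RdRp motifs in that order (falling back,
    flagged, to the longest ORF when no candidate has the motifs). ORF1–4
    are the chain of four upstream ORFs maximizing total coding length
    under the junction-spacing constraints. The poly(A) tail, if still
    present, is stripped first, so the result is invariant to it.
    """
    record = strip_polya(record)
    seq = record.seq
    evidence: list[str] = []
    candidates = find_orfs(seq, min_len_nt=min_orf_nt)
    if not candidates:
        return LayoutInference(record.id, False, None, None, ["no_orfs"])

    by_len = sorted(candidates, key=lambda o: (-o.length_nt, o.start))
    orf5 = None
    scan = None
    for cand in by_len:
        s = motif_scan.scan_motifs(cand.peptide, library)
        if s.ordered_ok:
            orf5, scan = cand, s
            break
    if orf5 is None:
        orf5 = by_len[0]
        scan = motif_scan.scan_motifs(orf5.peptide, library)
        evidence.append("orf5_motifs_missing")
    else:
        evidence.append("hel_pro_rdrp_ordered")

    upstream = [o for o in candidates if o.end < orf5.start]
    selected = _select_chain(upstream, max_gap=max_gap, max_overlap=max_overlap, extra_orf_allowed=extra_orf_allowed)
    if selected is None:
        evidence.append(f"upstream_chain_missing({len(upstream)}_candidates)")
        partial = GenomeLayout(
            genome_id=record.id,
            seq_len=len(seq),
            orfs=[OrfAnnotation("ORF5", orf5.start, orf5.end, 0, orf5.peptide)],
            utr3_len=len(seq) - orf5.end,
            five_prime_signature=five_prime_signature(seq),
            extends_to_polya=record.extends_to_polya,
        )
        return LayoutInference(record.id, False, partial, scan, evidence)
    chain, bridge = selected
    evidence.append("layout_ok")

    orfs: list[OrfAnnotation] = []
    for orf_id, cand in zip(("ORF1", "ORF2", "ORF3", "ORF4"), chain):
        orfs.append(
            OrfAnnotation(orf_id, cand.start, cand.end, _frame_offset(cand.start, orf5.start), cand.peptide)
        )
    if bridge is not None:
        orfs.append(
            OrfAnnotation("ORF3a", bridge.start, bridge.end, _frame_offset(bridge.start, orf5.start), bridge.peptide)
        )
        evidence.append("orf3a_bridge")
    orfs.append(OrfAnnotation("ORF5", orf5.start, orf5.end, 0, orf5.peptide))

    layout = GenomeLayout(
        genome_id=record.id,
        seq_len=len(seq),
        orfs=sorted(orfs, key=lambda o: (o.start, o.end)),
        utr5_len=chain[0].start - 1,
        utr3_len=len(seq) - orf5.end,
        igr_len=orf5.start - chain[3].end - 1,
        junction_gaps=[_chain_gap(a, b) for a, b in zip(chain, chain[1:])],
        five_prime_signature=five_prime_signature(seq),
        extends_to_polya=record.extends_to_polya,
    )
    if with_orf2b:
        orf2b = detect_orf2b(layout, seq, candidates=candidates, max_gap=max_gap)
        if orf2b is not None:
            orf2b.frame_offset_vs_orf5 = _frame_offset(orf2b.start, orf5.start)
            layout.orfs.append(orf2b)
            layout.orfs.sort(key=lambda o: (o.start, o.end))
            evidence.append("orf2b_present")
    return LayoutInference(record.id, True, layout, scan, evidence)


def layout_stats(row_or_layout) -> LayoutStats:
    """UTR/IGR lengths, junction gaps and frame offsets from coordinates.

    Accepts either an inferred :class:`GenomeLayout` or a
    :class:`~polycipi.seqio.LayoutTableRow`; the arithmetic is applied
    verbatim to whatever coordinates are present, and statistics whose
    ORFs are absent come back as ``None`` (or are omitted from the maps).
    An overlapping ORF4/ORF5 pair (negative intergenic region) is an error.
    """
    if isinstance(row_or_layout, GenomeLayout):
        coords = {o.orf_id: (o.start, o.end) for o in row_or_layout.orfs}
        seq_len = row_or_layout.seq_len
    else:
        row = row_or_layout
        coords = dict(row.orf_coords)
        for orf_id, (s, e) in row.partial_coords.items():
            coords.setdefault(orf_id, (s, e))
        seq_len = row.seq_len

    def get(orf_id: str) -> tuple[int | None, int | None]:
        c = coords.get(orf_id)
        return c if c is not None else (None, None)

    orf1_s, _ = get("ORF1")
    orf4_s, orf4_e = get("ORF4")
    orf5_s, orf5_e = get("ORF5")

    utr5 = orf1_s - 1 if orf1_s is not None else None
    utr3 = seq_len - orf5_e if orf5_e is not None else None
    igr = None
    if orf5_s is not None and orf4_e is not None:
        igr = orf5_s - orf4_e - 1
        if igr < 0:
            raise ValueError("ORF4 and ORF5 overlap: negative intergenic region")

    gaps: dict[str, int] = {}
    chain = ["ORF1", "ORF2", "ORF3", "ORF4"]
    for a, b in zip(chain, chain[1:]):
        (_, ae), (bs, _) = get(a), get(b)
        if ae is not None and bs is not None:
            gaps[f"{a}->{b}"] = bs - ae - 1

    offsets: dict[str, int] = {}
    if orf5_s is not None:
        for orf_id, (s, _e) in coords.items():
            if s is not None:
                offsets[orf_id] = _frame_offset(s, orf5_s)

    return LayoutStats(utr5_len=utr5, utr3_len=utr3, igr_len=igr, junction_gaps=gaps, frame_offsets=offsets)
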