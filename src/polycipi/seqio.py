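"""Reading and writing the flat formats the pipeline touches.

One coordinate convention is used throughout the package: nucleotide
positions are 1-based and inclusive, and ORF coordinates include the stop
codon. RNA input (``U``) is silently normalized to the DNA alphabet because
positive-sense RNA virus sequences are deposited and searched as DNA.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MAIN_ORF_IDS = ("ORF1", "ORF2b", "ORF2", "ORF3", "ORF3a", "ORF4", "ORF5")

_VALID_BASES = set("ACGTN")


@dataclass
class GenomeRecord:
    """An identified nucleotide sequence with provenance and poly(A) status.

    ``polya_trimmed_len`` is the number of trailing poly(A) nucleotides that
    were removed from the deposited sequence; the original length is
    ``len(seq) + polya_trimmed_len``.
    """

    id: str
    description: str
    seq: str
    polya_trimmed_len: int = 0

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)
        if self.polya_trimmed_len < 0:
            raise ValueError("polya_trimmed_len must be >= 0")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def extends_to_polya(self) -> bool:
        return self.polya_trimmed_len > 0


@dataclass
class LayoutTableRow:
    """One row of the packaged genome-architecture table.

    ``orf_coords`` holds only complete (start, end) pairs; ORFs the printed
    table leaves blank are absent from the mapping, never stored as 0.
    Coordinates printed with only one endpoint (a 5'- or 3'-truncated ORF)
    are kept in ``partial_coords`` as ``(start | None, end | None)``.
    The printed 5'UTR / IGR / 3'UTR columns are carried verbatim so layout
    arithmetic can be checked against them cell by cell.
    """

    name: str
    accessions: list[str]
    host: str
    seq_len: int
    orf_coords: dict[str, tuple[int, int]]
    extends_to_polya: bool
    utr5_len: int | None = None
    igr_len: int | None = None
    utr3_len: int | None = None
    partial_coords: dict[str, tuple[int | None, int | None]] = field(default_factory=dict)


@dataclass
class HitRecord:
    """A BLAST outfmt-6-like exchange record for one query/subject pair."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class PileupPosition:
    """Depth and per-base counts at one genome position."""

    depth: int
    counts: dict[str, int]

    def alt_fraction(self, ref: str, alt: str) -> float:
        if self.depth == 0:
            return 0.0
        return self.counts.get(alt, 0) / self.depth


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U to T, and validate the {A,C,G,T,N} alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return s


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into normalized :class:`GenomeRecord` objects.

    An empty file yields an empty list. Content before the first header is a
    malformed-header error naming the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: line {lineno}: expected FASTA header line starting with '>'")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(GenomeRecord(id=rec.id, description=desc, seq=str(rec.seq)))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def write_gff3(layout, path: str | Path) -> None:
    """Write one CDS feature per annotated ORF (1-based inclusive, + strand).

    Accepts any object with ``genome_id``, ``seq_len`` and an ``orfs``
    iterable of annotations carrying ``orf_id``, ``start`` and ``end``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if getattr(layout, "seq_len", None):
            fh.write(f"##sequence-region {layout.genome_id} 1 {layout.seq_len}\n")
        for orf in layout.orfs:
            fh.write(
                "\t".join(
                    [
                        layout.genome_id,
                        "polycipi",
                        "CDS",
                        str(orf.start),
                        str(orf.end),
                        ".",
                        "+",
                        "0",
                        f"ID={orf.orf_id}",
                    ]
                )
                + "\n"
            )


def read_gff3_cds(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read back CDS coordinates written by :func:`write_gff3` (round-trip)."""
    coords: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            coords[attrs.get("ID", f"{cols[3]}-{cols[4]}")] = (int(cols[3]), int(cols[4]))
    return coords


def packaged_layout_table_path() -> Path:
    """Path of the packaged genome-architecture table (15 family genomes)."""
    return Path(importlib.resources.files("polycipi").joinpath("data/layout_table.tsv"))


def read_layout_table(path: str | Path | None = None) -> list[LayoutTableRow]:
    """Read the architecture table; defaults to the packaged 15-row fixture.

    Every complete ORF coordinate pair is checked against the frame
    invariant (length divisible by 3, start < end within the sequence);
    a violation is an error naming the row and ORF.
    """
    if path is None:
        path = packaged_layout_table_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows: list[LayoutTableRow] = []
    for _, r in df.iterrows():
        name = r["name"]
        seq_len = int(r["seq_len"])
        coords: dict[str, tuple[int, int]] = {}
        partial: dict[str, tuple[int | None, int | None]] = {}
        for orf in MAIN_ORF_IDS:
            key = orf.lower().replace("orf", "orf")
            s = r.get(f"{key}_start")
            e = r.get(f"{key}_end")
            s = int(s) if pd.notna(s) else None
            e = int(e) if pd.notna(e) else None
            if s is not None and e is not None:
                if not (1 <= s < e <= seq_len):
                    raise ValueError(f"row {name!r}, {orf}: coordinates ({s}, {e}) outside 1..{seq_len}")
                if (e - s + 1) % 3 != 0:
                    raise ValueError(f"row {name!r}, {orf}: length {e - s + 1} not a multiple of 3")
                coords[orf] = (s, e)
            elif s is not None or e is not None:
                partial[orf] = (s, e)
        rows.append(
            LayoutTableRow(
                name=name,
                accessions=str(r["accessions"]).split(";"),
                host=r["host"],
                seq_len=seq_len,
                orf_coords=coords,
                extends_to_polya=str(r["extends_to_polya"]).strip().lower() == "yes",
                utr5_len=int(r["utr5_len"]) if pd.notna(r["utr5_len"]) else None,
                igr_len=int(r["igr_len"]) if pd.notna(r["igr_len"]) else None,
                utr3_len=int(r["utr3_len"]) if pd.notna(r["utr3_len"]) else None,
                partial_coords=partial,
            )
        )
    return rows


PILEUP_COLUMNS = ["genome_id", "pos", "depth", "countA", "countC", "countG", "countT"]


def read_pileup(path: str | Path) -> dict[tuple[str, int], PileupPosition]:
    """Read a per-position pileup TSV into a (genome id, position) map.

    Positions absent from the file have depth 0 by convention. Base counts
    summing above the stated depth are an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup file missing columns: {sorted(missing)}")
    out: dict[tuple[str, int], PileupPosition] = {}
    for r in df.itertuples(index=False):
        counts = {"A": int(r.countA), "C": int(r.countC), "G": int(r.countG), "T": int(r.countT)}
        depth = int(r.depth)
        if sum(counts.values()) > depth:
            raise ValueError(f"pileup {r.genome_id}:{r.pos}: base counts sum above depth {depth}")
        out[(str(r.genome_id), int(r.pos))] = PileupPosition(depth=depth, counts=counts)
    return out


def write_pileup(pileup: Mapping[tuple[str, int], PileupPosition], path: str | Path) -> None:
    rows = [
        {
            "genome_id": gid,
            "pos": pos,
            "depth": p.depth,
            "countA": p.counts.get("A", 0),
            "countC": p.counts.get("C", 0),
            "countG": p.counts.get("G", 0),
            "countT": p.counts.get("T", 0),
        }
        for (gid, pos), p in sorted(pileup.items())
    ]
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


HIT_COLUMNS = ["query_id", "subject_id", "pct_identity", "aln_len", "score", "evalue"]


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a six-column outfmt-6-like hit table."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "subject_id": str})
    return [
        HitRecord(
            query_id=r.query_id,
            subject_id=r.subject_id,
            pct_identity=float(r.pct_identity),
            aln_len=int(r.aln_len),
            score=float(r.score),
            evalue=float(r.evalue),
        )
        for r in df.itertuples(index=False)
    ]


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "pct_identity": h.pct_identity,
                "aln_len": h.aln_len,
                "score": h.score,
                "evalue": h.evalue,
            }
            for h in hits
        ],
        columns=HIT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
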