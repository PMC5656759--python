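"""Seeded generators for genomes, families, decoys and pileups.

Every generator is a pure function of (spec, seed) and returns its ground
truth alongside the data, so the annotation, discovery, classification and
variant modules are testable without any download. The default genome spec
is the SINV-2-shaped architecture: a ~11.3 kb polyadenylated positive-sense
genome with a 301-nt 5'UTR carrying the UUU/AU-rich completeness signature,
four closely spaced 5' ORFs (junction gaps −4/−8/−4), an overlapping
+1-frame ORF2b with a central hydrophobic stretch, a 662-nt intergenic
region, a long 3' ORF carrying ordered Hel/Pro/RdRp motif blocks (serine
protease GxSG, canonical GDD motif VI), a 387-nt 3'UTR and a 30-nt poly(A).

Construction is codon-wise with bounded rejection: mandatory cells (start
and stop codons, motif blocks, the ORF2b core, the 5' signature head) are
fixed first, remaining cells are filled randomly, and a repair loop
re-rolls non-mandatory cells until no planted ORF has an internal stop or
an upstream in-frame extension, no unplanned ORF outgrows the shortest
planted one, and the long-ORF polypeptide shows no motif matches outside
the planted blocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from skbio import TreeNode

from .motif_scan import MotifPattern, default_library
from .orf_layout import (
    STOP_CODONS,
    GenomeLayout,
    OrfAnnotation,
    _frame_offset,
    _translate_cds,
    find_orfs,
)
from .seqio import GenomeRecord, PileupPosition

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# Hydrophobic-core codons (I/L/V/F) whose second position is always T and
# whose first two positions never form TA/TG/GA/AG: runs of these codons
# cannot create a stop codon or an ATG in any reading frame.
_CORE_HYDROPHOBIC = ("ATT", "ATC", "CTC", "GTC", "TTC", "TTT")
# Charged-core codons (D/E/K/R) containing no T: no stop codon (all contain
# T) and no ATG can arise from them in any frame.
_CORE_CHARGED = ("GAC", "GAG", "AAG", "CGC")

# --- planted motif blocks (peptide strings matching the default library) ---

HEL_BLOCK = "GESGSGKS" + "QQN" + "ILVKADE" + "QQN" + "STNAADE"


def pro_block(triad: str) -> str:
    site = {"GxSG": "GDSGAAIL", "GxCG": "GDCGAAIL"}[triad]
    return "LHYAGD" + "AQN" + "DLLGAKP" + "AQN" + site


def rdrp_block(motif6_variant: str) -> str:
    m6 = {"GDD": "YGDD", "ADD": "MADD", "SDD": "FSDD"}[motif6_variant]
    return (
        "KGKTRLI" + "AQN" + "SRFDAW" + "AQN" + "DASGFD" + "AQN" + "DYSAFD"
        + "AQN" + "GGLPSG" + "AQN" + m6 + "AQN" + "FLKRGF" + "AQN" + "SGFPMT"
    )


def _codon_map() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, str] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, codon)
    return out


_AA_TO_CODON = _codon_map()


def _encode_peptide(pep: str) -> str:
    return "".join(_AA_TO_CODON[aa] for aa in pep)


@dataclass
class Orf2bSpec:
    offset: int = 4  # nt downstream of ORF2's start; must be ≡ 1 (mod 3)
    length: int = 231
    hydrophobic_core: bool = True


@dataclass
class Orf3aSpec:
    length: int = 210
    gap_before: int = -4  # ORF2 -> ORF3a junction
    gap_after: int = -4  # ORF3a -> ORF3 junction


def _default_orf_lens() -> dict[str, int]:
    return {"ORF1": 777, "ORF2": 804, "ORF3": 777, "ORF4": 1149, "ORF5": 6462}


@dataclass
class GenomeSpec:
    """A stated genome architecture with planted ground truth."""

    utr5_len: int = 301
    utr3_len: int = 387
    igr_len: int = 662
    orf_lens: dict[str, int] = field(default_factory=_default_orf_lens)
    junction_gaps: tuple[int, int, int] = (-4, -8, -4)  # ORF1->2, 2->3, 3->4
    orf2b: Orf2bSpec | None = field(default_factory=Orf2bSpec)
    orf3a: Orf3aSpec | None = None
    motif6_variant: str = "GDD"  # GDD | ADD | SDD
    triad: str = "GxSG"  # GxSG | GxCG
    five_prime_signature: bool = True
    polya_len: int = 30
    seed: int = 0


@dataclass
class GenomeTruth:
    """Ground truth accompanying a generated genome."""

    layout: GenomeLayout
    motif_blocks_aa: dict[str, tuple[int, int]]  # 0-based aa [start, end) on the long ORF
    triad: str
    motif6_variant: str
    orf2b_planted: bool
    genus: str
    protected: np.ndarray  # bool per body position: mandatory cells
    planted_spans: list[tuple[int, int]]  # 0-based inclusive nt spans of planted ORFs


class _Unsatisfiable(Exception):
    pass


def _spec_coordinates(spec: GenomeSpec) -> dict[str, tuple[int, int]]:
    """1-based inclusive coordinates implied by a spec; validates lengths."""
    for orf, ln in spec.orf_lens.items():
        if ln <= 0 or ln % 3:
            raise ValueError(f"{orf} length {ln} must be a positive multiple of 3")
    for name in ("ORF1", "ORF2", "ORF3", "ORF4", "ORF5"):
        if name not in spec.orf_lens:
            raise ValueError(f"orf_lens must define {name}")
    if min(spec.utr5_len, spec.utr3_len, spec.igr_len, spec.polya_len) < 0:
        raise ValueError("lengths must be >= 0")
    coords: dict[str, tuple[int, int]] = {}
    s = spec.utr5_len + 1
    coords["ORF1"] = (s, s + spec.orf_lens["ORF1"] - 1)
    gaps = list(spec.junction_gaps)
    if spec.orf3a is not None:
        if spec.orf3a.length % 3:
            raise ValueError("ORF3a length must be a multiple of 3")
        gaps[1] = spec.orf3a.gap_before + spec.orf3a.length + spec.orf3a.gap_after
    prev = "ORF1"
    for orf, gap in zip(("ORF2", "ORF3", "ORF4"), gaps):
        s = coords[prev][1] + 1 + gap
        coords[orf] = (s, s + spec.orf_lens[orf] - 1)
        prev = orf
    if spec.orf3a is not None:
        s = coords["ORF2"][1] + 1 + spec.orf3a.gap_before
        coords["ORF3a"] = (s, s + spec.orf3a.length - 1)
    s = coords["ORF4"][1] + spec.igr_len + 1
    coords["ORF5"] = (s, s + spec.orf_lens["ORF5"] - 1)
    if spec.orf2b is not None:
        b = spec.orf2b
        if b.offset % 3 != 1 or b.offset < 0:
            raise ValueError("ORF2b offset must be positive and ≡ 1 (mod 3)")
        if b.length % 3 or b.length < 69:
            raise ValueError("ORF2b length must be a multiple of 3 and >= 69 nt")
        s2 = coords["ORF2"][0] + b.offset
        e2 = s2 + b.length - 1
        if e2 > coords["ORF2"][1] + 60:
            raise ValueError("ORF2b extends too far past ORF2")
        coords["ORF2b"] = (s2, e2)
    for orf, (a, b) in coords.items():
        if a < 1:
            raise ValueError(f"{orf} start {a} before sequence start (junction gaps too negative?)")
    return coords


@dataclass
class _Plan:
    """Internal construction plan shared by family and decoy builders."""

    body_len: int
    orfs: dict[str, tuple[int, int]]  # 1-based inclusive
    motif_orf: str
    triad: str
    motif6_variant: str
    orf2b_id: str | None = None
    hydrophobic_core: bool = True
    signature: bool = False
    min_planted_override: int | None = None


def _fixed_write(seq: list[str], fixed: list[bool], pos0: int, text: str) -> None:
    for i, ch in enumerate(text):
        p = pos0 + i
        if fixed[p] and seq[p] != ch:
            raise _Unsatisfiable(f"conflicting mandatory cells at {p}")
        seq[p] = ch
        fixed[p] = True


def _write_stop(seq, fixed, pos0: int, rng) -> None:
    for stop in rng.permutation(_STOPS):
        ok = all(not fixed[pos0 + i] or seq[pos0 + i] == stop[i] for i in range(3))
        if ok:
            _fixed_write(seq, fixed, pos0, stop)
            return
    raise _Unsatisfiable(f"no stop codon fits at {pos0}")


def _motif_blocks(plan: _Plan, pep_len: int) -> dict[str, tuple[int, int]]:
    hel, pro, rdrp = HEL_BLOCK, pro_block(plan.triad), rdrp_block(plan.motif6_variant)
    offs = {
        "Hel": int(0.15 * pep_len),
        "Pro": int(0.45 * pep_len),
        "RdRp": int(0.70 * pep_len),
    }
    blocks = {
        "Hel": (offs["Hel"], offs["Hel"] + len(hel)),
        "Pro": (offs["Pro"], offs["Pro"] + len(pro)),
        "RdRp": (offs["RdRp"], offs["RdRp"] + len(rdrp)),
    }
    if not (1 <= blocks["Hel"][0] and blocks["Hel"][1] < blocks["Pro"][0]
            and blocks["Pro"][1] < blocks["RdRp"][0] and blocks["RdRp"][1] < pep_len):
        raise ValueError("long ORF too short to hold the Hel/Pro/RdRp motif blocks")
    return blocks


_BLOCK_PEPTIDES = {
    "Hel": lambda plan: HEL_BLOCK,
    "Pro": lambda plan: pro_block(plan.triad),
    "RdRp": lambda plan: rdrp_block(plan.motif6_variant),
}


def _construct(plan: _Plan, rng, library: list[MotifPattern] | None = None, max_rounds: int = 200) -> tuple[str, list[bool], dict[str, tuple[int, int]]]:
    """Build one genome body satisfying the plan; raises _Unsatisfiable."""
    if library is None:
        library = default_library()
    n = plan.body_len
    seq = [""] * n
    fixed = [False] * n

    # 5' completeness signature: terminal TTT then an AU-rich head.
    if plan.signature:
        for _ in range(50):
            head = "TTT" + "".join(rng.choice(list("ATCG"), p=[0.45, 0.45, 0.05, 0.05], size=22))
            if sum(1 for b in head if b in "AT") / 25 >= 0.7:
                break
        else:
            raise _Unsatisfiable("could not draw an AU-rich head")
        _fixed_write(seq, fixed, 0, head)
    else:
        _fixed_write(seq, fixed, 0, "G")  # never starts with the UUU signature

    spans = {orf: (s - 1, e - 1) for orf, (s, e) in plan.orfs.items()}  # 0-based
    # start codons first, then compatible stop codons
    for orf, (s0, _) in sorted(spans.items(), key=lambda kv: kv[1]):
        _fixed_write(seq, fixed, s0, "ATG")
    for orf, (_, e0) in sorted(spans.items(), key=lambda kv: kv[1]):
        _write_stop(seq, fixed, e0 - 2, rng)

    # ORF2b central core: 21 residues, hydrophobic (TM helix) or charged
    if plan.orf2b_id is not None:
        s0, e0 = spans[plan.orf2b_id]
        pep_len = (e0 - s0 + 1) // 3 - 1
        core_aa = 21
        core_start_aa = (pep_len - core_aa) // 2
        pool = _CORE_HYDROPHOBIC if plan.hydrophobic_core else _CORE_CHARGED
        codons = [pool[rng.integers(len(pool))] for _ in range(core_aa)]
        _fixed_write(seq, fixed, s0 + 3 * core_start_aa, "".join(codons))

    # motif blocks on the long ORF
    s5, e5 = spans[plan.motif_orf]
    pep_len5 = (e5 - s5 + 1) // 3 - 1
    blocks = _motif_blocks(plan, pep_len5)
    for dom, (aa_lo, _) in blocks.items():
        _fixed_write(seq, fixed, s5 + 3 * aa_lo, _encode_peptide(_BLOCK_PEPTIDES[dom](plan)))

    # the body must not end in A, or poly(A) stripping would eat into it
    if not fixed[n - 1]:
        _fixed_write(seq, fixed, n - 1, "TCG"[rng.integers(3)])

    # random fill
    for p in range(n):
        if not fixed[p]:
            seq[p] = _BASES[rng.integers(4)]

    planted = sorted(spans.values())
    min_planted = plan.min_planted_override or min(e - s + 1 for s, e in planted)
    block_spans = list(blocks.values())
    extra_rx = [
        MotifPattern("Pro", "_triad_site", "G.[CS]G").compiled(),
    ]
    lib_rx = [(m.motif_id, m.compiled()) for m in library]

    def reroll(cells: list[int]) -> bool:
        hit = False
        for p in cells:
            if not fixed[p]:
                seq[p] = _BASES[rng.integers(4)]
                hit = True
        return hit

    def fix_internal_stops() -> bool:
        dirty = False
        for s0, e0 in planted:
            for p in range(s0, e0 - 4, 3):
                if "".join(seq[p : p + 3]) in STOP_CODONS:
                    if not reroll([p, p + 1, p + 2]):
                        raise _Unsatisfiable("mandatory cells form an internal stop")
                    dirty = True
        return dirty

    def fix_extensions() -> bool:
        dirty = False
        for s0, _e0 in planted:
            p = s0 - 3
            while p >= 0:
                codon = "".join(seq[p : p + 3])
                if codon in STOP_CODONS:
                    break
                if codon == "ATG":
                    if not reroll([p, p + 1, p + 2]):
                        raise _Unsatisfiable("fixed upstream ATG extends a planted ORF")
                    dirty = True
                p -= 3
        return dirty

    def fix_unplanned_orfs() -> bool:
        dirty = False
        for orf in find_orfs("".join(seq), min_len_nt=min_planted + 3):
            span0 = (orf.start - 1, orf.end - 1)
            if span0 in planted:
                continue
            atg = [orf.start - 1 + i for i in range(3)]
            if any(not fixed[p] for p in atg):
                while "".join(seq[atg[0] : atg[0] + 3]) == "ATG":
                    if not reroll(atg):
                        break
                dirty = True
            elif _insert_breaking_stop(seq, fixed, span0, planted, rng):
                dirty = True
            else:
                raise _Unsatisfiable("cannot break an unplanned long ORF")
        return dirty

    def fix_spurious_motifs() -> bool:
        dirty = False
        pep = _translate_cds("".join(seq[s5 : e5 + 1]))
        for _mid, rx in lib_rx + [("_triad_site", extra_rx[0])]:
            for m in rx.finditer(pep):
                if any(lo <= m.start() < hi for lo, hi in block_spans):
                    continue
                cells = list(range(s5 + 3 * m.start(), s5 + 3 * m.end()))
                if not reroll(cells):
                    raise _Unsatisfiable("fixed cells form a spurious motif")
                dirty = True
        return dirty

    # Later checks only run on a state the earlier ones accept, so e.g. a
    # re-created internal stop is never misread as an unplanned ORF.
    for _ in range(max_rounds):
        if fix_internal_stops():
            continue
        if fix_extensions():
            continue
        if fix_unplanned_orfs():
            continue
        if fix_spurious_motifs():
            continue
        return "".join(seq), fixed, blocks
    raise _Unsatisfiable("repair loop did not converge")


def _creates_planted_stop(seq, planted, p: int) -> bool:
    """True if any planted-ORF internal codon covering p..p+2 is now a stop."""
    for ps, pe in planted:
        if pe - 2 < p - 2 or ps > p + 2:
            continue
        first = ps + ((max(ps, p - 2) - ps) // 3) * 3
        for q in range(first, min(p + 3, pe - 2), 3):  # pe-2 is the planted stop itself
            if q >= ps and "".join(seq[q : q + 3]) in STOP_CODONS:
                return True
    return False


def _insert_breaking_stop(seq, fixed, span0, planted, rng) -> bool:
    """Write a stop codon into an unplanned ORF without breaking planted ORFs."""
    s0, e0 = span0
    positions = list(range(s0 + 3, e0 - 4, 3))
    rng.shuffle(positions)
    for p in positions[:50]:
        if any(fixed[p + i] for i in range(3)):
            continue
        old = seq[p : p + 3]
        for stop in rng.permutation(_STOPS):
            seq[p : p + 3] = list(stop)
            if not _creates_planted_stop(seq, planted, p):
                return True
        seq[p : p + 3] = old
    return False


def _layout_from_spec(spec: GenomeSpec, coords: dict[str, tuple[int, int]], body: str, genome_id: str, polya: int) -> GenomeLayout:
    orf5_s = coords["ORF5"][0]
    orfs = [
        OrfAnnotation(orf, s, e, _frame_offset(s, orf5_s), _translate_cds(body[s - 1 : e]))
        for orf, (s, e) in sorted(coords.items(), key=lambda kv: kv[1])
    ]
    return GenomeLayout(
        genome_id=genome_id,
        seq_len=len(body),
        orfs=orfs,
        utr5_len=coords["ORF1"][0] - 1,
        utr3_len=len(body) - coords["ORF5"][1],
        igr_len=coords["ORF5"][0] - coords["ORF4"][1] - 1,
        junction_gaps=[
            coords["ORF2"][0] - coords["ORF1"][1] - 1,
            coords["ORF3"][0] - coords["ORF2"][1] - 1,
            coords["ORF4"][0] - coords["ORF3"][1] - 1,
        ],
        five_prime_signature=spec.five_prime_signature,
        extends_to_polya=polya >= 10,
    )


def implied_genus(spec: GenomeSpec) -> str:
    if spec.orf2b is not None:
        return "Sopolycivirus"
    if spec.motif6_variant == "ADD":
        return "Chipolycivirus"
    return "Hupolycivirus"


def generate_genome(
    spec: GenomeSpec,
    genome_id: str | None = None,
    max_attempts: int = 20,
) -> tuple[GenomeRecord, GenomeLayout, GenomeTruth]:
    """Generate one genome with its true layout and planted features.

    Deterministic in ``spec`` (including ``spec.seed``): the same spec
    yields a byte-identical genome. An unsatisfiable spec raises
    ``ValueError`` before generation.
    """
    coords = _spec_coordinates(spec)
    body_len = coords["ORF5"][1] + spec.utr3_len
    plan = _Plan(
        body_len=body_len,
        orfs=coords,
        motif_orf="ORF5",
        triad=spec.triad,
        motif6_variant=spec.motif6_variant,
        orf2b_id="ORF2b" if spec.orf2b is not None else None,
        hydrophobic_core=spec.orf2b.hydrophobic_core if spec.orf2b else True,
        signature=spec.five_prime_signature,
    )
    rng = np.random.default_rng(spec.seed)
    last = None
    for _ in range(max_attempts):
        try:
            body, fixed, blocks = _construct(plan, rng)
            break
        except _Unsatisfiable as exc:
            last = exc
    else:
        raise ValueError(f"could not generate genome for spec: {last}")

    if genome_id is None:
        genome_id = f"synthetic_{spec.seed}"
    record = GenomeRecord(id=genome_id, description="synthetic polycipivirus-like genome", seq=body + "A" * spec.polya_len)
    layout = _layout_from_spec(spec, coords, body, genome_id, spec.polya_len)
    truth = GenomeTruth(
        layout=layout,
        motif_blocks_aa=blocks,
        triad=spec.triad,
        motif6_variant=spec.motif6_variant,
        orf2b_planted=spec.orf2b is not None,
        genus=implied_genus(spec),
        protected=np.array(fixed, dtype=bool),
        planted_spans=[(s - 1, e - 1) for s, e in coords.values()],
    )
    return record, layout, truth


def mutate_genome(
    record: GenomeRecord,
    subs_per_site: float,
    rng,
    truth: GenomeTruth | None = None,
    new_id: str | None = None,
) -> GenomeRecord:
    """Apply random substitutions; with ``truth``, proposals are codon-aware.

    With ground truth supplied, proposals landing on mandatory cells (start
    and stop codons, motif blocks, the ORF2b core) or creating a stop codon
    inside a planted ORF are rejected, so the planted architecture
    persists. Without it, substitutions are unconstrained.
    """
    body_len = len(record.seq) if truth is None else len(truth.protected)
    seq = list(record.seq)
    n_prop = rng.poisson(subs_per_site * body_len)
    for _ in range(n_prop):
        p = int(rng.integers(body_len))
        old = seq[p]
        new = old
        while new == old:
            new = _BASES[rng.integers(4)]
        if truth is not None:
            if truth.protected[p]:
                continue
            seq[p] = new
            bad = False
            for s0, e0 in truth.planted_spans:
                if not s0 <= p <= e0:
                    continue
                q = s0 + ((p - s0) // 3) * 3
                if q < e0 - 2 and "".join(seq[q : q + 3]) in STOP_CODONS:
                    bad = True
                    break
            if bad:
                seq[p] = old
        else:
            seq[p] = new
    return GenomeRecord(
        id=new_id or f"{record.id}_mut",
        description=record.description,
        seq="".join(seq),
        polya_trimmed_len=record.polya_trimmed_len,
    )


@dataclass
class FamilySpec:
    """A family of genomes evolved from one template along a known tree."""

    template: GenomeSpec = field(default_factory=GenomeSpec)
    tree: TreeNode | None = None  # if None, a random topology is drawn
    n_taxa: int = 12
    branch_length_range: tuple[float, float] = (0.02, 0.08)  # subs/site
    subs_rate: float = 1.0  # scales every branch
    seed: int = 0


def _random_topology(n_taxa: int, bl_range: tuple[float, float], rng) -> TreeNode:
    nodes = [TreeNode(name=f"taxon{i + 1:02d}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        a.length = float(rng.uniform(*bl_range))
        b.length = float(rng.uniform(*bl_range))
        nodes.append(TreeNode(children=[a, b]))
    root = nodes[0]
    root.length = None
    return root


def evolve_family(family_spec: FamilySpec) -> tuple[list[tuple[GenomeRecord, GenomeLayout]], TreeNode]:
    """Evolve the template genome along a tree; returns leaves + truth tree.

    Substitutions are applied along each branch in proportion to its length
    (expected ``subs_rate × length`` substitutions per site); codon-aware
    rejection keeps every planted ORF and motif block intact, so each leaf
    carries the template's layout (with its own peptides).
    """
    rng = np.random.default_rng(family_spec.seed)
    template_spec = dataclasses.replace(family_spec.template, seed=family_spec.seed)
    record, layout, truth = generate_genome(template_spec, genome_id="template")
    tree = family_spec.tree
    if tree is None:
        tree = _random_topology(family_spec.n_taxa, family_spec.branch_length_range, rng)
    coords = {o.orf_id: (o.start, o.end) for o in layout.orfs}
    polya = "A" * template_spec.polya_len
    body = record.seq[: len(record.seq) - template_spec.polya_len] if template_spec.polya_len else record.seq

    leaves: list[tuple[GenomeRecord, GenomeLayout]] = []

    def walk(node: TreeNode, seq: str) -> None:
        for child in node.children:
            bl = (child.length or 0.0) * family_spec.subs_rate
            mutated = mutate_genome(
                GenomeRecord(id="tmp", description="", seq=seq),
                bl,
                rng,
                truth=truth,
                new_id="tmp",
            ).seq
            if child.is_tip():
                rec = GenomeRecord(
                    id=child.name,
                    description="synthetic family member",
                    seq=mutated + polya,
                )
                lay = _layout_from_spec(template_spec, coords, mutated, child.name, template_spec.polya_len)
                leaves.append((rec, lay))
            else:
                walk(child, mutated)

    walk(tree, body)
    leaves.sort(key=lambda rl: rl[0].id)
    return leaves, tree


def generate_decoys(
    kind: str,
    n: int,
    seed: int,
    template: GenomeRecord | None = None,
    length: int = 11_000,
    with_truth: bool = False,
) -> list[GenomeRecord] | tuple[list[GenomeRecord], list[GenomeTruth | None]]:
    """Negative-control genomes: dicistro-like, shuffled or random.

    ``dicistro_like`` decoys have only two long ORFs with the
    non-structural (Hel/Pro/RdRp) ORF 5'-proximal — the opposite of the
    family architecture; ``shuffled`` permutes a supplied genome's bases
    (exact composition preserved); ``random`` draws i.i.d. uniform bases.
    With ``with_truth`` a parallel list of ground truths is returned
    (``None`` for shuffled/random decoys), usable for codon-aware mutation.
    """
    rng = np.random.default_rng(seed)
    records: list[GenomeRecord] = []
    truths: list[GenomeTruth | None] = []
    if kind == "dicistro_like":
        utr5, orf_a, igr, orf_b, utr3 = 250, 6000, 200, 4200, 300
        coords = {
            "ORF-A": (utr5 + 1, utr5 + orf_a),
            "ORF-B": (utr5 + orf_a + igr + 1, utr5 + orf_a + igr + orf_b),
        }
        body_len = coords["ORF-B"][1] + utr3
        plan = _Plan(
            body_len=body_len,
            orfs=coords,
            motif_orf="ORF-A",
            triad="GxCG",
            motif6_variant="GDD",
            signature=False,
        )
        for i in range(n):
            for _ in range(20):
                try:
                    body, fixed, blocks = _construct(plan, rng)
                    break
                except _Unsatisfiable:
                    continue
            else:
                raise ValueError("could not build dicistro-like decoy")
            gid = f"decoy_dicistro_{i:02d}"
            records.append(
                GenomeRecord(id=gid, description="synthetic dicistrovirus-like decoy", seq=body + "A" * 30)
            )
            orf5_s = coords["ORF-A"][0]
            layout = GenomeLayout(
                genome_id=gid,
                seq_len=len(body),
                orfs=[
                    OrfAnnotation(orf, s, e, _frame_offset(s, orf5_s), _translate_cds(body[s - 1 : e]))
                    for orf, (s, e) in sorted(coords.items(), key=lambda kv: kv[1])
                ],
                extends_to_polya=True,
            )
            truths.append(
                GenomeTruth(
                    layout=layout,
                    motif_blocks_aa=blocks,
                    triad=plan.triad,
                    motif6_variant=plan.motif6_variant,
                    orf2b_planted=False,
                    genus="unassigned",
                    protected=np.array(fixed, dtype=bool),
                    planted_spans=[(s - 1, e - 1) for s, e in coords.values()],
                )
            )
    elif kind == "shuffled":
        if template is None:
            raise ValueError("shuffled decoys need a template genome")
        for i in range(n):
            shuffled = "".join(rng.permutation(list(template.seq)))
            records.append(GenomeRecord(id=f"decoy_shuffled_{i:02d}", description="mononucleotide shuffle", seq=shuffled))
            truths.append(None)
    elif kind == "random":
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            records.append(GenomeRecord(id=f"decoy_random_{i:02d}", description="i.i.d. random sequence", seq=seq))
            truths.append(None)
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    if with_truth:
        return records, truths
    return records


def simulate_pileup(
    genome: GenomeRecord,
    mean_depth: float,
    snps: list[tuple[int, str, float]],
    seed: int,
) -> tuple[dict[tuple[str, int], PileupPosition], list[tuple[int, str, float]]]:
    """Simulate a pileup: Poisson depth, binomial alternative-allele counts.

    ``snps`` is a list of (position, alternative base, frequency); the
    planted list is returned unchanged as the truth. No sequencing-error
    model: non-SNP positions are pure reference.
    """
    for pos, alt, freq in snps:
        if not 1 <= pos <= len(genome.seq):
            raise ValueError(f"SNP position {pos} outside genome")
        if not 0.0 < freq < 1.0:
            raise ValueError("SNP frequencies must be in (0, 1)")
        if genome.seq[pos - 1] == alt:
            raise ValueError(f"SNP alt at {pos} equals the reference base")
    rng = np.random.default_rng(seed)
    snp_at = {pos: (alt, freq) for pos, alt, freq in snps}
    pileup: dict[tuple[str, int], PileupPosition] = {}
    depths = rng.poisson(mean_depth, size=len(genome.seq))
    for pos in range(1, len(genome.seq) + 1):
        depth = int(depths[pos - 1])
        counts = {b: 0 for b in "ACGT"}
        ref = genome.seq[pos - 1]
        if pos in snp_at and depth > 0:
            alt, freq = snp_at[pos]
            k = int(rng.binomial(depth, freq))
            counts[alt] = k
            if ref in counts:
                counts[ref] = depth - k
        else:
            if ref in counts:
                counts[ref] = depth
        pileup[(genome.id, pos)] = PileupPosition(depth=depth, counts=counts)
    return pileup, list(snps)
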