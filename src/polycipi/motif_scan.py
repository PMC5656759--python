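"""Replication-protein motif scanning on the long 3' ORF polypeptide.

The long 3' ORF of a polycipivirus-type genome encodes a non-structural
polyprotein carrying, in order, a superfamily III helicase (Hel), a 3C-like
chymotrypsin-related protease (Pro) and a superfamily I RNA-dependent RNA
polymerase (RdRp). This module locates those domains through short
sequence motifs, classifies the protease catalytic-site tetrapeptide
(GxCG vs the serine-protease GxSG variant) and the RdRp motif-VI triplet
(canonical GDD vs the ADD / SDD variants), and provides the
Kyte–Doolittle hydropathy transmembrane predictor used to detect the
overlapping ORF2b membrane protein.

Motif patterns are data: the default library ships as a YAML file and any
mapping with the same shape can replace it. In patterns, ``.`` matches any
of the 20 standard residues; ``X`` (unknown residue on partial transcript
translations) and ``*`` never match.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

DOMAIN_ORDER = ("Hel", "Pro", "RdRp")

# Any standard residue; X and * are deliberately excluded so unknown
# positions in partial translations never complete a motif.
_ANY = "[ACDEFGHIKLMNPQRSTVWY]"


@dataclass(frozen=True)
class MotifPattern:
    domain: str
    motif_id: str
    pattern: str
    required: bool = True

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern.replace(".", _ANY))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start_aa: int  # 1-based position of the first matched residue
    matched: str


@dataclass
class DomainScanResult:
    """Ordered motif evidence for the Hel/Pro/RdRp complement.

    ``hits`` holds the leftmost match per motif; ``all_hits`` additionally
    keeps every further occurrence. ``ordered_ok`` is true when every Hel
    hit starts before every Pro hit, and every Pro hit before every RdRp
    hit, and all three domains have their required motifs.
    """

    hits: list[MotifHit] = field(default_factory=list)
    all_hits: list[MotifHit] = field(default_factory=list)
    triad_variant: str = "absent"  # GxCG | GxSG | absent
    motif6_variant: str = "absent"  # GDD | ADD | SDD | other | absent
    ordered_ok: bool = False
    domains_present: set[str] = field(default_factory=set)
    triad_h_found: bool = False
    triad_d_found: bool = False

    def hits_for_domain(self, library: list[MotifPattern], domain: str) -> list[MotifHit]:
        ids = {m.motif_id for m in library if m.domain == domain}
        return [h for h in self.hits if h.motif_id in ids]


@dataclass
class TmPrediction:
    """Sliding-window hydropathy evidence for a transmembrane helix."""

    windows: list[tuple[int, int, float]]  # (start_aa, end_aa, mean) per above-threshold run
    has_central_tm: bool


def load_motif_library(path: str | Path | None = None) -> list[MotifPattern]:
    """Load a motif library from YAML; defaults to the packaged library."""
    if path is None:
        path = Path(importlib.resources.files("polycipi").joinpath("data/motifs.yml"))
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    lib = [
        MotifPattern(
            domain=m["domain"],
            motif_id=m["id"],
            pattern=m["pattern"],
            required=bool(m.get("required", True)),
        )
        for m in doc["motifs"]
    ]
    ids = [m.motif_id for m in lib]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate motif ids in library")
    return lib


_DEFAULT_LIBRARY: list[MotifPattern] | None = None


def default_library() -> list[MotifPattern]:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = load_motif_library()
    return _DEFAULT_LIBRARY


def scan_motifs(peptide: str, library: list[MotifPattern] | None = None) -> DomainScanResult:
    """Scan a polypeptide for the Hel/Pro/RdRp motif complement.

    Records the leftmost match per motif (all matches are kept in
    ``all_hits``), evaluates the Hel < Pro < RdRp ordering constraint over
    the leftmost hits, and calls the protease-triad and motif-VI variants.
    An empty peptide yields an empty result with ``ordered_ok`` false.
    """
    if library is None:
        library = default_library()
    result = DomainScanResult()
    if not peptide:
        return result
    for motif in library:
        rx = motif.compiled()
        first = True
        for m in rx.finditer(peptide):
            hit = MotifHit(motif_id=motif.motif_id, start_aa=m.start() + 1, matched=m.group())
            result.all_hits.append(hit)
            if first:
                result.hits.append(hit)
                first = False

    by_domain: dict[str, list[MotifHit]] = {d: [] for d in DOMAIN_ORDER}
    for motif in library:
        for h in result.hits:
            if h.motif_id == motif.motif_id:
                by_domain[motif.domain].append(h)
    required_ok = all(
        any(h.motif_id == m.motif_id for h in result.hits)
        for m in library
        if m.required
    )
    for domain in DOMAIN_ORDER:
        req = [m.motif_id for m in library if m.domain == domain and m.required]
        found = {h.motif_id for h in result.hits}
        if req and all(r in found for r in req):
            result.domains_present.add(domain)

    ordered = required_ok and len(result.domains_present) == 3
    if ordered:
        for a, b in zip(DOMAIN_ORDER, DOMAIN_ORDER[1:]):
            if not by_domain[a] or not by_domain[b]:
                ordered = False
                break
            if max(h.start_aa for h in by_domain[a]) >= min(h.start_aa for h in by_domain[b]):
                ordered = False
                break
    result.ordered_ok = ordered

    result.triad_variant = call_triad_variant(peptide, result, library)
    result.motif6_variant = call_motif6_variant(peptide, result, library)
    return result


_TRIAD_RX = re.compile(f"G{_ANY}[CS]G")


def call_triad_variant(
    peptide: str,
    scan: DomainScanResult | None = None,
    library: list[MotifPattern] | None = None,
    triad_window_aa: int = 200,
) -> str:
    """Classify the protease catalytic-site tetrapeptide as GxCG or GxSG.

    When the scan located both flanking domains the search is restricted to
    the interval between the last Hel hit and the first RdRp hit. The
    upstream catalytic H and D triad members are searched within
    ``triad_window_aa`` residues upstream of the site and reported on the
    scan result when one was supplied.
    """
    if library is None:
        library = default_library()
    lo, hi = 0, len(peptide)
    if scan is not None:
        hel = scan.hits_for_domain(library, "Hel")
        rdrp = scan.hits_for_domain(library, "RdRp")
        if hel and rdrp:
            lo = max(h.start_aa - 1 + len(h.matched) for h in hel)
            hi = min(h.start_aa - 1 for h in rdrp)
            if lo >= hi:
                lo, hi = 0, len(peptide)
    m = _TRIAD_RX.search(peptide, lo, hi)
    if m is None:
        m = _TRIAD_RX.search(peptide)
    if m is None:
        return "absent"
    if scan is not None:
        upstream = peptide[max(0, m.start() - triad_window_aa): m.start()]
        scan.triad_h_found = "H" in upstream
        scan.triad_d_found = "D" in upstream
    return "GxCG" if m.group()[2] == "C" else "GxSG"


_MOTIF6_CONTEXT_RX = re.compile(f"[YFM]{_ANY}DD")
_MOTIF6_BARE_RX = re.compile(f"{_ANY}DD")


def call_motif6_variant(
    peptide: str,
    scan: DomainScanResult | None = None,
    library: list[MotifPattern] | None = None,
) -> str:
    """Classify the RdRp motif-VI (motif C) triplet by its first residue.

    The locus is the rightmost occurrence of the motif-VI context pattern
    downstream of the helicase hits and, when motif VII was located, before
    it — i.e. the occurrence consistent with the I..VIII motif ordering.
    G/A/S first residues map to GDD/ADD/SDD; anything else is ``other``.
    """
    if library is None:
        library = default_library()
    lo, hi = 0, len(peptide)
    if scan is not None:
        hel = scan.hits_for_domain(library, "Hel")
        if hel:
            lo = max(h.start_aa - 1 + len(h.matched) for h in hel)
        after = [h for h in scan.hits if h.motif_id in ("RdRp-VII", "RdRp-VIII")]
        if after:
            hi = min(h.start_aa - 1 for h in after)
        if lo >= hi:
            lo, hi = 0, len(peptide)
    matches = list(_MOTIF6_CONTEXT_RX.finditer(peptide, lo, hi))
    if not matches:
        matches = list(_MOTIF6_BARE_RX.finditer(peptide, lo, hi))
    if not matches:
        return "absent"
    triplet = matches[-1].group()[-3:]
    return {"G": "GDD", "A": "ADD", "S": "SDD"}.get(triplet[0], "other")


# Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hydropathy_profile(peptide: str, window_aa: int = 19) -> list[float]:
    """Sliding-window mean Kyte–Doolittle hydropathy.

    Window ``i`` (0-based) covers residues ``i+1 .. i+window_aa``. Unknown
    residues (X) contribute 0. A peptide shorter than the window yields an
    empty profile.
    """
    if window_aa < 5 or window_aa % 2 == 0:
        raise ValueError("window_aa must be an odd integer >= 5")
    n = len(peptide)
    if n < window_aa:
        return []
    vals = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in peptide])
    kernel = np.ones(window_aa) / window_aa
    return list(np.convolve(vals, kernel, mode="valid"))


def predict_tm(
    profile: list[float],
    peptide_len: int | None = None,
    window_aa: int = 19,
    threshold: float = 1.6,
) -> TmPrediction:
    """Call transmembrane-helix windows from a hydropathy profile.

    Contiguous above-threshold windows are merged into candidate helices.
    ``has_central_tm`` is true when some above-threshold window has its
    center within the middle half (25–75 % span) of the peptide.
    """
    if not profile:
        return TmPrediction(windows=[], has_central_tm=False)
    if peptide_len is None:
        peptide_len = len(profile) + window_aa - 1
    windows: list[tuple[int, int, float]] = []
    central = False
    run_start = None
    run_best = -np.inf
    for i, v in enumerate(list(profile) + [-np.inf]):  # sentinel flushes last run
        if v > threshold:
            if run_start is None:
                run_start = i
                run_best = v
            else:
                run_best = max(run_best, v)
            center = i + (window_aa + 1) / 2  # 1-based residue at window center
            if 0.25 * peptide_len <= center <= 0.75 * peptide_len:
                central = True
        else:
            if run_start is not None:
                windows.append((run_start + 1, i - 1 + window_aa, float(run_best)))
                run_start = None
    return TmPrediction(windows=windows, has_central_tm=central)


def has_central_tm(peptide: str, window_aa: int = 19, threshold: float = 1.6) -> bool:
    """Convenience predicate used by ORF2b detection."""
    profile = hydropathy_profile(peptide, window_aa)
    return predict_tm(profile, peptide_len=len(peptide), window_aa=window_aa, threshold=threshold).has_central_tm
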