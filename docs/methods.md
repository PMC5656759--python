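# Methods

This note documents the models, procedures and numerical choices behind
`polycipi`, and what its synthetic data do and do not establish.

## Coordinate and alphabet conventions

All nucleotide coordinates are 1-based and inclusive, and every ORF span
includes its stop codon; genome lengths exclude the poly(A) tail. This is
the convention of the published architecture table packaged in
`polycipi/data/layout_table.tsv`, where missing cells are stored as absent
(never 0) and two partially printed ORFs (a 3′-truncated ORF5 and a
5′-truncated ORF3) are kept as partial coordinate pairs so the intergenic
arithmetic still covers all 15 rows. RNA input (`U`) is silently mapped to
`T` on read: these are RNA viruses, but all deposited sequence and search
machinery is DNA-alphabet.

## Architecture inference

`find_orfs` enumerates forward-strand ATG→stop spans, keeping the 5′-most
ATG per (frame, stop) pair; the default minimum of 150 nt sits below the
shortest annotated ORF in the family (ORF3a, 210 nt). Only the forward
strand is scanned because the genomes are positive-sense; reverse-deposited
database records are expected to be orientation-normalized at ingest.

`infer_layout` proceeds in three steps:

1. **Long ORF.** The longest candidate whose polypeptide contains the Hel,
   Pro and RdRp motif complement in order is ORF5. If no candidate has the
   motifs, the longest ORF is used and the result flagged
   (`orf5_motifs_missing`).
2. **Upstream chain.** ORF1–ORF4 are the four ORFs upstream of ORF5 that
   maximize total coding length subject to every junction gap lying in
   [−20, +60] nt (gap = next start − previous end − 1; negative = overlap).
   These bounds quantify "closely spaced, often overlapping": they cover
   every junction in the published table, including a 48-nt gap and 4–14 nt
   overlaps, and are configurable. One junction may exceed the gap bound if
   a short intervening ORF bridges it with both sub-junctions in range;
   the bridge is reported as ORF3a. The maximization is a small DP over
   the candidate DAG with a "bridge used" bit; it is deterministic, and a
   genome with no admissible chain yields a "not polycipivirus-like"
   outcome object carrying the partial evidence rather than an exception.
3. **ORF2b.** Among candidates starting within 120 nt of ORF2's start in
   the +1 frame relative to ORF2 ((start − ORF2.start) mod 3 == 1), at
   least 200 nt long and ending by ORF2.end + 60, the one whose peptide
   has a predicted central transmembrane helix is ORF2b.

Frame offsets relative to ORF5 are displayed as {0, +1, −1} for
(Δstart mod 3) ∈ {0, 1, 2} — the genome-map label convention; the
arithmetic behind the labels is this package's choice. Poly(A) stripping
removes the entire trailing A-run when it reaches 10 nt, so inference is
invariant to tail presence and length. The 5′-completeness signature is
`seq.startswith("TTT")` with A+T fraction ≥ 0.7 over the first 25 nt,
quantifying the "AU-rich tract with 5′-terminal UUU" shared by
5′-complete genomes.

## Motif scanning

Motif patterns are data, not code: the default YAML library encodes
consensus-style picorna-like patterns (Walker A `G..G.GK[ST]`, protease
nucleophile `G.[CS]G` with context, eight RdRp motifs including the
motif-VI locus `[YFM].DD`). `.` matches the 20 standard residues; `X` and
`*` never match, so unknown positions in partial transcript translations
cannot complete a motif. One deliberate deviation from textbook motifs:
the library's Walker B pattern ends in an acidic `DE` pair rather than
`DD`, keeping the helicase locus disjoint from the motif-VI `xDD` locus so
the two calls cannot collide on short peptides.

The protease-triad call restricts the `G.[CS]G` search to the interval
between the last helicase hit and the first RdRp hit when both exist; the
upstream catalytic H and D are searched within a 200-aa window (the exact
residue spacing of the triad is not standardized for this group, so the
window is configurable and the H/D findings are reported as flags rather
than gating the call). The motif-VI call takes the rightmost `[YFM].DD`
occurrence downstream of the helicase and upstream of motif VII when
present, classifying the triplet by its first residue (G/A/S → GDD/ADD/SDD,
else `other`).

The transmembrane stand-in is a Kyte–Doolittle sliding window of 19
residues with threshold 1.6 — standard hydropathy-plot defaults — and
"central" means the window center falls in the 25–75 % span of the
peptide, quantifying "a transmembrane domain in the middle of the
protein". This replaces an HMM-based TM predictor and is adequate for the
planted-versus-scrambled-core distinction the pipeline needs; it is not a
general-purpose topology predictor.

## Homology and the reciprocal-best-hit filter

Alignment is affine-gap Smith–Waterman / Needleman–Wunsch under BLOSUM62
with gap open 11 / extend 1 (a gap of length L costs 11 + L), via
Bio.Align's deterministic aligner; percent identity is computed over all
alignment columns of the global alignment, gaps included — stated here
because aligners disagree on the denominator. The E-value is the
Karlin–Altschul form E = K·m·n·exp(−λ·score) with fixed gapped-BLOSUM62
constants (λ = 0.267, K = 0.041); it is used purely as a retention
threshold, not as a calibrated statistic.

`rbh_filter` mirrors transcriptome-mining practice: candidates shorter
than 10 kb are dropped; the candidate's longest-ORF peptide must best-hit
a designated reference in the panel with E < 10⁻⁶ over at least 100
aligned columns (300 nt of coding sequence); and the reference's own
search over the candidates plus the panel must return the candidate ahead
of every non-reference entry. The reciprocal search deliberately includes
the decoys so the reference is free to "choose" one, which is what makes
the filter reciprocal rather than merely best-hit.

## Phylogenetics

Distances are raw p-distances (1 − identity/100) from pairwise global
alignments — no multiple-hit correction, by design, since only clade
structure is asked of the tree; correction hooks can be added by
substituting the distance function. Neighbor joining uses the
Studier–Keppler Q criterion with ties broken by the lexicographically
smallest leaf label under each node, so trees are byte-for-byte
reproducible; negative limb estimates are clamped to zero and the total
clamped deficit recorded on the tree. On additive matrices the
implementation recovers topology and branch lengths exactly (and its
topologies match an independent NJ implementation). Midpoint rooting and
the leaf-set-equality monophyly test operate on scikit-bio trees; Bayesian
inference and posterior supports are out of scope — the clade claims
exercised here (family monophyly, genus clusters) are distance-scale
claims.

## Classification

Family membership requires (a) the complete ORF1–ORF5 chain within the
junction constraints, (b) the ordered Hel/Pro/RdRp complement on the ORF5
peptide, and (c) ORF5 covering at least half the genome (the long ORF
spans roughly the 3′ two-thirds in every known member; 0.5 is a safe
floor). The genus rule is a decision tree distilled from the genus
descriptions: ORF2b → Sopolycivirus; else motif VI = ADD → Chipolycivirus;
else Hupolycivirus. The true delineation is phylogenetic, so a rooted tree
with labelled genus clades can be supplied as a cross-check; conflicts are
flagged in the evidence but the rule verdict stands, keeping
classification runnable without a tree.

## Variants and coverage

The pileup TSV (genome, position, depth, four base counts) is the
contract; read mapping itself is out of scope. SNPs are kept when the
alternative allele exceeds **strictly** 10 % of reads, matching the
">10 % of reads" rule. A SNP inside overlapping ORFs yields one
synonymous/nonsynonymous call per containing main ORF (ORF1–ORF5);
double-coding accessory ORFs (ORF2b, ORF3a) are excluded from tallies by
default because published per-ORF counts imply main-ORF accounting, and
can be opted in. Stop gain/loss is labelled `stop_affecting` and counted
as non-synonymous in totals. Coverage is summarized as a centered 1000-nt
sliding-window mean, truncated at the genome ends.

## Synthetic data: the stated world

The default `GenomeSpec` is the SINV-2-shaped architecture: 5′UTR 301 nt
with the UUU/AU-rich signature; ORF lengths 777 / 231 (ORF2b) / 804 / 777
/ 1149 / 6462 nt; junction gaps −4, −8, −4; IGR 662 nt; 3′UTR 387 nt;
poly(A) 30 nt; serine protease (GxSG) and canonical GDD. Family-level
spec ranges (5′UTR 130–370, IGR 336–768, 3′UTR 385–479 among 3′-complete
genomes) are the published ranges. Families evolve a template along a
random (or supplied) tree with per-branch lengths drawn U(0.02, 0.08)
substitutions/site — divergences at which architecture and clade structure
remain recoverable, i.e. a "highly divergent but clearly related" family.

Construction is codon-wise with bounded rejection: mandatory cells (start
and stop codons, motif-block codons, the 21-residue ORF2b core, the 5′
signature head) are fixed first, the rest filled randomly, then a repair
loop re-rolls non-mandatory cells until (a) no planted ORF has an internal
stop, (b) no upstream in-frame ATG extends a planted ORF, (c) no unplanned
ORF is longer than the shortest planted one, and (d) the long-ORF peptide
has no motif-library matches outside the planted blocks — so the scan
ground truth is exact, not merely probable. The hydrophobic ORF2b core is
drawn from I/L/V/F codons whose composition guarantees a Kyte–Doolittle
window mean above threshold and which cannot form a stop codon or ATG in
any reading frame (the charged D/E/K/R alternative, used to model a
non-membrane core, is T-free for the same reason). Evolution along the
tree rejects proposals that hit mandatory cells or create stops inside
planted ORFs, so every leaf keeps the template's layout.

What a green synthetic test does **not** establish: performance on real
TSA contigs with sequencing errors, chimeras or incomplete ends; motif
sensitivity beyond the consensus patterns shipped; TM-prediction accuracy
against real membrane proteins; or phylogenetic behavior under
substitution-model misspecification. The pileup simulator has Poisson
depth and binomial allele counts with no sequencing-error model, so SNP
false-positive behavior under miscalls is untested by design.

## Degenerate inputs and tie-breaks

Empty FASTA files parse to empty lists; an empty peptide scan returns an
empty result with ordering false; local alignments whose optimum is empty
report score 0. Search ranking ties break by percent identity then subject
id; longest-ORF ties prefer the forward strand, then the 5′-most start;
NJ Q-ties and the aligner's co-optimal traceback are resolved
deterministically (the package's outputs are reproducible byte for byte
given a seed).

## Known limitations

Heuristic seeded search (BLAST-style k-mer indexing) is not implemented —
searches are exhaustive pairwise alignments, fine at panel scale; E-values
are nominal; IRES structure, polyprotein cleavage sites, VPg and
structure-homology (HHpred-class) evidence are out of scope; negative-
strand coverage is carried only if supplied as a separate pileup channel.
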