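# polycipi

Comparative genomics of **polycistronic picorna-like RNA viruses** — the
polycipivirus group typified by Solenopsis invicta virus 2 (SINV-2) and its
relatives from ants and other arthropods.

These viruses have a distinctive architecture among picorna-like viruses:
a polyadenylated positive-sense genome of ~11–12 kb with **four closely
spaced (often overlapping) 5′-proximal ORFs** (three encoding jelly-roll
capsid domains), an intergenic region of a few hundred nucleotides, and
**one long 3′ ORF** spanning more than half the genome that encodes the
non-structural polyprotein with superfamily III helicase (Hel), 3C-like
chymotrypsin-related protease (Pro) and superfamily I RNA-dependent RNA
polymerase (RdRp) domains, in that order. Ant-associated members carry an
extra short ORF (ORF2b) overlapping ORF2's 5′ end in the +1 frame and
encoding a small protein with a central transmembrane helix. Unusually,
the protease is a **serine** protease (catalytic site GxSG rather than
GxCG), and two divergent members carry an **ADD** instead of the canonical
GDD at RdRp motif VI (motif C).

`polycipi` is a library (no CLI) for everyone who needs to recognize,
annotate or simulate this architecture:

| module | what it does |
|---|---|
| `polycipi.seqio` | FASTA/GFF3/pileup/hit-table I/O; the packaged 15-genome architecture table |
| `polycipi.orf_layout` | ORF enumeration, poly(A) stripping, five-ORF layout inference, ORF2b detection, UTR/IGR arithmetic |
| `polycipi.motif_scan` | Hel/Pro/RdRp motif scanning (YAML-configurable library), GxSG/GxCG and GDD/ADD/SDD variant calls, Kyte–Doolittle TM prediction |
| `polycipi.homology` | six-frame translation, longest-ORF extraction, BLOSUM62 local/global alignment, E-values, ranked search, reciprocal-best-hit contig filtering |
| `polycipi.phylo` | p-distance matrices, neighbor joining, midpoint rooting, monophyly tests, Newick I/O |
| `polycipi.classify` | family-membership criteria and the three-genus decision tree (Sopolycivirus / Hupolycivirus / Chipolycivirus) |
| `polycipi.variants` | pileup-based coverage windows and synonymous/nonsynonymous SNP classification (>10 %-of-reads rule) |
| `polycipi.synthetic` | seeded generators for genomes, evolved families, decoys and pileups, all with ground truth |

All coordinates are 1-based, inclusive, with the stop codon included in
each ORF — the convention of the published architecture table that ships
with the package.

## Worked example

```python
from polycipi.orf_layout import infer_layout
from polycipi.classify import assign_genus
from polycipi.synthetic import GenomeSpec, generate_genome

record, truth, _ = generate_genome(GenomeSpec(seed=1), genome_id="demo")
inference = infer_layout(record)
for orf in inference.layout.orfs:
    print(orf.orf_id, orf.start, orf.end, orf.frame_offset_vs_orf5)
print(assign_genus(inference).genus)
```

prints

```
ORF1 302 1078 -1
ORF2 1075 1878 1
ORF2b 1079 1309 -1
ORF3 1871 2647 -1
ORF4 2644 3792 1
ORF5 4455 10916 0
Sopolycivirus
```

i.e. the inferred architecture: four 5′ ORFs whose stop/start codons
overlap by 4–8 nt (ORF2 begins 4 nt *before* ORF1 ends), the overlapping
ORF2b in the +1 frame relative to ORF2, and the long 3′ ORF at
4455–10916 preceded by a 662-nt intergenic region — with the genus called
Sopolycivirus because ORF2b (with its central transmembrane helix) is
present. Frame offsets are relative to the long ORF, the convention used
in genome-map figures of this virus group.

Each script in `examples/` demonstrates one capability end to end
(annotation + GFF3 export, motif scanning, reciprocal-best-hit discovery,
NJ phylogeny with a monophyly test, genus classification of the 15
published genomes, coverage/SNP analysis) and prints what the numbers
mean.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline quantities from scratch: the UTR/IGR
arithmetic of all 15 published genome records and their 11/2/2 genus
split, the published per-ORF synonymous/total SNP pairs, a synthetic
generate→infer→classify round trip, reciprocal-best-hit verdicts for
related and off-target contigs, NJ monophyly of an evolved family, and
SNP recovery at mean coverage 1348 — then writes the JSON result map to
`--out`. The `--seed` argument drives every source of randomness.
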