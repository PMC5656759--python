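"""Scan a non-structural polypeptide for the Hel/Pro/RdRp motif complement.

The long 3' ORF of a family genome encodes helicase, protease and RdRp
domains in that order. This example scans the generated ORF5 polypeptide,
prints every motif hit, and calls the protease-triad variant (the family is
unusual in using a serine protease, GxSG) and the RdRp motif-VI variant
(canonical GDD; two family members carry ADD).
"""

from polycipi.motif_scan import scan_motifs
from polycipi.synthetic import GenomeSpec, generate_genome

_, layout, truth = generate_genome(GenomeSpec(seed=3, motif6_variant="ADD", orf2b=None))
peptide = layout.orf("ORF5").peptide

scan = scan_motifs(peptide)
print(f"ORF5 polypeptide: {len(peptide)} aa")
for hit in scan.hits:
    print(f"  {hit.motif_id:10s} at aa {hit.start_aa:>5}  {hit.matched}")
print(f"domains present: {sorted(scan.domains_present)}  ordered Hel<Pro<RdRp: {scan.ordered_ok}")
print(f"protease catalytic site: {scan.triad_variant} (planted {truth.triad})")
print(f"RdRp motif VI: {scan.motif6_variant} (planted {truth.motif6_variant})")
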