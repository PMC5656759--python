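"""Reciprocal-best-hit discovery of family-related contigs.

Emulates transcriptome-assembly mining: candidate contigs are kept only if
they are long (>10 kb), their longest-ORF peptide best-hits a reference in
the search panel with a significant E-value, and the reference points back
at the candidate ahead of every decoy (iflavirus/dicistrovirus-style
off-target genomes are discarded).
"""

import numpy as np

from polycipi.homology import longest_orf_peptide, rbh_filter
from polycipi.synthetic import GenomeSpec, generate_decoys, generate_genome, mutate_genome

reference, _, truth = generate_genome(GenomeSpec(seed=10), genome_id="reference")
decoys, decoy_truths = generate_decoys("dicistro_like", 2, seed=11, with_truth=True)
panel = [("reference", longest_orf_peptide(reference.seq))] + [
    (d.id, longest_orf_peptide(d.seq)) for d in decoys
]

rng = np.random.default_rng(12)
candidates = [
    mutate_genome(reference, 0.05, rng, truth=truth, new_id="contig_related"),
    mutate_genome(decoys[0], 0.05, rng, truth=decoy_truths[0], new_id="contig_offtarget"),
    generate_decoys("random", 1, seed=13, length=8000)[0],  # an 8 kb fragment
]

for d in rbh_filter(candidates, {"reference"}, panel):
    fwd = f"best hit {d.fwd_best.subject_id} (score {d.fwd_best.score:.0f}, E {d.fwd_best.evalue:.2g})" if d.fwd_best else "no forward hit"
    print(f"{d.candidate_id:18s} retained={d.retained!s:5s} reason={d.reason:18s} {fwd}")
print("\nA retained contig is reciprocally closest to the reference; the rest are discarded.")
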