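"""Distance phylogeny of a synthetic virus family with outgroups.

Evolves 10 genomes from one template along a random tree, adds two
unrelated outgroup genomes, builds a p-distance matrix from pairwise
global alignments of the ORF5 polypeptides, joins it with NJ, midpoint
roots the tree and tests whether the family forms a single clade.
"""

from polycipi.phylo import is_monophyletic, midpoint_root, nj_tree, pdistance_matrix, write_newick
from polycipi.synthetic import FamilySpec, GenomeSpec, evolve_family, generate_genome

template = GenomeSpec(
    utr5_len=60, utr3_len=60, igr_len=120,
    orf_lens={"ORF1": 300, "ORF2": 450, "ORF3": 300, "ORF4": 450, "ORF5": 1200},
    orf2b=None, seed=20,
)
leaves, true_tree = evolve_family(FamilySpec(template=template, n_taxa=10, seed=21))
peptides = [(rec.id, lay.orf("ORF5").peptide) for rec, lay in leaves]
for k in range(2):
    spec = GenomeSpec(**{**template.__dict__, "seed": 30 + k})
    _, lay, _ = generate_genome(spec, genome_id=f"outgroup{k}")
    peptides.append((f"outgroup{k}", lay.orf("ORF5").peptide))

dm = pdistance_matrix(peptides)
family = {rec.id for rec, _ in leaves}
within = [dm[a, b] for a in sorted(family) for b in sorted(family) if a < b]
print(f"mean within-family p-distance: {sum(within) / len(within):.3f}")
print(f"family vs outgroup0 p-distance: {dm['taxon01', 'outgroup0']:.3f}")

tree = midpoint_root(nj_tree(dm))
print(f"family monophyletic: {is_monophyletic(tree, family)}")
print(write_newick(tree))
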