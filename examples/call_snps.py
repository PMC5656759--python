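"""Coverage and SNP analysis from a simulated pileup.

Simulates deep sequencing of a genome (mean depth 1348, the kind of
coverage a heavily infected host sample yields), plants SNPs at 25%
frequency, recovers every variant above the strict >10%-of-reads rule, and
classifies each as synonymous/nonsynonymous per containing ORF.
"""

import numpy as np

from polycipi.orf_layout import strip_polya
from polycipi.synthetic import GenomeSpec, generate_genome, simulate_pileup
from polycipi.variants import aggregate_counts, classify_snp, coverage_windows, filter_snps, mean_coverage

record, layout, _ = generate_genome(GenomeSpec(seed=40), genome_id="demo")
genome = strip_polya(record)

rng = np.random.default_rng(41)
positions = sorted(int(p) for p in rng.choice(np.arange(100, len(genome.seq) - 100), 15, replace=False))
planted = []
for p in positions:
    ref = genome.seq[p - 1]
    alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
    planted.append((p, alt, 0.25))

pileup, _ = simulate_pileup(genome, mean_depth=1348, snps=planted, seed=42)
print(f"mean coverage: {mean_coverage(pileup, len(genome.seq)):.0f}")
windows = coverage_windows(pileup, len(genome.seq), window=1000)
print(f"1000-nt sliding-window coverage: min {windows.min():.0f}, max {windows.max():.0f}")

snps = filter_snps(pileup, genome, min_frac=0.10)
calls = [c for s in snps for c in classify_snp(s, layout, genome)]
agg = aggregate_counts(calls)
print(f"SNPs above 10% of reads: {len(snps)} (planted {len(planted)})")
for orf, (syn, tot) in sorted(agg.per_orf.items()):
    print(f"  {orf}: {syn}/{tot} synonymous")
print(f"totals: {agg.synonymous}/{agg.total} synonymous, {agg.noncoding} noncoding")
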