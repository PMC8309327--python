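"""Heterozygosity and repeat content from the spectrum mixture fit.

Simulates a 300-kb diploid with 1% heterozygosity and 20% of the haploid
length in 2-copy repeats, fits the four-component negative-binomial mixture,
and prints the genome-property report. Expect ~1% heterozygosity and a
repeat percentage near the simulated 20%.
"""

import kspectra as ks

spec = ks.GenomeSpec(haploid_length=300_000, ploidy_structure="AB",
                     het_rate=0.01, repeat_fraction=0.2,
                     repeat_unit_length=500, seed=9)
haps = ks.simulate_genome(spec)
reads = ks.simulate_reads(haps, ks.ReadSimConfig(coverage=80, seed=10))
table = ks.count_canonical_kmers(reads, 21)
hist = ks.histogram_from_counts(table)

fit = ks.fit_spectrum(hist, k=21, ploidy=2)
print(fit.property_table())
print()
p = fit.params
print(f"fitted mixture: lambda = {p.lam:.2f} (per-haplotype k-mer depth), "
      f"rho = {p.rho:.3f}, r = {p.r:.4f}, d = {p.d:.3f}")
print(f"ground truth: het 1.00%, repeat fraction 20%, haploid 300,000 bp")
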