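"""Simulate a small heterozygous diploid and inspect its k-mer spectrum.

Builds a 200-kb diploid with 1% heterozygosity, samples 60x pooled coverage
of 151-bp reads with 0.1% substitution errors, counts canonical 21-mers and
prints the spectrum around its two coverage peaks.
"""

import numpy as np

import kspectra as ks

spec = ks.GenomeSpec(haploid_length=200_000, ploidy_structure="AB",
                     het_rate=0.01, seed=42)
haps = ks.simulate_genome(spec)
reads = ks.simulate_reads(haps, ks.ReadSimConfig(coverage=60, seed=43))
print(f"simulated {haps.ploidy} haplotypes of {haps.haploid_length:,} bp; "
      f"{reads.n_reads:,} reads = {reads.total_bases / 1e6:.1f} Mb")

table = ks.count_canonical_kmers(reads, 21)
hist = ks.histogram_from_counts(table)
print(f"{len(table):,} distinct canonical 21-mers, "
      f"{hist.total_instances:,} instances")

x_err = ks.find_error_cutoff(hist)
peaks = ks.find_peaks(hist, x_err)
print(f"error cutoff x_err = {x_err}; modal depth M = {peaks.peak_depth}; "
      f"secondary peaks at {peaks.secondary_peaks}")
print("(per-haplotype k-mer depth is coverage/2 x (L-k+1)/L ~= "
      f"{60 / 2 * 131 / 151:.1f}, so the peaks near lambda and 2*lambda mark "
      "heterozygous and homozygous k-mers)")

dense = hist.dense()
for depth in range(x_err + 1, min(hist.max_depth, 70) + 1, 4):
    bar = "#" * int(60 * dense[depth] / dense[peaks.peak_depth])
    print(f"{depth:>4} {dense[depth]:>8} {bar}")
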