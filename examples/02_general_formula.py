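"""Genome size from the spectrum peak (the general formula).

Simulates a 500-kb haploid at 40x, finds the error cutoff and modal k-mer
depth M, and applies G = T / M with N = M L / (L - k + 1), for k = 21 and 31.
The printed G should land within a few percent of the true 500,000 bp.
"""

import kspectra as ks

spec = ks.GenomeSpec(haploid_length=500_000, ploidy_structure="A", seed=7)
haps = ks.simulate_genome(spec)
reads = ks.simulate_reads(haps, ks.ReadSimConfig(coverage=40, seed=8))

print("k\tx_err\tM\tN\tT\tG\terror%")
for k in (21, 31):
    table = ks.count_canonical_kmers(reads, k)
    hist = ks.histogram_from_counts(table)
    x_err = ks.find_error_cutoff(hist)
    peaks = ks.find_peaks(hist, x_err)
    res = ks.general_formula_size(hist, x_err, peaks.peak_depth, L=151, K=k)
    err = abs(res.genome_size - 500_000) / 500_000 * 100
    print(f"{k}\t{res.x_err}\t{res.M}\t{res.N:.2f}\t{res.total_kmers}"
          f"\t{res.genome_size:,.0f}\t{err:.2f}")
print("T = k-mer instances above the error cutoff; M = modal depth; "
      "N = implied base depth; G = T/M estimates the genome size.")
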