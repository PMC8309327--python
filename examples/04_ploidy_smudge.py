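"""Ploidy from heterozygous k-mer pairs (smudge analysis).

Simulates a diploid (AB) and a triploid (AAB), finds one-substitution k-mer
pairs, and calls the ploidy structure from where their (minor coverage
ratio, coverage sum) mass concentrates: (1/2, 2*lambda) for AB,
(1/3, 3*lambda) for AAB. A fully homozygous genome yields no pairs and the
analysis refuses to call — the method's documented blind spot.
"""

import kspectra as ks
from kspectra import smudge

for structure, cov in (("AB", 60), ("AAB", 66), ("AAAA", 80)):
    het = 0.0 if structure == "AAAA" else 0.01
    spec = ks.GenomeSpec(haploid_length=200_000, ploidy_structure=structure,
                         het_rate=het, seed=13)
    haps = ks.simulate_genome(spec)
    reads = ks.simulate_reads(haps, ks.ReadSimConfig(coverage=cov, seed=14))
    table = ks.count_canonical_kmers(reads, 21)
    hist = ks.histogram_from_counts(table)
    fit = ks.fit_spectrum(hist, k=21, ploidy=len(structure))
    lam = 2 * fit.params.lam / len(structure)  # per-copy k-mer depth
    try:
        grid = smudge.analyze(table, lam=lam,
                              x_err=ks.find_error_cutoff(hist))
    except ks.NoPairsError as e:
        print(f"true {structure}: no call ({e})")
        continue
    top = sorted(grid.structure_probs.items(), key=lambda kv: -kv[1])[:3]
    shares = ", ".join(f"{tok} {share:.2f}" for tok, share in top)
    print(f"true {structure}: called {grid.ploidy_call} from "
          f"{grid.n_pairs:,} pairs (shares: {shares})")
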