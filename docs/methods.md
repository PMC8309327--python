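# Methods

## Scope and data flow

kspectra implements the comparative genome-size workflow end to end at desk
scale: simulate a genome with known properties → count canonical k-mers →
build the coverage spectrum → estimate size from the spectrum peak →
fit a mixture model for heterozygosity and repeat content → infer ploidy
from heterozygous k-mer pairs → aggregate estimates across k and compare
with flow-cytometry C-values. Each stage is usable on its own; the pipeline
chains them into a run directory with a manifest.

## The synthetic-data generator

The simulator is the source of ground truth, so its model is deliberately
minimal and exactly known:

- **Haplotypes.** One template ("A") sequence is drawn i.i.d. with a target
  GC fraction (default 0.45, in the range typical of plant nuclear
  genomes). The divergent ("B") haplotype applies i.i.d. substitutions at
  rate `het_rate`; all A copies are identical and all B copies are
  identical, so a ploidy token like AAAAAB has exactly one divergent copy.
  Divergence is substitution-only — no indels — which keeps haplotypes
  length-matched and makes every heterozygous site produce a k-mer pair
  exactly one substitution apart, the signal the ploidy caller uses.
- **Repeats.** A central block covering `repeat_fraction` of the haploid
  length is tiled with repeat units (default 500 bp), each unit copied
  `repeat_copy_number` times (default 2, an exact-copy "duplicated"
  signature at twice the baseline depth; a per-copy mutation knob exists
  and defaults to 0).
- **Reads.** Fixed-length reads (default 151 bp, the common paired-end
  Illumina length) are drawn uniformly over haplotypes and positions at a
  pooled coverage (per-haplotype depth = coverage/ploidy), with i.i.d.
  substitution errors (default 0.1%, matching the error rates reported for
  quality-processed short-read libraries). Coverage below 10× is rejected:
  spectrum methods need the genomic peak clear of the error peak.
  Qualities are a constant Phred 30 and are never used downstream; paired
  output affects file layout only.
- **`long_repeat_recovery`.** Real libraries under-recover long repetitive
  regions (the standard explanation for k-mer sizes falling short of
  flow-cytometry values in repeat-rich genomes). Under perfectly uniform
  sampling the general formula is provably repeat-insensitive — T counts
  every repeat instance — so that bias cannot occur in the default
  simulator. Setting `long_repeat_recovery < 1` downsamples reads starting
  inside annotated repeat intervals and reproduces the downward bias; the
  default is 1.0 (uniform).

What the simulator does **not** emulate: indels and structural variation,
GC-biased coverage, position-dependent error profiles, PCR duplicates.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions, not robustness to every artefact of real
libraries.

## Canonical k-mer counting

Odd k (≤ 63) only: odd k cannot be palindromic, so the canonical form —
the lexicographic minimum of a k-mer and its reverse complement — is always
strict. K-mers are 2-bit packed (one 64-bit limb up to k = 31, two limbs
above); all windows of a read batch are coded in one vectorised pass, the
reverse-complement codes come for free from coding the reversed
complemented batch, and counts are produced by sort/unique. Windows
touching any non-ACGT character are skipped. `.histo` files are written
dense from depth 1 (zero rows included, the counter-tool convention);
the reader accepts sparse files. No maximum-depth clamp is applied by
default (a `clamp` method exists for compatibility with capped counters):
the deep tail carries the repeat signal the length accounting needs.

## Error cutoff and the general formula

The error cutoff x_err is the first local minimum scanning up from depth 2
(strictly decreasing on the left, non-increasing on the right; plateaus
resolve to their left edge). A monotonically decreasing spectrum has no
separable genomic peak and raises an error advising more coverage. The
peak depth M is the global mode above x_err, ties to the smaller depth;
secondary peaks are local maxima with prominence ≥ 5% of h(M) (the region
is zero-padded so a mode at the range boundary is still detected). The
estimator is G = T/M with T = Σ_{x>x_err} x·h(x) and implied base depth
N = M·L/(L−K+1). For a heterozygous diploid the global mode may be either
the λ or the 2λ peak depending on heterozygosity (the α₁/α₂ weight ratio);
the convention used is recorded in the result metadata. Because M is an
integer, G is quantised in steps of roughly 1/M, which dominates the
spread of a k-sweep at desk-scale depths.

## The spectrum mixture model

Expected distinct k-mers at depth x:

    f(x) = A · Σ_{m=1..4} α_m · NB(x; mean = mλ, variance = mλ(1+ρ))

with q = (1−r)^k and α₁ = 2(1−d)(1−q), α₂ = (1−d)q + d(1−q)²,
α₃ = 2dq(1−q), α₄ = dq². ρ → 0 is the Poisson limit (the NB size parameter
is mλ/ρ). Fitting is weighted least squares with weights 1/max(h,1) over
(x_err, x_max], multi-started at λ ∈ {M, M/2, 2M} to escape the
heterozygous/homozygous peak swap; after a first pass the range is clipped
at x_max = 8λ̂ (an unbounded tail destabilises least squares at desk scale)
and the fit repeated. Convergence tolerances: 1e-8 on relative residual
change, 400 function evaluations per start.

**Identifiability.** A clean two-peak spectrum admits exact impostors:
(λ, r, d=0) is reproduced both by (λ, r large, d = α₂) and by
(λ/2, r=0, d) — the duplicated components can impersonate heterozygosity
and vice versa whenever the 3λ/4λ mass is negligible. Both impostors
inflate d, so the fit (a) restricts r to [0, 0.2] — beyond ~20% per-base
divergence the substitution model the mixture describes no longer applies —
and (b) among starts whose costs agree within 5%, selects the smallest
duplicated fraction, then the smallest heterozygosity. On simulated grids
(r up to 1.5%, d up to 0.2) this recovers r to a median absolute error
well under 0.002.

**Derived quantities.** het % = 100·r̂. Haploid length = T/(ploidy·λ̂)
(diploid divisor 2λ̂ by default; pass the ploidy when known). Unique length
weights each depth's instances by the fitted posterior mass of the
non-duplicated components (α₁ plus the (1−d)q share of α₂); depths where
the model density underflows (deep exact repeats) are counted as repeat.
Repeat length is the difference, and model-fit % is the L1 residual ratio
100·(1 − Σ|h−f̂|/Σh) over the fit range — the "model fit" figure reported
by profiling tools is tool-internal, so this definition is fixed here.

## Hetmer ploidy inference

Retained k-mers (coverage in (x_err, 16λ] by default) are paired at
Hamming distance 1 in any position and either orientation, by enumerating
all 3k substitution neighbours against the retained-set hash (O(3k·n);
the all-pairs scan is kept as a test oracle). A k-mer participating in
more than one pair is dropped entirely. Pairs are binned over
(minor ratio ∈ (0, 0.5], width 0.02) × (coverage sum, width λ/4) and each
pair is assigned to the nearest theoretical centre (a/n, nλ) for
n = 2..8, 1 ≤ a ≤ n/2, with Euclidean distance in the normalised space
(ratio/0.5, total/8λ); the call is the structure with the largest mass
share. λ is the per-copy depth: from the diploid-convention fit,
λ_copy = 2λ̂/ploidy. Pairing requires k ≤ 31 (single-limb codes); the
standard choice is k = 21.

Any genome yields a handful of chance Hamming-1 collisions, so the
end-to-end `analyze()` refuses to call from fewer than 30 pairs and raises
the no-pairs error instead — this is what reproduces the method's
documented failure on totally homozygous polyploids (simulated AAAA gives
no call, not a wrong call).

## Cytometry arithmetic

2C = (F_sample/F_standard) × 2C_standard (tomato, 1.96 pg, is the default
standard); 1 pg = 978 Mbp, hence 1C [Mbp] = 489 × 2C [pg] exactly.
Replicates aggregate as mean ± sample SD (n−1 throughout the package — the
only convention under which published k-sweep summaries reproduce from
their own columns). Report rounding: pg to 2 decimals, Mbp to 1; the
k-mer-derived 2C column uses the visible chain Mbp → 1C pg rounded to 2
decimals → doubled, the only chain consistent with published 1C/2C
pairings. One published comparison table prints a 1C Mbp value inconsistent
with its own 2C pg × 489 (973.11 vs 934.0); the package always follows the
formula.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run everything on synthetic
genomes of 0.1–1 Mb at 40–80× coverage — large enough that binomial noise
is far below the tolerances tested (a 1-Mb diploid at 80× yields ~70M
k-mer instances), small enough that the whole suite runs in minutes on one
CPU. Determinism is end-to-end: every RNG is seeded from the config, no
timestamps are written, and a pipeline rerun is byte-identical.

## Known limitations

- The mixture model is diploid-shaped; for higher ploidies it still anchors
  λ usefully (via 2λ̂/p) but per-haplotype dosage components are not
  modelled.
- Heterozygosity estimates assume isolated SNPs; clustered variation
  violates the q = (1−r)^k geometry.
- The hetmer caller assumes one divergent haplotype class (A…AB…B); mixed
  divergence patterns produce multiple smudges it will split mass across.
- Integer peak depth quantises the general formula at low coverage; at the
  ~100× depths of real projects this is negligible.
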