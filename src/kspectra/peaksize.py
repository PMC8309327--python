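"""Error-k-mer cutoff, coverage-peak detection and the general-formula
genome-size estimator.

Sequencing errors create a mass of near-unique k-mers at very low depth; the
first local minimum of the spectrum scanning upward from depth 2 separates
that error peak from genomic k-mers. Above the cutoff, the modal depth M is
tied to base depth N through M = N (L - K + 1) / L (a read of length L holds
L - K + 1 k-mers), and genome size follows as G = T / M where T is the number
of k-mer instances above the cutoff.

For a heterozygous diploid the spectrum is bimodal: a peak near the
per-haplotype depth lambda (heterozygous k-mers) and a second near 2*lambda
(homozygous k-mers). By convention the general formula here uses the global
mode above the cutoff; the choice is recorded in the result metadata so both
conventions can be compared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .errors import NoCutoffError
from .kmercount import KmerHistogram

__all__ = [
    "SpectrumPeaks",
    "GeneralFormulaResult",
    "find_error_cutoff",
    "find_peaks",
    "general_formula_size",
]


@dataclass(frozen=True)
class SpectrumPeaks:
    """Error cutoff and coverage peaks of one spectrum."""

    x_err: int
    peak_depth: int
    secondary_peaks: tuple[int, ...] = ()


@dataclass(frozen=True)
class GeneralFormulaResult:
    """General-formula genome size estimate.

    Identities: N = M * L / (L - K + 1) and G = T / M, with T the number of
    k-mer instances at depth above ``x_err``.
    """

    M: int
    K: int
    L: float
    x_err: int
    N: float
    total_kmers: int
    genome_size: float
    peak_convention: str = "global-mode"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def tsv_header(self) -> str:
        return "k\tL\tx_err\tM\tN\tT\tG"

    def tsv_row(self) -> str:
        return (
            f"{self.K}\t{self.L:g}\t{self.x_err}\t{self.M}\t"
            f"{self.N:.6g}\t{self.total_kmers}\t{self.genome_size:.6g}"
        )


def find_error_cutoff(hist: KmerHistogram) -> int:
    """First local minimum of the dense spectrum scanning up from depth 2.

    Returns the smallest depth x >= 2 with h(x-1) > h(x) and h(x+1) >= h(x)
    (strictly-greater required on the left only, so plateaus resolve to their
    left edge). Raises :class:`NoCutoffError` for a monotonically decreasing
    spectrum, which indicates coverage too low to separate the genomic peak.
    """
    if hist.max_depth < 5:
        raise NoCutoffError("histogram too shallow (max depth < 5)")
    h = hist.dense()
    # one padding zero above the top so x = max_depth can qualify
    h = np.append(h, 0)
    for x in range(2, hist.max_depth + 1):
        if h[x - 1] > h[x] and h[x + 1] >= h[x]:
            return x
    raise NoCutoffError(
        "spectrum decreases monotonically: no genomic peak separable from "
        "the error peak; higher sequencing coverage is required"
    )


def find_peaks(
    hist: KmerHistogram,
    x_err: int,
    prominence_frac: float = 0.05,
) -> SpectrumPeaks:
    """Locate the modal depth and secondary peaks above the error cutoff.

    The primary peak M is the argmax of h(x) over x > x_err (ties break to
    the smaller depth). Secondary peaks are other local maxima whose
    prominence exceeds ``prominence_frac`` of h(M).
    """
    h = hist.dense()
    if x_err + 1 >= h.size:
        raise NoCutoffError("no histogram mass above the error cutoff")
    region = h[x_err + 1 :]
    M = int(np.argmax(region)) + x_err + 1
    floor = prominence_frac * h[M]
    # zero-pad so maxima at the region boundaries are detectable
    padded = np.concatenate(([0.0], region.astype(float), [0.0]))
    idx, _ = _scipy_find_peaks(padded, prominence=floor)
    secondary = tuple(int(i) - 1 + x_err + 1 for i in idx
                      if int(i) - 1 + x_err + 1 != M)
    return SpectrumPeaks(x_err=x_err, peak_depth=M, secondary_peaks=secondary)


def general_formula_size(
    hist: KmerHistogram,
    x_err: int,
    M: int,
    L: float,
    K: int | None = None,
) -> GeneralFormulaResult:
    """Genome size by the peak-depth general formula.

    T = sum of x * h(x) over x > x_err; G = T / M; implied base depth
    N = M * L / (L - K + 1).
    """
    if K is None:
        K = hist.k
    if K <= 0:
        raise ValueError("k-mer length K must be positive (pass K explicitly "
                         "if the histogram does not record it)")
    if L <= K:
        raise ValueError(f"read length L={L} must exceed k={K}")
    if M <= x_err:
        raise ValueError(f"peak depth M={M} must exceed the error cutoff {x_err}")
    sel = hist.depths > x_err
    T = int((hist.depths[sel] * hist.counts[sel]).sum())
    N = M * L / (L - K + 1)
    G = T / M
    return GeneralFormulaResult(
        M=int(M), K=int(K), L=float(L), x_err=int(x_err),
        N=float(N), total_kmers=T, genome_size=float(G),
    )
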