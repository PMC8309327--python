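"""Ploidy inference from heterozygous k-mer pairs ("hetmers").

A heterozygous site in a genome with n haplotype copies, a of which carry the
minor allele, produces two k-mers one substitution apart with coverages
proportional to a and n - a. Plotting every such pair by
(minor coverage ratio = covB / (covA + covB), coverage sum) concentrates mass
in "smudges" at (a/n, n * lambda), where lambda is the per-copy k-mer depth:
a heterozygous diploid (AB) at (1/2, 2 lambda), a triploid (AAB) at
(1/3, 3 lambda), the hexaploid-heterozygous form (AAAAAB) at (1/6, 6 lambda).

Pairing is canonical-aware Hamming distance 1 at any position; a k-mer that
would participate in more than one pair is dropped entirely (ambiguity rule).
A totally homozygous genome yields no pairs — by design the analysis then
fails with a no-pairs error rather than fabricating a call.

Pair search enumerates the 3k substitution neighbours of every retained
k-mer against the retained-set hash (O(3k n)); the brute-force all-pairs
scan is reserved for test oracles. Requires single-limb codes, i.e. k <= 31.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _codec
from .errors import NoPairsError
from .kmercount import KmerCountTable

__all__ = [
    "HetmerPair",
    "HetmerGrid",
    "find_hetmer_pairs",
    "build_grid",
    "call_ploidy",
    "analyze",
    "structure_token",
]

RATIO_BIN_WIDTH = 0.02
MAX_PLOIDY = 8
MIN_PAIRS_FOR_CALL = 30


def structure_token(n: int, a: int) -> str:
    """Genotype token for n haplotype copies with a minor copies: AAB etc."""
    return "A" * (n - a) + "B" * a


@dataclass(frozen=True)
class HetmerPair:
    """Two canonical k-mers one substitution apart, coverage-ordered."""

    kmer_a: str
    kmer_b: str
    cov_a: int
    cov_b: int

    def __post_init__(self):
        if self.cov_b > self.cov_a:
            raise ValueError("pair must be ordered cov_a >= cov_b")

    @property
    def total(self) -> int:
        return self.cov_a + self.cov_b

    @property
    def minor_ratio(self) -> float:
        return self.cov_b / self.total


@dataclass
class HetmerGrid:
    """2-D mass distribution of hetmer pairs over (minor ratio, coverage sum).

    ``bins`` is the histogram over ratio bins (width 0.02 spanning (0, 0.5])
    x coverage-sum bins (width lambda/4); the raw per-pair coordinates are
    kept for the structure assignment.
    """

    lam: float
    ratios: np.ndarray
    totals: np.ndarray
    bins: np.ndarray
    ratio_edges: np.ndarray
    total_edges: np.ndarray
    ploidy_call: str | None = None
    structure_probs: dict[str, float] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return int(self.ratios.size)

    def write_tsv(self, path: str | Path) -> None:
        """Binned-grid dump: ratio_low, total_low, mass."""
        with open(path, "w") as fh:
            fh.write("minor_ratio_low\tcoverage_sum_low\tpairs\n")
            for i in range(self.bins.shape[0]):
                for j in range(self.bins.shape[1]):
                    if self.bins[i, j]:
                        fh.write(
                            f"{self.ratio_edges[i]:.2f}\t"
                            f"{self.total_edges[j]:.6g}\t{int(self.bins[i, j])}\n"
                        )

    def call_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "ploidy_call": self.ploidy_call,
                "ploidy": len(self.ploidy_call) if self.ploidy_call else None,
                "lambda": self.lam,
                "n_pairs": self.n_pairs,
                "structure_probs": self.structure_probs,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def find_hetmer_pairs(
    table: KmerCountTable, lower: int, upper: int
) -> list[HetmerPair]:
    """All unambiguous canonical k-mer pairs at Hamming distance 1 (in some
    orientation) with both coverages in [lower, upper].

    K-mers participating in more than one candidate pair are dropped
    entirely. Raises :class:`NoPairsError` when the retained set is empty.
    """
    k = table.k
    if k > 31:
        raise ValueError("hetmer pairing requires k <= 31")
    if lower < 1 or upper < lower:
        raise ValueError("need 1 <= lower <= upper")
    keep = (table.counts >= lower) & (table.counts <= upper)
    codes = table.codes[keep]
    counts = table.counts[keep]
    if codes.size == 0:
        raise NoPairsError(
            f"no k-mers retained in coverage window [{lower}, {upper}]"
        )
    # codes are already sorted (table invariant); enumerate 3k neighbours
    edges_i: list[np.ndarray] = []
    edges_j: list[np.ndarray] = []
    three = np.uint64(3)
    for pos in range(k):
        shift = np.uint64(2 * (k - 1 - pos))
        fld = (codes >> shift) & three
        cleared = codes & ~(three << shift)
        for delta in (1, 2, 3):
            newbase = (fld + np.uint64(delta)) & three
            nb = cleared | (newbase << shift)
            nb = _codec.canonicalize_codes(nb, k)
            idx = np.searchsorted(codes, nb)
            idx[idx >= codes.size] = codes.size - 1
            hit = codes[idx] == nb
            # orient each edge from the smaller code to avoid double entry
            i = np.flatnonzero(hit)
            j = idx[i]
            fwd = codes[i] < codes[j]
            edges_i.append(i[fwd])
            edges_j.append(j[fwd])
    if not edges_i:
        raise NoPairsError("no heterozygous k-mer pairs found")
    ei = np.concatenate(edges_i)
    ej = np.concatenate(edges_j)
    if ei.size == 0:
        raise NoPairsError("no heterozygous k-mer pairs found")
    edges = np.unique(np.stack([ei, ej], axis=1), axis=0)

    # ambiguity rule: drop any k-mer appearing in more than one pair
    degree = np.bincount(edges.ravel(), minlength=codes.size)
    ok = (degree[edges[:, 0]] == 1) & (degree[edges[:, 1]] == 1)
    edges = edges[ok]
    if edges.shape[0] == 0:
        raise NoPairsError("no unambiguous heterozygous k-mer pairs found")

    pairs: list[HetmerPair] = []
    km_i = _codec.codes_to_kmers(codes[edges[:, 0]], k)
    km_j = _codec.codes_to_kmers(codes[edges[:, 1]], k)
    for (i, j), ka, kb in zip(edges, km_i, km_j):
        ca, cb = int(counts[i]), int(counts[j])
        if ca >= cb:
            pairs.append(HetmerPair(kmer_a=ka, kmer_b=kb, cov_a=ca, cov_b=cb))
        else:
            pairs.append(HetmerPair(kmer_a=kb, kmer_b=ka, cov_a=cb, cov_b=ca))
    return pairs


def build_grid(pairs: list[HetmerPair], lam: float) -> HetmerGrid:
    """Bin pairs over (minor ratio, coverage sum).

    Ratio bins have width 0.02 over (0, 0.5]; coverage-sum bins have width
    lambda / 4. ``lam`` anchors the theoretical smudge centres (a/n, n*lam).
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    ratios = np.array([p.minor_ratio for p in pairs], dtype=float)
    totals = np.array([p.total for p in pairs], dtype=float)
    ratio_edges = np.arange(0.0, 0.5 + RATIO_BIN_WIDTH / 2, RATIO_BIN_WIDTH)
    t_width = lam / 4.0
    t_max = max(totals.max() if totals.size else lam, (MAX_PLOIDY + 1) * lam)
    total_edges = np.arange(0.0, t_max + t_width, t_width)
    bins, _, _ = np.histogram2d(ratios, totals, bins=[ratio_edges, total_edges])
    return HetmerGrid(
        lam=float(lam),
        ratios=ratios,
        totals=totals,
        bins=bins,
        ratio_edges=ratio_edges[:-1],
        total_edges=total_edges[:-1],
    )


def call_ploidy(
    grid: HetmerGrid, n_max: int = MAX_PLOIDY
) -> tuple[str, dict[str, float]]:
    """Assign each pair to the nearest theoretical smudge centre and call the
    structure with the largest mass share.

    Centres are (a/n, n * lambda) for n = 2..n_max, 1 <= a <= n/2; distance
    is Euclidean in the normalised space (ratio / 0.5, total / (n_max*lambda)).
    Ties break toward the simpler structure (smaller n, then larger a).
    """
    if grid.n_pairs == 0:
        raise NoPairsError("grid holds no pairs")
    centres = []
    for n in range(2, n_max + 1):
        for a in range(1, n // 2 + 1):
            centres.append((structure_token(n, a), a / n, n * grid.lam))
    cr = np.array([c[1] for c in centres])
    ct = np.array([c[2] for c in centres])
    dr = (grid.ratios[:, None] - cr[None, :]) / 0.5
    dt = (grid.totals[:, None] - ct[None, :]) / (n_max * grid.lam)
    nearest = np.argmin(dr**2 + dt**2, axis=1)
    mass = np.bincount(nearest, minlength=len(centres)).astype(float)
    shares = mass / mass.sum()
    order = sorted(
        range(len(centres)),
        key=lambda i: (-shares[i], len(centres[i][0]), centres[i][0]),
    )
    call = centres[order[0]][0]
    probs = {
        centres[i][0]: float(shares[i]) for i in range(len(centres)) if shares[i] > 0
    }
    grid.ploidy_call = call
    grid.structure_probs = probs
    return call, probs


def analyze(
    table: KmerCountTable,
    lam: float,
    lower: int | None = None,
    upper: int | None = None,
    x_err: int | None = None,
    min_pairs: int = MIN_PAIRS_FOR_CALL,
) -> HetmerGrid:
    """End-to-end hetmer analysis: pair search, grid, ploidy call.

    Default coverage window is (x_err + 1, 16 * lambda), excluding error
    k-mers below and deep repeats above. Fewer than ``min_pairs`` pairs is
    treated as no heterozygous signal (chance Hamming-1 collisions exist in
    any genome) and raises :class:`NoPairsError`, reproducing the known
    failure of hetmer ploidy inference on homozygous polyploids.
    """
    if lower is None:
        lower = (x_err if x_err is not None else 2) + 1
    if upper is None:
        upper = int(np.ceil(16 * lam))
    pairs = find_hetmer_pairs(table, lower, upper)
    if len(pairs) < min_pairs:
        raise NoPairsError(
            f"only {len(pairs)} heterozygous k-mer pair(s) found "
            f"(minimum {min_pairs}); genome appears homozygous — hetmer "
            "ploidy inference is uninformative"
        )
    grid = build_grid(pairs, lam)
    call_ploidy(grid)
    return grid
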