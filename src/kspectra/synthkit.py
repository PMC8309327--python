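"""Synthetic genomes, haplotypes and error-bearing short reads.

This module generates the ground-truth material every downstream estimator is
tested against: a haploid template sequence with a tunable fraction of exact
repeat copies, a set of haplotypes ("A" copies identical, "B" copies diverged
by i.i.d. substitutions at the target heterozygosity), and uniformly sampled
fixed-length reads with i.i.d. substitution errors.

The divergence model is substitution-only, so all haplotypes stay
length-matched and every heterozygous site yields a pair of k-mers exactly one
substitution apart — the signal the ploidy ("smudge") analysis relies on.

Coverage is defined over the pooled genome: a diploid simulated at coverage 80
has per-haplotype base depth 40. Total emitted bases = coverage x haploid
length, reads drawn uniformly over haplotypes and positions.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from . import _codec
from .errors import InvalidSpecError

__all__ = [
    "GenomeSpec",
    "HaplotypeSet",
    "ReadSimConfig",
    "ReadSet",
    "simulate_genome",
    "simulate_reads",
]

_FIXED_QUALITY_CHAR = "?"  # Phred 30, Phred+33 encoding; never used downstream


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a simulated genome.

    Parameters
    ----------
    haploid_length:
        Length of each haplotype in bases (>= 1000).
    ploidy_structure:
        Genotype token over {A, B}, all A's first: "AB" is a heterozygous
        diploid, "AAB" a triploid with one divergent copy, "AAAAAB" the
        hexaploid-heterozygous form. Length = ploidy.
    het_rate:
        Per-base substitution rate between A-type and B-type haplotypes
        (the ground-truth heterozygosity r), 0 <= r <= 0.1.
    repeat_fraction:
        Fraction of the haploid length occupied by repeat copies.
    repeat_unit_length:
        Length of each repeat unit in bases.
    repeat_copy_number:
        Copies per distinct repeat unit (default 2: a clean "duplicated"
        signature at twice the baseline k-mer depth).
    repeat_divergence:
        Per-base mutation rate applied independently to each repeat copy
        (default 0: exact copies).
    gc_content:
        Fraction of G+C in randomly generated sequence.
    seed:
        Seed for the genome RNG; identical spec+seed is byte-reproducible.
    """

    haploid_length: int
    ploidy_structure: str = "AB"
    het_rate: float = 0.0
    repeat_fraction: float = 0.0
    repeat_unit_length: int = 500
    repeat_copy_number: int = 2
    repeat_divergence: float = 0.0
    gc_content: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.haploid_length < 1000:
            raise InvalidSpecError("haploid_length must be >= 1000")
        if not (0.0 <= self.het_rate <= 0.1):
            raise InvalidSpecError("het_rate must be in [0, 0.1]")
        if not (0.0 <= self.repeat_fraction < 1.0):
            raise InvalidSpecError("repeat_fraction must be in [0, 1)")
        s = self.ploidy_structure
        if not s or set(s) - {"A", "B"}:
            raise InvalidSpecError("ploidy_structure must be a nonempty token over {A,B}")
        if "".join(sorted(s)) != s:
            raise InvalidSpecError("ploidy_structure must be sorted: all A's then B's")
        if not (0.0 < self.gc_content < 1.0):
            raise InvalidSpecError("gc_content must be in (0, 1)")
        if self.repeat_unit_length < 1 or self.repeat_copy_number < 1:
            raise InvalidSpecError("repeat unit length and copy number must be >= 1")
        if not (0.0 <= self.repeat_divergence <= 0.5):
            raise InvalidSpecError("repeat_divergence must be in [0, 0.5]")
        if self.repeat_fraction > 0 and (
            self.repeat_unit_length > self.haploid_length * self.repeat_fraction
        ):
            raise InvalidSpecError(
                "repeat_unit_length exceeds total repeat span "
                "(haploid_length * repeat_fraction)"
            )

    @property
    def ploidy(self) -> int:
        return len(self.ploidy_structure)

    @property
    def n_b_copies(self) -> int:
        return self.ploidy_structure.count("B")


@dataclass
class HaplotypeSet:
    """Haplotype sequences (2-bit encoded) plus the spec they came from."""

    arrays: list[np.ndarray]
    provenance: GenomeSpec
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def sequences(self) -> list[str]:
        return [_codec.decode(a) for a in self.arrays]

    @property
    def ploidy(self) -> int:
        return len(self.arrays)

    @property
    def haploid_length(self) -> int:
        return int(self.arrays[0].size)

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        """Write haplotypes as FASTA (60-column wrapped; .gz honoured)."""
        with _open_text(path, "wt") as fh:
            for name, seq in zip(self.names(), self.sequences):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def names(self) -> list[str]:
        return [
            f"hap{i}_{c}" for i, c in enumerate(self.provenance.ploidy_structure)
        ]


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-sampling parameters.

    ``coverage`` is mean depth over the pooled genome (all haplotypes sampled
    evenly), so per-haplotype depth is coverage / ploidy. Spectrum-based
    estimators need pooled coverage above ~10x to separate the genomic peak
    from the error peak, so lower values are rejected.

    ``long_repeat_recovery`` < 1 downsamples reads that start inside annotated
    repeat intervals, emulating the under-recovery of long repetitive regions
    in real libraries (default 1.0 = perfectly uniform sampling).
    """

    read_length: int = 151
    coverage: float = 40.0
    error_rate: float = 0.001
    paired: bool = False
    seed: int = 0
    long_repeat_recovery: float = 1.0

    def __post_init__(self):
        if self.read_length < 20:
            raise InvalidSpecError("read_length must be >= 20")
        if self.coverage <= 10:
            raise InvalidSpecError("coverage must exceed 10x for spectrum analysis")
        if not (0.0 <= self.error_rate <= 0.2):
            raise InvalidSpecError("error_rate must be in [0, 0.2]")
        if not (0.0 < self.long_repeat_recovery <= 1.0):
            raise InvalidSpecError("long_repeat_recovery must be in (0, 1]")


@dataclass
class ReadSet:
    """Simulated reads as an (n_reads, read_length) 2-bit matrix."""

    matrix: np.ndarray
    config: ReadSimConfig
    source: GenomeSpec | None = None

    @property
    def n_reads(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def total_bases(self) -> int:
        return int(self.matrix.size)

    def sequences(self) -> Iterator[str]:
        for row in self.matrix:
            yield _codec.decode(row)

    def write_fastq(self, path: str | Path) -> list[Path]:
        """Write reads as 4-line FASTQ with fixed Phred-30 qualities.

        With ``paired=True`` in the config, alternate reads go to synchronised
        ``<stem>_1.fastq`` / ``<stem>_2.fastq`` files (pairing affects file
        layout only; every read is an independent single-end draw). Returns
        the list of paths written. ``.gz`` suffixes are honoured.
        """
        path = Path(path)
        qual = _FIXED_QUALITY_CHAR * self.read_length
        if not self.config.paired:
            with _open_text(path, "wt") as fh:
                for i, seq in enumerate(self.sequences()):
                    fh.write(f"@read{i}\n{seq}\n+\n{qual}\n")
            return [path]
        gz = path.suffix == ".gz"
        base = path.with_suffix("") if gz else path
        stem, ext = base.with_suffix(""), base.suffix or ".fastq"
        suffix = ext + (".gz" if gz else "")
        paths = [Path(f"{stem}_1{suffix}"), Path(f"{stem}_2{suffix}")]
        with _open_text(paths[0], "wt") as f1, _open_text(paths[1], "wt") as f2:
            for i, seq in enumerate(self.sequences()):
                pair, mate = divmod(i, 2)
                fh = f1 if mate == 0 else f2
                fh.write(f"@pair{pair}/{mate + 1}\n{seq}\n+\n{qual}\n")
        return paths


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _substitute(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Return a copy of ``arr`` with i.i.d. substitutions at ``rate``."""
    out = arr.copy()
    if rate <= 0:
        return out
    mask = rng.random(out.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return out


def simulate_genome(spec: GenomeSpec) -> HaplotypeSet:
    """Generate haplotypes per the spec's ploidy structure.

    All A haplotypes are identical; the B haplotype is derived from A by
    i.i.d. substitutions at ``het_rate`` (all B copies identical to each
    other). A contiguous central block covering ``repeat_fraction`` of the
    haploid length is tiled with repeat units, each unit copied
    ``repeat_copy_number`` times (exact copies unless ``repeat_divergence``
    is set). Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.haploid_length
    base = _random_bases(rng, L, spec.gc_content)

    repeat_intervals: list[tuple[int, int]] = []
    if spec.repeat_fraction > 0:
        total = int(round(L * spec.repeat_fraction))
        n_copies = total // spec.repeat_unit_length
        if n_copies < 1:
            raise InvalidSpecError(
                "repeat_unit_length exceeds total repeat span "
                "(haploid_length * repeat_fraction)"
            )
        copies: list[np.ndarray] = []
        remaining = n_copies
        while remaining > 0:
            unit = _random_bases(rng, spec.repeat_unit_length, spec.gc_content)
            for _ in range(min(spec.repeat_copy_number, remaining)):
                copies.append(_substitute(rng, unit, spec.repeat_divergence))
            remaining -= min(spec.repeat_copy_number, remaining)
        block = np.concatenate(copies)
        offset = (L - block.size) // 2
        base[offset : offset + block.size] = block
        repeat_intervals.append((offset, offset + int(block.size)))

    b_hap = _substitute(rng, base, spec.het_rate)
    arrays = [
        base if c == "A" else b_hap for c in spec.ploidy_structure
    ]
    return HaplotypeSet(arrays=arrays, provenance=spec, repeat_intervals=repeat_intervals)


def simulate_reads(haps: HaplotypeSet, cfg: ReadSimConfig) -> ReadSet:
    """Sample substitution-error reads uniformly over haplotypes and positions.

    Total emitted bases ~= coverage x haploid_length (within one read).
    """
    if not haps.arrays:
        raise InvalidSpecError("haplotype set is empty")
    L = cfg.read_length
    hap_len = haps.haploid_length
    if L > hap_len:
        raise InvalidSpecError(
            f"read_length {L} exceeds haplotype length {hap_len}"
        )
    rng = np.random.default_rng(cfg.seed)
    ploidy = haps.ploidy
    n_reads = max(1, int(round(cfg.coverage * hap_len / L)))
    hap_idx = rng.integers(0, ploidy, n_reads)
    starts = rng.integers(0, hap_len - L + 1, n_reads)

    if cfg.long_repeat_recovery < 1.0 and haps.repeat_intervals:
        in_repeat = np.zeros(n_reads, dtype=bool)
        for lo, hi in haps.repeat_intervals:
            in_repeat |= (starts >= lo) & (starts < hi)
        keep = ~in_repeat | (rng.random(n_reads) < cfg.long_repeat_recovery)
        hap_idx, starts = hap_idx[keep], starts[keep]
        n_reads = int(hap_idx.size)

    matrix = np.empty((n_reads, L), dtype=np.uint8)
    window = np.arange(L)
    chunk = 100_000  # caps the gather-index scratch memory
    for h in range(ploidy):
        rows = np.flatnonzero(hap_idx == h)
        hap = haps.arrays[h]
        for i in range(0, rows.size, chunk):
            r = rows[i : i + chunk]
            matrix[r] = hap[starts[r, None] + window]

    if cfg.error_rate > 0:
        total = matrix.size
        n_err = rng.binomial(total, cfg.error_rate)
        if n_err:
            pos = rng.integers(0, total, n_err)
            flat = matrix.reshape(-1)
            flat[pos] = (flat[pos] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4

    return ReadSet(matrix=matrix, config=cfg, source=haps.provenance)
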