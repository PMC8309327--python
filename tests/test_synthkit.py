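"""Simulator ground-truth checks: divergence, coverage, errors, determinism,
file layout."""

import gzip
import math

import numpy as np
import pytest

import kspectra as ks
from kspectra.errors import InvalidSpecError


def _mismatch_fraction(a: str, b: str) -> float:
    arr_a = np.frombuffer(a.encode(), np.uint8)
    arr_b = np.frombuffer(b.encode(), np.uint8)
    return float((arr_a != arr_b).mean())


class TestGenomeSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"haploid_length": 500},
            {"haploid_length": 10_000, "het_rate": 0.2},
            {"haploid_length": 10_000, "repeat_fraction": 1.0},
            {"haploid_length": 10_000, "ploidy_structure": ""},
            {"haploid_length": 10_000, "ploidy_structure": "BA"},
            {"haploid_length": 10_000, "ploidy_structure": "AXB"},
            # repeat unit longer than the whole repeat span
            {"haploid_length": 10_000, "repeat_fraction": 0.01,
             "repeat_unit_length": 500},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            ks.GenomeSpec(**kwargs)

    def test_ploidy_properties(self):
        spec = ks.GenomeSpec(haploid_length=1000, ploidy_structure="AAAAAB")
        assert spec.ploidy == 6
        assert spec.n_b_copies == 1


class TestSimulateGenome:
    def test_zero_divergence_gives_identical_haplotypes(self):
        spec = ks.GenomeSpec(haploid_length=5000, ploidy_structure="AB",
                             het_rate=0.0, seed=1)
        haps = ks.simulate_genome(spec)
        assert haps.sequences[0] == haps.sequences[1]

    def test_hexaploid_structure_copies(self):
        spec = ks.GenomeSpec(haploid_length=2000, ploidy_structure="AAAAAB",
                             het_rate=0.01, seed=2)
        haps = ks.simulate_genome(spec)
        assert len(haps.arrays) == 6
        first_five = haps.sequences[:5]
        assert all(s == first_five[0] for s in first_five)
        assert haps.sequences[5] != first_five[0]

    def test_divergence_matches_binomial_oracle(self):
        # observed mismatch fraction ~ Binomial(L, r)/L within 3 sigma
        L, r = 1_000_000, 0.01
        spec = ks.GenomeSpec(haploid_length=L, ploidy_structure="AB",
                             het_rate=r, seed=3)
        haps = ks.simulate_genome(spec)
        obs = _mismatch_fraction(*haps.sequences)
        sigma = math.sqrt(r * (1 - r) / L)
        assert abs(obs - r) <= 3 * sigma

    def test_determinism_byte_identical(self, tmp_path):
        spec = ks.GenomeSpec(haploid_length=20_000, ploidy_structure="AB",
                             het_rate=0.01, repeat_fraction=0.1, seed=4)
        paths = []
        for tag in ("a", "b"):
            haps = ks.simulate_genome(spec)
            reads = ks.simulate_reads(haps, ks.ReadSimConfig(coverage=20, seed=9))
            fa = tmp_path / f"{tag}.fasta"
            fq = tmp_path / f"{tag}.fastq"
            haps.write_fasta(fa)
            reads.write_fastq(fq)
            paths.append((fa.read_bytes(), fq.read_bytes()))
        assert paths[0] == paths[1]

    def test_gc_content_respected(self):
        spec = ks.GenomeSpec(haploid_length=200_000, ploidy_structure="A",
                             gc_content=0.6, seed=5)
        haps = ks.simulate_genome(spec)
        seq = haps.sequences[0]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.6) < 0.01


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        spec = ks.GenomeSpec(haploid_length=5000, ploidy_structure="AB",
                             het_rate=0.01, seed=6)
        haps = ks.simulate_genome(spec)
        reads = ks.simulate_reads(
            haps, ks.ReadSimConfig(read_length=100, coverage=12,
                                   error_rate=0.0, seed=7))
        seqs = haps.sequences
        for read in reads.sequences():
            assert any(read in s for s in seqs)

    def test_error_count_matches_binomial_oracle(self):
        # mismatches vs the source positions ~ Binomial(total_bases, e)
        spec = ks.GenomeSpec(haploid_length=5000, ploidy_structure="A", seed=8)
        haps = ks.simulate_genome(spec)
        e = 0.01
        cfg = ks.ReadSimConfig(read_length=100, coverage=20, error_rate=e, seed=9)
        clean = ks.simulate_reads(haps, ks.ReadSimConfig(
            read_length=100, coverage=20, error_rate=0.0, seed=9))
        noisy = ks.simulate_reads(haps, cfg)
        assert clean.matrix.shape == noisy.matrix.shape
        mismatches = int((clean.matrix != noisy.matrix).sum())
        total = noisy.total_bases
        mean = total * e
        # a double-hit can revert a base, so allow a slightly widened band
        assert abs(mismatches - mean) <= 3.5 * math.sqrt(mean * (1 - e))

    def test_total_bases_tracks_pooled_coverage(self):
        spec = ks.GenomeSpec(haploid_length=100_000, ploidy_structure="AB",
                             het_rate=0.01, seed=10)
        haps = ks.simulate_genome(spec)
        reads = ks.simulate_reads(haps, ks.ReadSimConfig(coverage=40, seed=11))
        assert abs(reads.total_bases - 4_000_000) <= 0.01 * 4_000_000

    def test_read_longer_than_haplotype_rejected(self):
        spec = ks.GenomeSpec(haploid_length=1000, ploidy_structure="A", seed=12)
        haps = ks.simulate_genome(spec)
        with pytest.raises(InvalidSpecError):
            ks.simulate_reads(haps, ks.ReadSimConfig(read_length=2000, coverage=20))

    def test_low_coverage_rejected(self):
        with pytest.raises(InvalidSpecError):
            ks.ReadSimConfig(coverage=5)

    def test_paired_layout_two_synchronized_files(self, tmp_path):
        spec = ks.GenomeSpec(haploid_length=2000, ploidy_structure="A", seed=13)
        haps = ks.simulate_genome(spec)
        reads = ks.simulate_reads(haps, ks.ReadSimConfig(
            read_length=50, coverage=12, paired=True, seed=14))
        paths = reads.write_fastq(tmp_path / "reads.fastq")
        assert [p.name for p in paths] == ["reads_1.fastq", "reads_2.fastq"]
        n1 = sum(1 for line in open(paths[0]) if line.startswith("@pair"))
        n2 = sum(1 for line in open(paths[1]) if line.startswith("@pair"))
        assert n1 + n2 == reads.n_reads
        assert abs(n1 - n2) <= 1

    def test_gzip_fastq_round_trip(self, tmp_path):
        spec = ks.GenomeSpec(haploid_length=2000, ploidy_structure="A", seed=15)
        haps = ks.simulate_genome(spec)
        reads = ks.simulate_reads(haps, ks.ReadSimConfig(
            read_length=50, coverage=12, seed=16))
        gz = tmp_path / "reads.fastq.gz"
        reads.write_fastq(gz)
        with gzip.open(gz, "rt") as fh:
            lines = fh.read().splitlines()
        assert len(lines) == 4 * reads.n_reads
        # counting straight from the gzip file matches in-memory counting
        t_file = ks.count_canonical_kmers(gz, 21)
        t_mem = ks.count_canonical_kmers(reads, 21)
        assert t_file.to_dict() == t_mem.to_dict()


def test_diploid_spectrum_is_bimodal(diploid_1mb_80x):
    """A ~1%-het diploid shows peaks near lambda and 2*lambda."""
    hist = diploid_1mb_80x["hist"]
    x_err = ks.find_error_cutoff(hist)
    peaks = ks.find_peaks(hist, x_err)
    lam = 80 / 2 * (151 - 21 + 1) / 151  # per-haplotype k-mer depth ~34.7
    found = {peaks.peak_depth, *peaks.secondary_peaks}
    assert any(abs(p - lam) <= 0.15 * lam for p in found)
    assert any(abs(p - 2 * lam) <= 0.15 * (2 * lam) for p in found)
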