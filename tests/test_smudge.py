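"""Hetmer pairing against a brute-force oracle, grid arithmetic and ploidy
calls on simulated genomes."""

import itertools

import numpy as np
import pytest

import kspectra as ks
from kspectra import smudge as sm
from kspectra._codec import revcomp_str
from kspectra.errors import NoPairsError
from kspectra.kmercount import KmerCountTable


def brute_force_pairs(counts: dict[str, int], lower: int, upper: int):
    """All-pairs Hamming-1 (canonical-aware) oracle on a {kmer: count} dict,
    including the ambiguity rule."""
    def hamming1(a, b):
        return sum(x != y for x, y in zip(a, b)) == 1

    retained = {k: c for k, c in counts.items() if lower <= c <= upper}
    keys = sorted(retained)
    edges = []
    for a, b in itertools.combinations(keys, 2):
        if hamming1(a, b) or hamming1(a, revcomp_str(b)):
            edges.append((a, b))
    degree = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    pairs = set()
    for a, b in edges:
        if degree[a] == 1 and degree[b] == 1:
            ca, cb = retained[a], retained[b]
            if (cb, b) > (ca, a):
                a, b, ca, cb = b, a, cb, ca
            pairs.add(frozenset([a, b]))
    return pairs


class TestFindPairs:
    def test_hand_built_single_pair(self):
        # one valid pair (differ at position 2), one far-away k-mer
        counts = {"AACGT": 30, "AATGT": 18, "CCCCC": 25}
        table = KmerCountTable.from_dict(counts, 5)
        pairs = sm.find_hetmer_pairs(table, lower=5, upper=100)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.cov_a >= p.cov_b
        assert {p.kmer_a, p.kmer_b} == {
            min("AACGT", revcomp_str("AACGT")),
            min("AATGT", revcomp_str("AATGT")),
        }
        assert (p.cov_a, p.cov_b) == (30, 18)

    def test_orientation_aware_pairing(self):
        # ACGGA pairs with TCCGA = revcomp(TCGGA), Hamming-1 from ACGGA
        counts = {"ACGGA": 12, "TCCGA": 20}
        table = KmerCountTable.from_dict(counts, 5)
        pairs = sm.find_hetmer_pairs(table, lower=5, upper=50)
        assert len(pairs) == 1

    def test_ambiguous_kmers_dropped(self):
        # AAAAA pairs with both AAATA and AATAA -> all three discarded
        counts = {"AAAAA": 30, "AAATA": 20, "AATAA": 22}
        table = KmerCountTable.from_dict(counts, 5)
        with pytest.raises(NoPairsError):
            sm.find_hetmer_pairs(table, lower=5, upper=50)

    def test_empty_retained_set_raises(self):
        table = KmerCountTable.from_dict({"AACGT": 2}, 5)
        with pytest.raises(NoPairsError):
            sm.find_hetmer_pairs(table, lower=10, upper=100)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kmers = set()
        while len(kmers) < 80:
            km = "".join("ACGT"[i] for i in rng.integers(0, 4, 7))
            kmers.add(min(km, revcomp_str(km)))
        counts = {km: int(rng.integers(1, 60)) for km in sorted(kmers)}
        # seed some guaranteed Hamming-1 partners
        for km in list(counts)[:10]:
            mutant = "A" + km[1:] if km[0] != "A" else "C" + km[1:]
            counts.setdefault(min(mutant, revcomp_str(mutant)),
                              int(rng.integers(1, 60)))
        table = KmerCountTable.from_dict(counts, 7)
        expected = brute_force_pairs(counts, 10, 50)
        try:
            got = {frozenset([p.kmer_a, p.kmer_b])
                   for p in sm.find_hetmer_pairs(table, 10, 50)}
        except NoPairsError:
            got = set()
        assert got == expected

    def test_diploid_pair_count_matches_expectation(self, smudge_diploid):
        """Pair count >= half the expected het-kmer count for r = 1%."""
        hist = smudge_diploid["hist"]
        x_err = ks.find_error_cutoff(hist)
        pairs = sm.find_hetmer_pairs(smudge_diploid["table"], x_err + 1,
                                     16 * 30)
        r, k, L = 0.01, 21, 200_000
        expected = L * (1 - (1 - r) ** k) * (1 - r) ** (k - 1)
        assert len(pairs) >= 0.5 * expected

    def test_homozygous_genome_yields_no_signal(self, smudge_homozygous_tetraploid):
        hist = smudge_homozygous_tetraploid["hist"]
        x_err = ks.find_error_cutoff(hist)
        with pytest.raises(NoPairsError):
            sm.analyze(smudge_homozygous_tetraploid["table"], lam=20.0,
                       x_err=x_err)


class TestGrid:
    def test_balanced_pair_maps_to_diploid_center(self):
        pair = sm.HetmerPair("AACGT", "AATGT", 40, 40)
        assert pair.minor_ratio == 0.5
        assert pair.total == 80
        grid = sm.build_grid([pair], lam=40)
        call, probs = sm.call_ploidy(grid)
        assert call == "AB"
        assert probs["AB"] == 1.0

    def test_two_to_one_pair_maps_to_triploid_center(self):
        pair = sm.HetmerPair("AACGT", "AATGT", 80, 40)
        assert pair.minor_ratio == pytest.approx(1 / 3)
        grid = sm.build_grid([pair], lam=40)
        call, _ = sm.call_ploidy(grid)
        assert call == "AAB"

    def test_pair_exactly_at_tetraploid_center(self):
        # (1/4, 4*lam) is the AAAB center
        pair = sm.HetmerPair("AACGT", "AATGT", 90, 30)
        grid = sm.build_grid([pair], lam=30)
        call, probs = sm.call_ploidy(grid)
        assert call == "AAAB"
        assert probs == {"AAAB": 1.0}

    def test_grid_mass_conserved(self, smudge_diploid):
        hist = smudge_diploid["hist"]
        x_err = ks.find_error_cutoff(hist)
        fit = ks.fit_spectrum(hist, k=21, ploidy=2)
        grid = sm.analyze(smudge_diploid["table"], lam=fit.params.lam,
                          x_err=x_err)
        assert grid.bins.sum() == grid.n_pairs
        assert sum(grid.structure_probs.values()) == pytest.approx(1.0)


class TestCalls:
    def test_diploid_called_ab(self, smudge_diploid):
        hist = smudge_diploid["hist"]
        fit = ks.fit_spectrum(hist, k=21, ploidy=2)
        grid = sm.analyze(smudge_diploid["table"], lam=fit.params.lam,
                          x_err=ks.find_error_cutoff(hist))
        assert grid.ploidy_call == "AB"
        assert grid.structure_probs["AB"] >= 0.6

    def test_triploid_called_aab(self, smudge_triploid):
        hist = smudge_triploid["hist"]
        fit = ks.fit_spectrum(hist, k=21, ploidy=3)
        lam = 2 * fit.params.lam / 3  # per-copy depth for a triploid
        grid = sm.analyze(smudge_triploid["table"], lam=lam,
                          x_err=ks.find_error_cutoff(hist))
        assert grid.ploidy_call == "AAB"

    def test_hexaploid_mass_near_one_sixth(self):
        """AAAAAB at per-copy depth 20: dominant mass near (1/6, 120)."""
        from conftest import simulate_and_count

        cov = 6 * 20 * 151 / 131
        data = simulate_and_count(haploid_length=150_000, structure="AAAAAB",
                                  het=0.01, coverage=cov, seed=41)
        x_err = ks.find_error_cutoff(data["hist"])
        pairs = sm.find_hetmer_pairs(data["table"], x_err + 1, 16 * 20)
        grid = sm.build_grid(pairs, lam=20.0)
        i, j = np.unravel_index(np.argmax(grid.bins), grid.bins.shape)
        assert abs(grid.ratio_edges[i] + 0.01 - 1 / 6) < 0.03
        assert abs(grid.total_edges[j] + 2.5 - 120) < 12
        call, _ = sm.call_ploidy(grid)
        assert call == "AAAAAB"

    def test_orientation_invariance(self, smudge_diploid):
        """Reverse-complementing every read leaves pairs and call unchanged."""
        reads = smudge_diploid["reads"]
        rc_reads = [revcomp_str(s) for s in
                    itertools.islice(reads.sequences(), 20_000)]
        fwd_reads = list(itertools.islice(reads.sequences(), 20_000))
        t_fwd = ks.count_canonical_kmers(fwd_reads, 21)
        t_rc = ks.count_canonical_kmers(rc_reads, 21)
        p_fwd = sm.find_hetmer_pairs(t_fwd, 3, 200)
        p_rc = sm.find_hetmer_pairs(t_rc, 3, 200)
        assert {(p.kmer_a, p.kmer_b, p.cov_a, p.cov_b) for p in p_fwd} == \
               {(p.kmer_a, p.kmer_b, p.cov_a, p.cov_b) for p in p_rc}

    def test_coverage_scaling(self):
        """Doubling coverage doubles pair totals, keeps ratios and call."""
        from conftest import simulate_and_count

        grids = {}
        for cov in (50, 100):
            data = simulate_and_count(haploid_length=150_000, structure="AB",
                                      het=0.01, coverage=cov, seed=51)
            hist = data["hist"]
            fit = ks.fit_spectrum(hist, k=21, ploidy=2)
            grids[cov] = sm.analyze(data["table"], lam=fit.params.lam,
                                    x_err=ks.find_error_cutoff(hist))
        ratio = np.median(grids[100].totals) / np.median(grids[50].totals)
        assert ratio == pytest.approx(2.0, rel=0.1)
        assert grids[50].ploidy_call == grids[100].ploidy_call == "AB"
        assert abs(np.median(grids[100].ratios) - np.median(grids[50].ratios)) < 0.05
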