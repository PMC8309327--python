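"""Shared fixtures: session-scoped simulations reused across module and
acceptance tests (the expensive genomes are built once)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kspectra as ks

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def simulate_and_count(
    *,
    haploid_length: int,
    structure: str = "AB",
    het: float = 0.0,
    coverage: float = 60.0,
    error_rate: float = 0.001,
    repeat_fraction: float = 0.0,
    repeat_unit_length: int = 500,
    seed: int = 0,
    k: int = 21,
    long_repeat_recovery: float = 1.0,
    repeat_copy_number: int = 2,
):
    spec = ks.GenomeSpec(
        haploid_length=haploid_length,
        ploidy_structure=structure,
        het_rate=het,
        repeat_fraction=repeat_fraction,
        repeat_unit_length=repeat_unit_length,
        repeat_copy_number=repeat_copy_number,
        seed=seed,
    )
    haps = ks.simulate_genome(spec)
    reads = ks.simulate_reads(
        haps,
        ks.ReadSimConfig(
            coverage=coverage,
            error_rate=error_rate,
            seed=seed + 1,
            long_repeat_recovery=long_repeat_recovery,
        ),
    )
    table = ks.count_canonical_kmers(reads, k)
    hist = ks.histogram_from_counts(table)
    return {"spec": spec, "haps": haps, "reads": reads, "table": table, "hist": hist}


@pytest.fixture(scope="session")
def haploid_1mb_40x():
    """1-Mb haploid at 40x, 0.1% error, k = 21."""
    return simulate_and_count(haploid_length=1_000_000, structure="A",
                              coverage=40, seed=101)


@pytest.fixture(scope="session")
def diploid_1mb_80x():
    """1-Mb heterozygous diploid (r = 1%) at 80x pooled, k = 21."""
    return simulate_and_count(haploid_length=1_000_000, structure="AB",
                              het=0.01, coverage=80, seed=103)


@pytest.fixture(scope="session")
def smudge_diploid():
    """200-kb heterozygous diploid for hetmer-pair analysis."""
    return simulate_and_count(haploid_length=200_000, structure="AB",
                              het=0.01, coverage=60, seed=105)


@pytest.fixture(scope="session")
def smudge_triploid():
    """200-kb AAB triploid for hetmer-pair analysis."""
    return simulate_and_count(haploid_length=200_000, structure="AAB",
                              het=0.01, coverage=66, seed=107)


@pytest.fixture(scope="session")
def smudge_homozygous_tetraploid():
    """200-kb fully homozygous AAAA tetraploid (the no-pairs failure mode)."""
    return simulate_and_count(haploid_length=200_000, structure="AAAA",
                              het=0.0, coverage=80, seed=109)


@pytest.fixture(scope="session")
def repeat_sweep():
    """300-kb diploids with repeat_fraction 0, 0.15, 0.3 (2-copy units)."""
    out = {}
    for rf in (0.0, 0.15, 0.3):
        out[rf] = simulate_and_count(
            haploid_length=300_000, structure="AB", het=0.01,
            repeat_fraction=rf, coverage=80, seed=111,
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
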