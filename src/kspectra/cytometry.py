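"""Flow-cytometry C-value arithmetic and replicate aggregation.

The 2C DNA content of a sample follows from the ratio of mean fluorescence
intensities of sample and co-processed external standard nuclei:

    2C_sample [pg] = (F_sample / F_standard) * 2C_standard

with tomato (Solanum lycopersicum, 2C = 1.96 pg) as the default standard.
Picograms convert to megabases via 1 pg = 978 Mbp, so 1C [Mbp] = 489 * 2C [pg]
exactly. Report rounding follows the common table convention: pg to 2
decimals, Mbp to 1 decimal; raw precision is kept internally.

The k-mer-derived 2C column of a C-value comparison table is produced by the
visible rounding chain Mbp -> 1C pg (rounded to 2 decimals) -> doubled, the
only chain consistent with published 1C/2C pairings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidSpecError

__all__ = [
    "PG_PER_MBP",
    "MBP_PER_PG",
    "TOMATO_2C_PG",
    "CytometryRun",
    "CValueRecord",
    "two_c_from_fluorescence",
    "pg_to_mbp",
    "mbp_to_pg",
    "aggregate_replicates",
    "kmer_two_c_pg",
    "cvalue_table",
]

MBP_PER_PG = 978.0
PG_PER_MBP = 1.0 / MBP_PER_PG
TOMATO_2C_PG = 1.96


@dataclass(frozen=True)
class CytometryRun:
    """One flow-cytometry measurement.

    F_sample / F_standard are mean fluorescence intensities (arbitrary
    units); standard_2c is the external standard's 2C DNA content in pg;
    g0g1_pct the percentage of events in the G0/G1 compartment.
    """

    f_sample: float
    f_standard: float
    standard_2c: float = TOMATO_2C_PG
    g0g1_pct: float = 100.0

    def __post_init__(self):
        if self.f_sample <= 0 or self.f_standard <= 0:
            raise InvalidSpecError("fluorescence intensities must be > 0")
        if self.standard_2c <= 0:
            raise InvalidSpecError("standard 2C content must be > 0")
        if not (0.0 <= self.g0g1_pct <= 100.0):
            raise InvalidSpecError("g0g1_pct must be in [0, 100]")


@dataclass(frozen=True)
class CValueRecord:
    """Aggregated C-value for one species: 2C mean +- sd over replicates."""

    label: str
    n_replicates: int
    two_c_pg: float
    two_c_sd: float

    @property
    def one_c_pg(self) -> float:
        return self.two_c_pg / 2.0

    @property
    def one_c_mbp(self) -> float:
        return pg_to_mbp(self.one_c_pg)


def two_c_from_fluorescence(run: CytometryRun) -> float:
    """Sample 2C DNA content in pg from a fluorescence-ratio run."""
    return (run.f_sample / run.f_standard) * run.standard_2c


def pg_to_mbp(pg: float) -> float:
    """Picograms of DNA to megabase pairs (1 pg = 978 Mbp)."""
    if pg < 0:
        raise InvalidSpecError("DNA amount must be >= 0")
    return pg * MBP_PER_PG


def mbp_to_pg(mbp: float) -> float:
    """Megabase pairs to picograms (inverse of :func:`pg_to_mbp`)."""
    if mbp < 0:
        raise InvalidSpecError("DNA amount must be >= 0")
    return mbp / MBP_PER_PG


def aggregate_replicates(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of replicates."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise InvalidSpecError(
            "at least 2 replicates are required for a standard deviation"
        )
    return float(values.mean()), float(values.std(ddof=1))


def kmer_two_c_pg(one_c_mbp: float) -> float:
    """K-mer-derived 2C in pg via the visible rounding chain:
    1C Mbp -> 1C pg rounded to 2 decimals -> doubled."""
    one_c_pg = round(mbp_to_pg(one_c_mbp), 2)
    return round(2.0 * one_c_pg, 2)


def cvalue_table(
    records: list[CValueRecord],
    kmer_one_c_mbp: dict[str, float] | None = None,
) -> pd.DataFrame:
    """C-value comparison table (one row per species).

    Columns mirror the standard comparison layout: replicate count, 2C pg
    (mean +- sd), 1C pg, 1C Mbp, and — when per-species k-mer 1C sizes are
    supplied — the 2C/1C k-mer columns via the rounding chain, plus the
    FCM - k-mer 2C difference.
    """
    rows = []
    for rec in records:
        row = {
            "label": rec.label,
            "n": rec.n_replicates,
            "2C DNA Content (pg)": round(rec.two_c_pg, 2),
            "2C sd (pg)": round(rec.two_c_sd, 2),
            "1C DNA Content (pg)": round(rec.one_c_pg, 3),
            "1C DNA Content (Mbp)": round(rec.one_c_mbp, 1),
        }
        if kmer_one_c_mbp and rec.label in kmer_one_c_mbp:
            mbp = kmer_one_c_mbp[rec.label]
            two_c_k = kmer_two_c_pg(mbp)
            row["2C K-Mer (pg)"] = two_c_k
            row["1C K-Mer (pg)"] = round(mbp_to_pg(mbp), 2)
            row["1C K-Mer (Mbp)"] = round(mbp, 1)
            row["FCM - K-Mer 2C diff (pg)"] = round(rec.two_c_pg - two_c_k, 2)
        rows.append(row)
    return pd.DataFrame(rows)
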