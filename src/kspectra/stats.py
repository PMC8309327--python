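"""Cross-estimator aggregation and the two significance tests used in
genome-size comparisons.

``summarize_estimates`` reduces a long-form table of genome-size estimates
(one row per estimator x k x dataset) to per-estimator mean +- sample SD over
the processed-data k-sweep. The one-sample t-test compares replicate C-values
against a fixed reference (e.g. the k-mer-derived value), and one-way ANOVA
tests whether k-mer length affects the size estimates.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import InvalidSpecError

__all__ = [
    "make_estimate_table",
    "summarize_estimates",
    "one_sample_t",
    "one_way_anova",
]

_COLUMNS = ["estimator", "k", "dataset", "size_mbp"]


def make_estimate_table(rows) -> pd.DataFrame:
    """Long-form estimate table from (estimator, k, dataset, size_mbp) rows.

    ``dataset`` labels distinguish e.g. raw vs processed inputs; only labels
    are carried (read QC itself is outside this package's scope).
    """
    df = pd.DataFrame(list(rows), columns=_COLUMNS)
    df["k"] = df["k"].astype(int)
    df["size_mbp"] = df["size_mbp"].astype(float)
    return df


def summarize_estimates(
    table: pd.DataFrame, dataset: str = "processed"
) -> pd.DataFrame:
    """Per-estimator mean and sample SD over one dataset's k-sweep.

    Estimators with fewer than 2 entries are listed in a completeness
    warning and excluded (an SD needs n >= 2).
    """
    sub = table[table["dataset"] == dataset]
    if sub.empty:
        raise InvalidSpecError(f"no rows with dataset label {dataset!r}")
    incomplete = [
        est for est, grp in sub.groupby("estimator") if len(grp) < 2
    ]
    if incomplete:
        warnings.warn(
            f"estimators with <2 {dataset!r} entries excluded: {incomplete}"
        )
    grp = sub[~sub["estimator"].isin(incomplete)].groupby("estimator")["size_mbp"]
    out = grp.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
    return out.reset_index()


def one_sample_t(values, mu: float) -> tuple[float, float]:
    """Two-sided one-sample t-test: t = (mean - mu) / (sd / sqrt(n)).

    Degenerate spread (sd = 0) maps to (0, 1) when the mean equals mu and to
    (+-inf, 0) otherwise, with a warning.
    """
    values = np.asarray(list(values), dtype=float)
    n = values.size
    if n < 2:
        raise InvalidSpecError("one-sample t-test needs n >= 2")
    sd = values.std(ddof=1)
    mean = values.mean()
    if sd == 0.0:
        if mean == mu:
            return 0.0, 1.0
        warnings.warn("zero spread with mean != mu: t is infinite")
        return math.copysign(math.inf, mean - mu), 0.0
    res = _sps.ttest_1samp(values, popmean=mu)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, float]:
    """One-way ANOVA across >= 2 groups (each n >= 2): between/within
    mean-square ratio, p from the F distribution.

    If every group has zero within-variance and all means coincide the data
    carry no signal and (0, 1) is returned.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidSpecError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise InvalidSpecError("every ANOVA group needs n >= 2")
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = [g.mean() for g in groups]
    if within == 0.0 and np.allclose(means, means[0]):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = _sps.f_oneway(*groups)
    return float(f), float(p)
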