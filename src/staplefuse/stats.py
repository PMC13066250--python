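"""Paired statistical comparison of segmentation methods.

The protocol: per metric family (DSC, JI, HD95, precision, recall), paired
two-sided Wilcoxon signed-rank tests between the STAPLE ensemble and soft
voting, STAPLE and each individual rater, and soft voting and each
individual rater — 1 + K + K comparisons per metric (11 with K = 5 raters).
Raw p-values are Benjamini–Hochberg adjusted *within* each metric family to
control the false discovery rate; majority voting is reported descriptively
and never enters the tests.

Wilcoxon conventions: zero paired differences are discarded (the classic
rule), tied absolute differences receive mean ranks, the null distribution
is exact by enumeration for n <= 25 without ties, otherwise a normal
approximation with tie and continuity correction.  Cases where a metric is
undefined for either member of a pair (HD95 on empty masks) are dropped
pairwise before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grids import DegenerateInputError

__all__ = [
    "PairedComparison",
    "ComparisonTable",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "compare_methods",
    "sample_skewness",
    "METRIC_FAMILIES",
    "EXACT_N_MAX",
]

#: metric families tested and adjusted independently
METRIC_FAMILIES = ("dsc", "ji", "hd95_mm", "precision", "recall")

#: largest n (after zero removal, no ties) for the exact null distribution
EXACT_N_MAX = 25


@dataclass
class PairedComparison:
    method_a: str
    method_b: str
    metric: str
    n_pairs: int
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    degenerate: bool = False


@dataclass
class ComparisonTable:
    """All pairwise rows, grouped by metric family, with the FDR level."""

    rows: pd.DataFrame
    alpha: float = 0.05

    COLUMNS = (
        "metric",
        "method_a",
        "method_b",
        "n_pairs",
        "statistic",
        "p_raw",
        "p_adjusted",
        "significant",
        "degenerate",
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns ``(statistic, p)`` where the statistic is the smaller of the
    positive/negative rank sums.  Raises :class:`DegenerateInputError` when
    every paired difference is zero (the test carries no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("need two equal-length 1D samples with n >= 1")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= EXACT_N_MAX and not has_ties) else "approx"
    res = sps.wilcoxon(
        d, zero_method="wilcox", correction=True, alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sorted p_(i) maps to min_{j >= i} (m * p_(j) / j), capped at 1 — the
    monotone step-up rule controlling the false discovery rate.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def sample_skewness(values: Sequence[float]) -> float:
    """Bias-corrected (adjusted Fisher–Pearson) sample skewness."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("skewness needs n >= 3")
    if np.var(v) == 0:
        raise DegenerateInputError("skewness undefined for zero-variance data")
    return float(sps.skew(v, bias=False))


def _paired_vectors(
    table_a: pd.DataFrame, table_b: pd.DataFrame, metric: str
) -> tuple[np.ndarray, np.ndarray]:
    merged = pd.merge(
        table_a[["case_id", metric]],
        table_b[["case_id", metric]],
        on="case_id",
        suffixes=("_a", "_b"),
    ).dropna()
    return merged[f"{metric}_a"].to_numpy(), merged[f"{metric}_b"].to_numpy()


def compare_methods(
    reports: Mapping[str, pd.DataFrame],
    staple: str = "staple",
    soft: str = "soft_voting",
    individuals: Sequence[str] | None = None,
    metrics: Sequence[str] = METRIC_FAMILIES,
    alpha: float = 0.05,
) -> ComparisonTable:
    """Build the full pairwise comparison table.

    ``reports`` maps method name to a per-case metric DataFrame (one row per
    case, columns ``case_id`` plus metric columns).  The comparison set is
    staple-vs-soft, staple-vs-each-individual, soft-vs-each-individual.
    Rows with all-zero paired differences are flagged degenerate and
    reported non-significant; BH adjustment runs within each metric family
    over the non-degenerate rows.
    """
    if staple not in reports or soft not in reports:
        raise ValueError(f"reports must contain the {staple!r} and {soft!r} methods")
    if individuals is None:
        individuals = [m for m in reports if m not in (staple, soft)]
    missing = [m for m in individuals if m not in reports]
    if missing:
        raise ValueError(f"individual methods missing from reports: {missing}")

    pairs = [(staple, soft)]
    pairs += [(staple, m) for m in individuals]
    pairs += [(soft, m) for m in individuals]

    rows: list[dict] = []
    for metric in metrics:
        family: list[dict] = []
        for a, b in pairs:
            xa, xb = _paired_vectors(reports[a], reports[b], metric)
            if xa.size == 0:
                raise ValueError(
                    f"no complete pairs for metric {metric!r} between {a!r} and {b!r}"
                )
            try:
                stat, p_raw = wilcoxon_signed_rank(xa, xb)
                degenerate = False
            except DegenerateInputError:
                stat, p_raw, degenerate = np.nan, np.nan, True
            family.append(
                dict(
                    metric=metric,
                    method_a=a,
                    method_b=b,
                    n_pairs=int(xa.size),
                    statistic=stat,
                    p_raw=p_raw,
                    degenerate=degenerate,
                )
            )
        testable = [r for r in family if not r["degenerate"]]
        if testable:
            adjusted = bh_adjust([r["p_raw"] for r in testable])
            for r, p_adj in zip(testable, adjusted):
                r["p_adjusted"] = float(p_adj)
        for r in family:
            if r["degenerate"]:
                r["p_adjusted"] = np.nan
            r["significant"] = bool(r["p_adjusted"] < alpha) if not r["degenerate"] else False
        rows.extend(family)

    frame = pd.DataFrame(rows, columns=list(ComparisonTable.COLUMNS))
    return ComparisonTable(rows=frame, alpha=alpha)
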