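"""Cohort-level statistics over intron ordinal groups.

Ordinal-group comparisons use the Wilcoxon rank-sum (Mann-Whitney) test;
conservation-vs-signal relationships use Kendall's tau-b, optionally after
binning sorted values into equal-size groups of genes (the smoothing used
for the headline correlations, bins of 10 genes by conservation, or 50 by
expression level); exon-count relationships use ordinary least squares on
per-group mean values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OrdinalGroupTable",
    "BinnedSeries",
    "GroupRegression",
    "CorrelationResult",
    "ordinal_summary",
    "first_vs_rest_test",
    "binned_kendall",
    "exon_group_regression",
    "expression_correlation",
]


@dataclass
class CorrelationResult:
    tau: float
    p_value: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.tau)


_UNDEFINED = CorrelationResult(float("nan"), float("nan"), 0)


@dataclass
class BinnedSeries:
    bin_size: int
    mean_x: np.ndarray
    mean_y: np.ndarray
    n_dropped: int


@dataclass
class GroupRegression:
    slope: float
    intercept: float
    r_squared: float
    n_groups: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.slope)


@dataclass
class OrdinalGroupTable:
    """Per-ordinal value lists (conserved fractions or coverage fractions)."""

    groups: dict[int, np.ndarray]

    @property
    def max_ordinal(self) -> int:
        return max(self.groups) if self.groups else 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.groups):
            v = self.groups[k]
            rows.append(
                {
                    "ordinal": k,
                    "n": len(v),
                    "median": float(np.median(v)),
                    "q1": float(np.quantile(v, 0.25)),
                    "q3": float(np.quantile(v, 0.75)),
                    "mean": float(np.mean(v)),
                }
            )
        return pd.DataFrame(rows)

    def medians(self) -> dict[int, float]:
        return {k: float(np.median(v)) for k, v in sorted(self.groups.items())}


def ordinal_summary(
    summaries: Iterable[tuple[int, float]], max_ordinal: int | None = None
) -> OrdinalGroupTable:
    """Group (ordinal, value) pairs into an :class:`OrdinalGroupTable`.

    Values must already be defined (NaN entries are dropped); ordinals above
    ``max_ordinal`` are discarded when a cap is given.
    """
    acc: dict[int, list[float]] = {}
    for ordinal, value in summaries:
        if value is None or math.isnan(value):
            continue
        if max_ordinal is not None and ordinal > max_ordinal:
            continue
        acc.setdefault(int(ordinal), []).append(float(value))
    return OrdinalGroupTable({k: np.asarray(v) for k, v in acc.items()})


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], alternative: str = "greater"
) -> float:
    """Wilcoxon rank-sum p for a vs b.

    Exact enumeration for <= 10 per side without ties, normal approximation
    with tie correction otherwise; with all observations tied the one-sided
    'greater' p is 1 by convention (no evidence of a shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def first_vs_rest_test(
    table: OrdinalGroupTable, alternative: str = "greater"
) -> dict[str | int, float]:
    """Rank-sum p-values of ordinal group 1 vs each other group and vs the pool.

    Returns a mapping: ordinal -> p for the pairwise comparisons, plus
    ``"pooled"`` for group 1 against all other groups combined.
    """
    if 1 not in table.groups:
        raise ValueError("ordinal group 1 is empty")
    first = table.groups[1]
    rest_groups = {k: v for k, v in table.groups.items() if k != 1 and len(v)}
    if not rest_groups:
        raise ValueError("no comparison groups")
    out: dict[str | int, float] = {
        k: rank_sum_test(first, v, alternative) for k, v in sorted(rest_groups.items())
    }
    pooled = np.concatenate(list(rest_groups.values()))
    out["pooled"] = rank_sum_test(first, pooled, alternative)
    return out


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall tau-b with the standard normal-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return _UNDEFINED
    res = sps.kendalltau(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def binned_kendall(
    x: Sequence[float],
    y: Sequence[float],
    bin_size: int = 10,
    drop_zero_zero: bool = True,
) -> tuple[BinnedSeries, CorrelationResult, CorrelationResult]:
    """Sort pairs by x, average consecutive ``bin_size`` pairs, correlate.

    Items where both variables are exactly 0 are excluded first by default
    (regions with neither conservation nor signal carry no information and
    retaining them only strengthens positive associations). Returns the
    binned series plus tau-b on the binned means (the headline statistic)
    and on the raw pairs. An incomplete trailing bin is dropped.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if drop_zero_zero:
        ok &= ~((x == 0) & (y == 0))
    x, y = x[ok], y[ok]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n_bins = len(x) // bin_size
    used = n_bins * bin_size
    mean_x = x[:used].reshape(n_bins, bin_size).mean(axis=1)
    mean_y = y[:used].reshape(n_bins, bin_size).mean(axis=1)
    series = BinnedSeries(bin_size, mean_x, mean_y, len(x) - used)
    binned = kendall_tau(mean_x, mean_y) if n_bins >= 2 else _UNDEFINED
    raw = kendall_tau(x, y)
    return series, binned, raw


def exon_group_regression(
    genes: Iterable[tuple[int, float]], max_group: int = 20
) -> GroupRegression:
    """OLS of per-group mean value on exon count.

    Genes are grouped by exon count: G1 = 2 exons, G2 = 3 exons, ... up to
    ``max_group`` (+1 exons). The regressor is the exon count itself, so the
    slope is in value units per exon. NaN values are dropped; fewer than two
    non-empty groups yields the undefined sentinel.
    """
    acc: dict[int, list[float]] = {}
    for n_exons, value in genes:
        if value is None or math.isnan(value):
            continue
        if 2 <= n_exons <= max_group + 1:
            acc.setdefault(int(n_exons), []).append(float(value))
    if len(acc) < 2:
        return GroupRegression(*([float("nan")] * 3), len(acc))
    xs = np.array(sorted(acc))
    ys = np.array([np.mean(acc[k]) for k in xs])
    res = sps.linregress(xs, ys)
    r2 = 0.0 if np.all(ys == ys[0]) else float(res.rvalue**2)
    return GroupRegression(float(res.slope), float(res.intercept), r2, len(xs))


def expression_correlation(
    cons: Mapping[str, float],
    expr: Mapping[str, float],
    bin_size: int = 50,
    drop_zero_zero: bool = True,
) -> tuple[BinnedSeries | None, CorrelationResult, CorrelationResult]:
    """Conservation-vs-expression tau over genes shared by both mappings.

    x = expression level, y = conserved fraction; delegates to
    :func:`binned_kendall` with bins of 50 genes by expression.
    """
    shared = sorted(set(cons) & set(expr))
    if not shared:
        return None, _UNDEFINED, _UNDEFINED
    x = [expr[g] for g in shared]
    y = [cons[g] for g in shared]
    return binned_kendall(x, y, bin_size, drop_zero_zero)
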