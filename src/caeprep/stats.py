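"""Friedman aligned-ranks comparison of treatments with Finner post hoc.

Given an ``n`` blocks x ``k`` treatments metric table, the aligned-ranks
procedure subtracts each block's mean from its observations ("alignment"),
then ranks all ``k*n`` aligned values jointly — rank 1 for the best value —
with average ranks for ties.  Aligning before ranking keeps between-block
level differences from swamping the treatment effect, which makes the test
more sensitive than the plain Friedman test when ``n`` is small.

The omnibus statistic is

    T = (k-1) [ sum_j Rhat_.j^2 - (k n^2 / 4)(k n + 1)^2 ]
        / [ k n (k n + 1)(2 k n + 1) / 6 - (1/k) sum_i Rhat_i.^2 ]

with ``Rhat_.j`` the treatment rank totals and ``Rhat_i.`` the block rank
totals, referred to a chi-square with ``k - 1`` degrees of freedom.

Post hoc, every treatment is compared against the control (the lowest —
best — average rank) via

    z_j = (Rbar_j - Rbar_control) / sqrt(k (k n + 1) / 6),

two-sided normal p-values, and the Finner step-down adjustment
``p_(i) -> max_{j<=i} [1 - (1 - p_(j))^(m/j)]`` with ``m = k - 1``
comparisons.

Typical use::

    res = FriedmanAlignedRanks(table).fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .containers import MetricTable
from .exceptions import ShapeError


def aligned_ranks(table: MetricTable) -> tuple[np.ndarray, np.ndarray]:
    """Joint ranks of block-mean-aligned values; rank 1 = best.

    Returns
    -------
    ranks
        ``(n, k)`` matrix of global ranks (average ranks at ties).
    avg_ranks
        Per-treatment column means of ``ranks``.
    """
    if table.n_blocks < 2:
        raise ShapeError("aligned ranks need at least 2 blocks")
    aligned = table.values - table.values.mean(axis=1, keepdims=True)
    if table.higher_is_better:
        aligned = -aligned  # so that ascending rankdata puts best first
    ranks = rankdata(aligned.ravel(), method="average").reshape(aligned.shape)
    return ranks, ranks.mean(axis=0)


def far_omnibus(ranks: np.ndarray) -> tuple[float, int, float]:
    """Aligned-ranks omnibus statistic, degrees of freedom and p-value.

    Raises ``ZeroDivisionError`` with an explanation when the denominator
    degenerates (every block fully concentrated on identical rank totals).
    """
    ranks = np.asarray(ranks, dtype=np.float64)
    n, k = ranks.shape
    kn = k * n
    col_tot = ranks.sum(axis=0)
    row_tot = ranks.sum(axis=1)
    numerator = (k - 1) * (np.sum(col_tot**2) - (k * n**2 / 4.0) * (kn + 1) ** 2)
    denominator = kn * (kn + 1) * (2 * kn + 1) / 6.0 - np.sum(row_tot**2) / k
    if abs(denominator) < 1e-12:
        raise ZeroDivisionError(
            "aligned-ranks statistic undefined: the block rank totals "
            "exhaust the rank variance (degenerate table)"
        )
    statistic = numerator / denominator
    df = k - 1
    pvalue = float(chi2.sf(statistic, df))
    return float(statistic), df, pvalue


@dataclass
class PairwiseComparison:
    treatment: str
    avg_rank: float
    rank_difference: float
    z: float
    pvalue: float  # raw two-sided
    pvalue_adjusted: float  # Finner step-down
    rejected: bool


@dataclass
class PosthocReport:
    """Comparisons of every treatment against the best-ranked control."""

    control: str
    alpha: float
    comparisons: list[PairwiseComparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "treatment": c.treatment,
                "avg_rank": c.avg_rank,
                "rank_difference": c.rank_difference,
                "z": c.z,
                "p_raw": c.pvalue,
                "p_finner": c.pvalue_adjusted,
                "H0": "Rejected" if c.rejected else "Not rejected",
            }
            for c in self.comparisons
        ])


def finner_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Finner step-down adjustment of ``m`` raw p-values (any order)."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order, start=1):
        value = 1.0 - (1.0 - p[idx]) ** (m / i)
        running = max(running, value)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def finner_posthoc(avg_ranks: np.ndarray, treatment_labels: list[str],
                   n_blocks: int, alpha: float = 0.05) -> PosthocReport:
    """Compare all treatments against the lowest-average-rank control.

    ``z = (Rbar_j - Rbar_control) / sqrt(k (k n + 1) / 6)`` with two-sided
    normal p-values, Finner-adjusted over the ``k - 1`` comparisons.
    """
    avg_ranks = np.asarray(avg_ranks, dtype=np.float64)
    k = avg_ranks.size
    if k < 2:
        raise ShapeError("need at least 2 treatments")
    n = n_blocks
    # lexicographic tie-break on equal average ranks
    order = sorted(range(k), key=lambda j: (avg_ranks[j], treatment_labels[j]))
    control = order[0]
    se = np.sqrt(k * (k * n + 1) / 6.0)
    others = [j for j in range(k) if j != control]
    z = np.array([(avg_ranks[j] - avg_ranks[control]) / se for j in others])
    raw = 2.0 * norm.sf(np.abs(z))
    adjusted = finner_adjust(raw)
    report = PosthocReport(control=treatment_labels[control], alpha=alpha)
    for j, zj, pj, aj in zip(others, z, raw, adjusted):
        report.comparisons.append(PairwiseComparison(
            treatment=treatment_labels[j],
            avg_rank=float(avg_ranks[j]),
            rank_difference=float(avg_ranks[j] - avg_ranks[control]),
            z=float(zj),
            pvalue=float(pj),
            pvalue_adjusted=float(aj),
            rejected=bool(aj < alpha),
        ))
    return report


class FriedmanAlignedRanks:
    """Model object for the aligned-ranks comparison of one metric table."""

    def __init__(self, table: MetricTable):
        self.table = table

    def fit(self, alpha: float = 0.05) -> "FARResults":
        ranks, avg = aligned_ranks(self.table)
        try:
            statistic, df, pvalue = far_omnibus(ranks)
        except ZeroDivisionError:
            statistic, df, pvalue = float("nan"), self.table.n_treatments - 1, float("nan")
        posthoc = finner_posthoc(
            avg, self.table.treatment_labels, self.table.n_blocks, alpha
        )
        return FARResults(self.table, ranks, avg, statistic, df, pvalue, posthoc)


@dataclass
class FARResults:
    """Fitted aligned-ranks comparison: ranks, omnibus test, post hoc."""

    table: MetricTable
    ranks: np.ndarray
    avg_ranks: np.ndarray
    statistic: float
    df: int
    pvalue: float
    posthoc: PosthocReport

    @property
    def aligned_values(self) -> np.ndarray:
        return self.table.values - self.table.values.mean(axis=1, keepdims=True)

    def rank_of(self, treatment: str) -> float:
        return float(self.avg_ranks[self.table.treatment_labels.index(treatment)])

    def to_dict(self) -> dict:
        return {
            "metric": self.table.metric_name,
            "n_blocks": self.table.n_blocks,
            "n_treatments": self.table.n_treatments,
            "avg_ranks": dict(zip(self.table.treatment_labels,
                                  map(float, self.avg_ranks))),
            "omnibus": {"statistic": self.statistic, "df": self.df,
                        "pvalue": self.pvalue},
            "control": self.posthoc.control,
            "alpha": self.posthoc.alpha,
            "comparisons": [
                {
                    "treatment": c.treatment,
                    "avg_rank": c.avg_rank,
                    "z": c.z,
                    "p_raw": c.pvalue,
                    "p_finner": c.pvalue_adjusted,
                    "rejected": c.rejected,
                }
                for c in self.posthoc.comparisons
            ],
        }

    def summary(self) -> str:
        lines = [
            f"Friedman aligned-ranks comparison — {self.table.metric_name or 'metric'}",
            f"blocks n={self.table.n_blocks}, treatments k={self.table.n_treatments}",
            f"omnibus T={self.statistic:.4f} (df={self.df}), p={self.pvalue:.6g}",
            f"control (best average rank): {self.posthoc.control}",
            "",
            f"{'treatment':<14}{'avg rank':>10}{'p (raw)':>12}"
            f"{'p (Finner)':>12}  H0",
        ]
        ctrl_rank = self.rank_of(self.posthoc.control)
        lines.append(f"{self.posthoc.control:<14}{ctrl_rank:>10.4f}"
                     f"{'-':>12}{'-':>12}  -")
        for c in sorted(self.posthoc.comparisons, key=lambda c: c.avg_rank):
            lines.append(
                f"{c.treatment:<14}{c.avg_rank:>10.4f}{c.pvalue:>12.6f}"
                f"{c.pvalue_adjusted:>12.6f}  "
                f"{'Rejected' if c.rejected else 'Not rejected'}"
            )
        return "\n".join(lines)
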