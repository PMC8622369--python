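"""Aligned-ranks test and Finner post hoc: oracles, symmetry, published values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, norm

from caeprep import (
    FriedmanAlignedRanks,
    MetricTable,
    aligned_ranks,
    far_omnibus,
    finner_posthoc,
)
from caeprep.benchmarks import combined_table
from caeprep.stats import finner_adjust
from caeprep.exceptions import ShapeError


def _table(values, higher_is_better=True):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return MetricTable(values, [f"b{i}" for i in range(n)],
                       [f"t{j}" for j in range(k)], "m", higher_is_better)


def _brute_force_aligned_ranks(values):
    """Independent oracle: align, then sort-and-assign global ranks by hand."""
    values = np.asarray(values, dtype=float)
    aligned = values - values.mean(axis=1, keepdims=True)
    flat = sorted(
        ((-aligned[i, j], (i, j)) for i in range(values.shape[0])
         for j in range(values.shape[1])),
        key=lambda pair: pair[0],
    )
    ranks = np.zeros_like(values)
    pos = 0
    while pos < len(flat):
        end = pos
        while end < len(flat) and flat[end][0] == flat[pos][0]:
            end += 1
        avg_rank = (pos + 1 + end) / 2.0  # mean of ranks pos+1 .. end
        for _, (i, j) in flat[pos:end]:
            ranks[i, j] = avg_rank
        pos = end
    return ranks


def _straight_formula_omnibus(ranks):
    """Second, independent implementation of the omnibus statistic."""
    n, k = ranks.shape
    kn = k * n
    rhat_col = [sum(ranks[i][j] for i in range(n)) for j in range(k)]
    rhat_row = [sum(ranks[i][j] for j in range(k)) for i in range(n)]
    num = (k - 1) * (sum(r * r for r in rhat_col)
                     - (k * n * n / 4) * (kn + 1) ** 2)
    den = kn * (kn + 1) * (2 * kn + 1) / 6 - sum(r * r for r in rhat_row) / k
    return num / den


class TestAlignedRanks:
    def test_rank_one_is_best(self):
        ranks, avg = aligned_ranks(_table([[1, 2, 10], [1, 2, 10]]))
        assert ranks[0, 2] < ranks[0, 0]
        assert avg[2] == ranks[:, 2].mean()

    def test_lower_is_better_flips(self):
        values = [[1, 2, 10], [3, 2, 20]]
        _, avg_hi = aligned_ranks(_table(values, higher_is_better=True))
        _, avg_lo = aligned_ranks(_table(values, higher_is_better=False))
        assert avg_hi[2] < avg_hi[0] and avg_lo[2] > avg_lo[0]

    def test_identical_columns_full_tie(self):
        n, k = 12, 3
        values = np.tile(np.arange(n)[:, None], (1, k))
        ranks, avg = aligned_ranks(_table(values))
        assert np.allclose(avg, (k * n + 1) / 2)  # 18.5 for n=12, k=3
        statistic, _, p = far_omnibus(ranks)
        assert statistic == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_oracle_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        values = np.round(rng.random((4, 3)), 1)  # coarse grid induces ties
        ranks, _ = aligned_ranks(_table(values))
        assert np.allclose(ranks, _brute_force_aligned_ranks(values))

    def test_brute_force_oracle_engineered_ties(self):
        values = np.array([[1.0, 2.0, 3.0],
                           [2.0, 3.0, 4.0],   # same aligned row as block 0
                           [5.0, 5.0, 5.0],
                           [0.0, 1.0, 5.0]])
        ranks, _ = aligned_ranks(_table(values))
        assert np.allclose(ranks, _brute_force_aligned_ranks(values))

    def test_rank_conservation(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, k = int(rng.integers(2, 8)), int(rng.integers(2, 5))
            values = np.round(rng.random((n, k)), 1)
            ranks, avg = aligned_ranks(_table(values))
            total = k * n * (k * n + 1) / 2
            assert ranks.sum() == pytest.approx(total)
            assert (avg * n).sum() == pytest.approx(total)

    def test_monotonicity_of_improvement(self):
        rng = np.random.default_rng(7)
        values = rng.random((5, 3))
        _, before = aligned_ranks(_table(values))
        boosted = values.copy()
        boosted[:, 1] += 0.5  # uniformly better in every block
        _, after = aligned_ranks(_table(boosted))
        assert after[1] <= before[1] + 1e-12

    def test_single_block_rejected(self):
        with pytest.raises(ShapeError):
            aligned_ranks(_table([[1.0, 2.0]]))


class TestOmnibus:
    @pytest.mark.parametrize("seed", range(5))
    def test_dual_implementation_agreement(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((6, 3))
        ranks, _ = aligned_ranks(_table(values))
        statistic, df, p = far_omnibus(ranks)
        assert statistic == pytest.approx(_straight_formula_omnibus(ranks),
                                          abs=1e-9)
        assert df == 2
        assert p == pytest.approx(float(chi2.sf(statistic, df)))

    def test_invariant_under_treatment_relabeling(self):
        rng = np.random.default_rng(11)
        values = rng.random((5, 3))
        ranks, _ = aligned_ranks(_table(values))
        t1 = far_omnibus(ranks)[0]
        perm = values[:, [2, 0, 1]]
        ranks_p, _ = aligned_ranks(_table(perm))
        t2 = far_omnibus(ranks_p)[0]
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_degenerate_denominator_reported(self):
        # crafted rank totals that exhaust the rank variance exactly
        a = np.sqrt(2.5)
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            far_omnibus(np.array([[a, a]]))

    def test_degenerate_table_yields_nan_results(self):
        res = FriedmanAlignedRanks(
            _table([[1.0, 1.0], [1.0, 1.0]])
        ).fit()
        # fully tied table: omnibus may degenerate but post hoc still reports
        assert res.posthoc.control == "t0"  # lexicographic tie-break


class TestFinner:
    def test_single_comparison_unchanged(self):
        assert finner_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_two_comparison_formula(self):
        adjusted = finner_adjust(np.array([0.01, 0.04]))
        assert adjusted[0] == pytest.approx(1 - 0.99**2)  # 0.0199
        assert adjusted[1] == pytest.approx(0.04)

    @given(st.lists(st.floats(1e-6, 0.999), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        p = np.array(pvals)
        adjusted = finner_adjust(p)
        assert np.all(adjusted >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_posthoc_z_formula(self):
        avg = np.array([10.0, 20.0, 15.0])
        report = finner_posthoc(avg, ["a", "b", "c"], n_blocks=12)
        assert report.control == "a"
        se = np.sqrt(3 * 37 / 6.0)
        comp = {c.treatment: c for c in report.comparisons}
        assert comp["b"].z == pytest.approx(10.0 / se)
        assert comp["b"].pvalue == pytest.approx(
            2 * (1 - norm.cdf(10.0 / se)))


class TestPublishedBenchmarkValues:
    """The shipped 12-block tables reproduce the published rankings."""

    def test_accuracy_average_ranks(self):
        res = FriedmanAlignedRanks(combined_table("accuracy")).fit()
        assert res.rank_of("Traditional") == pytest.approx(24.4167, abs=0.05)
        assert res.rank_of("MD") == pytest.approx(21.6667, abs=0.05)
        assert res.rank_of("CAE") == pytest.approx(9.4167, abs=0.05)
        assert res.posthoc.control == "CAE"

    def test_auc_average_ranks_and_pvalues(self):
        res = FriedmanAlignedRanks(combined_table("auc")).fit()
        assert res.rank_of("CAE") == pytest.approx(7.5833, abs=0.05)
        assert res.rank_of("MD") == pytest.approx(22.0417, abs=0.05)
        assert res.rank_of("Traditional") == pytest.approx(25.8750, abs=0.05)
        comp = {c.treatment: c for c in res.posthoc.comparisons}
        assert comp["MD"].pvalue == pytest.approx(0.000775, rel=0.02)
        assert comp["Traditional"].pvalue == pytest.approx(0.000021, rel=0.02)
        assert comp["MD"].rejected and comp["Traditional"].rejected

    def test_gm_average_ranks(self):
        res = FriedmanAlignedRanks(combined_table("gm")).fit()
        assert res.rank_of("CAE") == pytest.approx(11.5000, abs=0.25)
        assert res.rank_of("MD") == pytest.approx(17.8333, abs=0.25)
        assert res.rank_of("Traditional") == pytest.approx(26.1667, abs=0.25)

    def test_standard_error_constant(self):
        # k=3, n=12: sqrt(k(kn+1)/6) = sqrt(18.5); with the published AUC
        # rank difference 14.4584 this reproduces the published p-value
        se = np.sqrt(3 * (36 + 1) / 6.0)
        assert se == pytest.approx(4.30116, abs=1e-5)
        p = 2 * (1 - norm.cdf((22.0417 - 7.5833) / se))
        assert p == pytest.approx(0.000775, rel=0.02)

    def test_summary_renders(self):
        res = FriedmanAlignedRanks(combined_table("accuracy")).fit()
        text = res.summary()
        assert "CAE" in text and "Rejected" in text
        d = res.to_dict()
        assert d["n_blocks"] == 12 and len(d["comparisons"]) == 2
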