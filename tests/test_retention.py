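"""Gene filters, ratio tables, paired signed-rank and global-totals tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceburden.counting import CountMatrix
from spliceburden.design import SampleDesign, default_design
from spliceburden.retention import (
    condition_means,
    filter_genes,
    gene_ratio_table,
    global_totals,
    paired_retention_test,
    stratify_by_expression,
)


def matrix(genes, samples, exonic, genic, design=None):
    return CountMatrix(genes, samples, np.array(exonic), np.array(genic),
                       design or [])


def two_condition_design(n_reps=3):
    design = default_design(n_reps)
    return [d for d in design if d.sample_id.startswith(("Ccis", "Dcis"))]


class TestFilterGenes:
    def test_zero_read_gene_discarded(self):
        cm = matrix(["a", "b"], ["s1", "s2", "s3"],
                    [[0, 5, 5], [3, 3, 3]], [[1, 6, 6], [4, 4, 4]])
        filt, rep = filter_genes(cm)
        assert filt.genes == ["b"]
        assert rep.n_zero == 1 and rep.n_flagged == 0

    def test_flagged_gene_discarded(self):
        cm = matrix(["inner", "ok"], ["s1"], [[5], [3]], [[0], [4]])
        filt, rep = filter_genes(cm)
        assert filt.genes == ["ok"]
        assert rep.n_flagged == 1

    def test_all_positive_matrix_untouched(self):
        cm = matrix(["a", "b"], ["s1", "s2"], [[1, 2], [3, 4]], [[2, 3], [3, 5]])
        filt, rep = filter_genes(cm)
        assert filt.genes == ["a", "b"]
        assert rep.n_retained == 2 and rep.n_input == 2

    def test_counts_add_up(self):
        cm = matrix(["a", "b", "c"], ["s1"], [[0], [5], [2]], [[1], [3], [4]])
        _, rep = filter_genes(cm)
        assert rep.n_flagged + rep.n_zero + rep.n_retained == rep.n_input


class TestGeneRatioTable:
    def test_ratio_arithmetic(self):
        design = [SampleDesign(f"C_{i}", "shCtrl", "none", i) for i in (1, 2, 3)]
        cm = matrix(["g"], [d.sample_id for d in design],
                    [[10, 10, 10]], [[12, 13, 11]], design)
        ratios = gene_ratio_table(cm, design)
        assert ratios.loc["g"].tolist() == pytest.approx([0.2, 0.3, 0.1])
        means = condition_means(ratios, design)
        assert means.loc["g", "C"] == pytest.approx(0.2)

    def test_zero_intronic_gives_zero_ratio(self):
        design = [SampleDesign("C_1", "shCtrl", "none", 1)]
        cm = matrix(["g"], ["C_1"], [[10]], [[10]], design)
        assert gene_ratio_table(cm, design).loc["g", "C_1"] == 0.0

    def test_unfiltered_zero_exonic_is_contract_violation(self):
        design = [SampleDesign("C_1", "shCtrl", "none", 1)]
        cm = matrix(["g"], ["C_1"], [[0]], [[3]], design)
        with pytest.raises(RuntimeError, match="filter"):
            gene_ratio_table(cm, design)


def null_rejection_rate(n_rep=500, n_genes=2000, alpha=0.05, seed=1234):
    """Monte-Carlo type-I error of the paired test under a null where both
    conditions draw per-gene ratios from the same Poisson-mixture law.
    Returns (rejection rate, 99.9% binomial half-width)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        lam = rng.gamma(2.0, 2.0, size=n_genes)
        a = rng.poisson(lam) / 10.0
        b = rng.poisson(lam) / 10.0
        keep = a != b
        res = paired_retention_test(
            pd.DataFrame({"Ccis": a[keep], "Dcis": b[keep]}), "Ccis", "Dcis"
        )
        rejections += res.p_value < alpha
    rate = rejections / n_rep
    band = 3.29 * np.sqrt(alpha * (1 - alpha) / n_rep)
    return rate, band


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Oracle: two-sided exact p by enumerating all 2^n sign assignments."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


class TestPairedRetentionTest:
    def _frame(self, a, b):
        return pd.DataFrame({"Ccis": a, "Dcis": b})

    def test_all_positive_differences_n5(self):
        """Differences (1,2,3,4,5): the exact two-sided p is 2/32."""
        cm = self._frame(np.zeros(5), np.array([1.0, 2, 3, 4, 5]))
        res = paired_retention_test(cm, "Ccis", "Dcis")
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"
        assert res.n_pairs == 5

    def test_identical_conditions_error(self):
        cm = self._frame(np.ones(4), np.ones(4))
        with pytest.raises(ValueError, match="zero"):
            paired_retention_test(cm, "Ccis", "Dcis")

    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_matches_enumeration_oracle(self, n, rng):
        """Exact branch reproduces full sign-assignment enumeration for
        tie-free samples up to n=12."""
        for _ in range(5):
            d = rng.normal(0.1, 1.0, size=n)
            cm = self._frame(np.zeros(n), d)
            res = paired_retention_test(cm, "Ccis", "Dcis")
            assert res.p_value == pytest.approx(exact_signed_rank_p(d))

    def test_one_sided_alternative(self):
        d = np.array([1.0, 2, 3, 4, 5])
        res = paired_retention_test(
            self._frame(np.zeros(5), d), "Ccis", "Dcis", alternative="greater"
        )
        assert res.p_value == pytest.approx(1 / 32)

    def test_type_one_error_under_null(self):
        """Rejection rate at α=0.05 stays inside a 99.9% binomial band when
        both conditions share the same retention-ratio distribution."""
        rate, band = null_rejection_rate(n_rep=500, n_genes=2000, seed=1234)
        assert abs(rate - 0.05) <= band


class TestGlobalTotals:
    def test_identical_samples_give_null_result(self):
        design = two_condition_design(2)
        cols = [d.sample_id for d in design]
        cm = matrix(["g"], cols, [[10] * 4], [[15] * 4], design)
        res = global_totals(cm, design, "Ccis", "Dcis")
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_matches_hand_welch(self):
        """Intronic totals (100,110,90) vs (200,210,190) over constant exonic
        1000 reproduce a textbook Welch t-test on the intronic fractions."""
        design = two_condition_design(3)
        cols = [d.sample_id for d in design]
        intronic = np.array([100, 110, 90, 200, 210, 190])
        exonic = np.full(6, 1000)
        cm = matrix(["g"], cols, [exonic.tolist()], [(exonic + intronic).tolist()],
                    design)
        res = global_totals(cm, design, "Ccis", "Dcis")
        fa = intronic[:3] / (intronic[:3] + 1000)
        fb = intronic[3:] / (intronic[3:] + 1000)
        t_ref, p_ref = stats.ttest_ind(fb, fa, equal_var=False)
        assert res.t_statistic == pytest.approx(t_ref)
        assert res.p_value == pytest.approx(p_ref)
        # hand Welch: t = (mb-ma)/sqrt(sa^2/3+sb^2/3)
        t_hand = (fb.mean() - fa.mean()) / np.sqrt(fa.var(ddof=1) / 3 + fb.var(ddof=1) / 3)
        assert res.t_statistic == pytest.approx(t_hand)

    def test_requires_two_replicates(self):
        design = two_condition_design(1)
        cols = [d.sample_id for d in design]
        cm = matrix(["g"], cols, [[10, 10]], [[12, 15]], design)
        with pytest.raises(ValueError, match="replicates"):
            global_totals(cm, design, "Ccis", "Dcis")


class TestStratify:
    def _setup(self, n_genes, rng, shift_top_half=0.0):
        design = two_condition_design(3)
        cols = [d.sample_id for d in design]
        expr = np.sort(rng.integers(10, 1000, size=n_genes))
        exonic = np.tile(expr[:, None], (1, 6))
        intr = rng.poisson(exonic * 0.05)
        genic = exonic + intr
        # add a retention shift to the Dcis replicates of high-expression genes
        bump = np.zeros((n_genes, 6), dtype=int)
        top = np.arange(n_genes) >= n_genes // 2
        bump[np.ix_(top, [3, 4, 5])] = rng.poisson(
            expr[top][:, None] * shift_top_half, size=(top.sum(), 3)
        )
        genic = genic + bump
        cm = CountMatrix(
            [f"g{i:04d}" for i in range(n_genes)], cols, exonic, genic, design
        )
        return design, cm

    def test_equal_size_strata(self, rng):
        design, cm = self._setup(100, rng)
        ratios = gene_ratio_table(cm, design)
        results = stratify_by_expression(ratios, cm, design, "Ccis", "Dcis", 4)
        assert [r.n_genes for r in results] == [25, 25, 25, 25]

    def test_single_stratum_reproduces_unstratified(self, rng):
        design, cm = self._setup(60, rng, shift_top_half=0.05)
        ratios = gene_ratio_table(cm, design)
        overall = paired_retention_test(
            condition_means(ratios, design), "Ccis", "Dcis"
        )
        [res] = stratify_by_expression(ratios, cm, design, "Ccis", "Dcis", 1)
        assert res.result.p_value == overall.p_value
        assert res.result.statistic == overall.statistic

    def test_shift_detected_only_in_top_strata(self, rng):
        design, cm = self._setup(400, rng, shift_top_half=0.15)
        ratios = gene_ratio_table(cm, design)
        low, high = stratify_by_expression(ratios, cm, design, "Ccis", "Dcis", 2)
        assert high.result.p_value < 1e-6
        assert low.result.p_value > 0.01
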