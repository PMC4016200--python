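"""G-test, BH adjustment, fold changes and responsive-transcript calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from cdseq.diffexpr import (
    bh_fdr,
    call_responsive,
    fold_change,
    g_test_2x2,
    g_test_vectorized,
    rank_top_upregulated,
)
from cdseq.models import Contrast, CountLibrary, TranscriptModel


def bh_stepup_oracle(pvals):
    """Textbook BH step-up, written independently of the implementation."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestGTest:
    def test_worked_example(self):
        # frozen from an independent evaluation of 2*sum O*ln(O/E) and
        # the chi-square(1) upper tail
        G, p = g_test_2x2(30, 1000, 60, 1000)
        assert G == pytest.approx(10.66516577275901, rel=1e-10)
        assert p == pytest.approx(0.0010917206723411934, rel=1e-10)

    def test_equal_proportions_give_zero(self):
        G, p = g_test_2x2(10, 100, 20, 200)
        assert G == 0.0
        assert p == 1.0

    def test_symmetric_under_condition_swap(self):
        G1, p1 = g_test_2x2(30, 1000, 60, 1000)
        G2, p2 = g_test_2x2(60, 1000, 30, 1000)
        assert G1 == pytest.approx(G2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_count_cells_contribute_nothing(self):
        G, p = g_test_2x2(0, 100, 5, 100)
        assert np.isfinite(G) and G > 0 and 0 < p < 1

    @pytest.mark.parametrize("args", [(-1, 10, 1, 10), (11, 10, 1, 10), (1, 0, 1, 10)])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            g_test_2x2(*args)

    def test_matches_likelihood_ratio_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(50, 5000, size=2)
            a = int(rng.integers(1, n1))
            b = int(rng.integers(1, n2))
            G, p = g_test_2x2(a, int(n1), b, int(n2))
            table = [[a, n1 - a], [b, n2 - b]]
            res = chi2_contingency(table, correction=False, lambda_="log-likelihood")
            assert G == pytest.approx(res.statistic, rel=1e-10, abs=1e-12)
            assert p == pytest.approx(res.pvalue, rel=1e-9, abs=1e-300)

    def test_close_to_pearson_on_large_counts(self):
        # the likelihood-ratio and Pearson statistics are asymptotically
        # equivalent; on well-filled tables they agree to a few percent
        rng = np.random.default_rng(1)
        for _ in range(50):
            n1 = n2 = 100_000
            a = int(rng.integers(500, 2000))
            b = int(rng.integers(500, 2000))
            G, _ = g_test_2x2(a, n1, b, n2)
            chi2_stat = chi2_contingency(
                [[a, n1 - a], [b, n2 - b]], correction=False
            ).statistic
            assert G == pytest.approx(chi2_stat, rel=0.05, abs=0.05)

    def test_monotone_in_depth_at_fixed_proportions(self):
        G1, _ = g_test_2x2(30, 1000, 60, 1000)
        G2, _ = g_test_2x2(300, 10000, 600, 10000)
        assert G2 > G1

    def test_vectorized_agrees_with_scalar(self):
        a = np.array([3, 10, 0])
        b = np.array([9, 10, 4])
        G, p = g_test_vectorized(a, 500, b, 600)
        for i in range(3):
            gs, ps = g_test_2x2(int(a[i]), 500, int(b[i]), 600)
            assert G[i] == pytest.approx(gs) and p[i] == pytest.approx(ps)


class TestBH:
    def test_hand_computed_vectors(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert bh_fdr([]).size == 0

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
        st.randoms(use_true_random=False),
    )
    def test_matches_stepup_oracle_and_permutation_invariant(self, pvals, rnd):
        q = bh_fdr(pvals)
        assert q == pytest.approx(bh_stepup_oracle(pvals))
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q_perm = bh_fdr([pvals[i] for i in perm])
        assert [q_perm[perm.index(i)] for i in range(len(pvals))] == pytest.approx(list(q))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestFoldChange:
    @pytest.mark.parametrize(
        "trt,base,expected", [(0, 0, 1.0), (9, 4, 2.0), (4, 9, 0.5), (1, 0, 2.0)]
    )
    def test_pseudocounted_ratio(self, trt, base, expected):
        assert fold_change(trt, base) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 2.0)


class TestCallResponsive:
    def test_all_zero_transcript_not_responsive_fc_one(self):
        models = [
            TranscriptModel("T1", "L1", 1000),
            TranscriptModel("T2", "L2", 1000),
        ]
        merged = {
            ("root", "0h"): CountLibrary("root", "0h", {"T2": 100}, 10_000),
            ("root", "1h"): CountLibrary("root", "1h", {"T2": 5000}, 10_000),
        }
        contrast = Contrast("root", "0h", "1h")
        res = call_responsive(merged, models, [contrast])[contrast]
        assert not res.loc["T1", "responsive"]
        assert res.loc["T1", "fold_change"] == pytest.approx(1.0)
        assert res.loc["T1", "q"] == 1.0
        # the strongly shifted detected transcript is called
        assert res.loc["T2", "responsive"] and res.loc["T2", "direction"] == "up"

    def test_missing_condition_raises(self):
        models = [TranscriptModel("T1", "L1", 1000)]
        merged = {("root", "0h"): CountLibrary("root", "0h", {"T1": 5}, 1000)}
        with pytest.raises(ValueError, match="missing merged library"):
            call_responsive(merged, models, [Contrast("root", "0h", "1h")])

    def test_planted_high_effect_recovered(self, merged_small, contrasts):
        merged, models, truth = merged_small
        res = call_responsive(merged, models, contrasts)
        for contrast in contrasts:
            planted = truth.de_ids(contrast)
            called = set(res[contrast].index[res[contrast]["responsive"]])
            recall = len(planted & called) / len(planted)
            assert recall > 0.9


class TestRankTopUpregulated:
    def test_reference_table_order_preserved(self):
        from cdseq.reference_tables import load_top20_novel_upregulated

        table = load_top20_novel_upregulated()
        ranked = rank_top_upregulated(table, k=20)
        assert list(ranked["fold_change"]) == sorted(table["fold_change"], reverse=True)
        assert ranked["fold_change"].iloc[0] == 341.43
        assert ranked["fold_change"].iloc[-1] == 68.00

    def test_k_larger_than_table_returns_all(self):
        df = pd.DataFrame({"transcript_id": ["a", "b"], "fold_change": [3.0, 2.0]})
        assert len(rank_top_upregulated(df, k=100)) == 2

    def test_ties_break_lexicographically(self):
        df = pd.DataFrame(
            {"transcript_id": ["c", "a", "b"], "fold_change": [2.0, 2.0, 2.0]}
        )
        ranked = rank_top_upregulated(df, k=3)
        assert list(ranked["transcript_id"]) == ["a", "b", "c"]

    def test_annotation_filter_and_k_validation(self):
        df = pd.DataFrame({"fold_change": [3.0, 2.0]}, index=["a", "b"])
        df.index.name = "transcript_id"
        kept = rank_top_upregulated(df, annotation_filter=lambda t: t == "b", k=5)
        assert list(kept.index) == ["b"]
        with pytest.raises(ValueError):
            rank_top_upregulated(df, k=0)
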