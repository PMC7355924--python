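"""Correlation, homogeneity, FDR adjustment, and coherency rules."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import coherenet as cn
from coherenet.association import ConstantVectorError


def pv(x, y, ds="d1"):
    return cn.PairedVectors(ds, np.asarray(x, dtype=float),
                            np.asarray(y, dtype=float))


class TestCorrelate:
    def test_perfect_linear(self):
        assert cn.correlate(pv([1, 2, 3], [2, 4, 6])).r == pytest.approx(1.0)
        assert cn.correlate(pv([1, 2, 3], [3, 2, 1])).r == pytest.approx(-1.0)

    def test_pearson_p_equals_t_transform(self):
        """r = 0.8 by hand; p must match the closed-form t CDF with n-2 df."""
        res = cn.correlate(pv([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        assert res.r == pytest.approx(0.8)
        t = res.r * np.sqrt(3) / np.sqrt(1 - res.r ** 2)
        p_closed = 2 * sps.t.sf(abs(t), df=3)
        assert res.p == pytest.approx(p_closed, abs=1e-10)

    def test_constant_vector_signals(self):
        with pytest.raises(ConstantVectorError):
            cn.correlate(pv([1, 1, 1], [1, 2, 3]))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cn.correlate(pv([1, 2], [2, 1]))

    def test_spearman_is_pearson_on_ranks(self):
        rng = np.random.default_rng(5)
        x = rng.permutation(20).astype(float)   # no ties
        y = rng.permutation(20).astype(float)
        sp = cn.correlate(pv(x, y), method="spearman")
        pe = cn.correlate(pv(sps.rankdata(x), sps.rankdata(y)), method="pearson")
        assert sp.r == pytest.approx(pe.r, abs=1e-12)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
    def test_methods_agree_in_sign_on_monotone_data(self, method):
        x = np.arange(1.0, 13.0)
        up = cn.correlate(pv(x, np.exp(x)), method=method)
        down = cn.correlate(pv(x, -x ** 3), method=method)
        assert up.r > 0 > down.r


class TestAssessPair:
    def make_coll(self, specs):
        """specs: list of (x, y) per dataset."""
        datasets = []
        for k, (x, y) in enumerate(specs):
            df = pd.DataFrame([x, y], index=["A", "B"],
                              columns=[f"s{i}" for i in range(len(x))],
                              dtype=float)
            datasets.append(cn.ExpressionDataset(f"d{k}", df))
        return cn.ExpressionCollection(datasets)

    def test_single_dataset_identity(self):
        x = np.arange(10.0)
        y = 0.9 * x + np.array([0.1, -0.2, 0.05, 0.3, -0.1, 0.2, -0.3, 0.0, 0.1, -0.05])
        coll = self.make_coll([(x, y)])
        assoc = cn.assess_pair("A", "B", coll)
        assert assoc.homogeneous
        assert assoc.combined_r == pytest.approx(assoc.per_dataset[0].r)
        assert assoc.combined_p == pytest.approx(assoc.per_dataset[0].p)

    def test_sign_flip_is_heterogeneous(self):
        rng = np.random.default_rng(1)
        x1 = rng.standard_normal(10)
        x2 = rng.standard_normal(10)
        coll = self.make_coll([(x1, x1 + 0.1 * rng.standard_normal(10)),
                               (x2, -x2 + 0.1 * rng.standard_normal(10))])
        assert not cn.assess_pair("A", "B", coll).homogeneous

    def test_weighted_mean_combination(self):
        """Datasets engineered to r=+0.5 (n=10) and r=+0.7 (n=30) combine
        to the n-weighted mean 0.65."""
        rng = np.random.default_rng(0)

        def with_r(n, r, seed):
            g = np.random.default_rng(seed)
            x = g.standard_normal(n)
            y = g.standard_normal(n)
            # Gram-Schmidt: make y exactly r-correlated with x
            x0 = (x - x.mean()) / x.std()
            y0 = y - y.mean()
            y0 -= x0 * (x0 @ y0) / (x0 @ x0)
            y0 /= y0.std()
            return x0, r * x0 + np.sqrt(1 - r ** 2) * y0

        coll = self.make_coll([with_r(10, 0.5, 1), with_r(30, 0.7, 2)])
        assoc = cn.assess_pair("A", "B", coll)
        assert assoc.per_dataset[0].r == pytest.approx(0.5, abs=1e-9)
        assert assoc.per_dataset[1].r == pytest.approx(0.7, abs=1e-9)
        assert assoc.combined_r == pytest.approx((10 * 0.5 + 30 * 0.7) / 40, abs=1e-9)
        fisher = sps.combine_pvalues([res.p for res in assoc.per_dataset],
                                     method="fisher").pvalue
        assert assoc.combined_p == pytest.approx(fisher)

    def test_max_n_aggregation(self):
        rng = np.random.default_rng(7)
        x1, x2 = rng.standard_normal(8), rng.standard_normal(20)
        coll = self.make_coll([(x1, x1 + rng.standard_normal(8)),
                               (x2, x2 + rng.standard_normal(20))])
        assoc = cn.assess_pair("A", "B", coll, aggregation="max_n")
        assert assoc.combined_r == pytest.approx(assoc.per_dataset[1].r)

    def test_ineligible_pair_raises(self):
        coll = self.make_coll([([1, 2], [2, 1])])
        with pytest.raises(cn.association.IneligiblePairError):
            cn.assess_pair("A", "B", coll)


class TestFDR:
    def test_step_up_hand_case(self):
        np.testing.assert_allclose(cn.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        np.testing.assert_allclose(cn.fdr_adjust([0.5]), [0.5])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(cn.fdr_adjust([0.2] * 6), [0.2] * 6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cn.fdr_adjust([0.5, 1.5])

    def test_order_preserving(self):
        p = [0.04, 0.001, 0.2, 0.01]
        q = cn.fdr_adjust(p)
        assert list(np.argsort(q)) == list(np.argsort(p))


class TestClassification:
    def make_assoc(self, r, q):
        a = cn.PairAssociation("A", "B", [], True, r, q)
        a.q = q
        return a

    @pytest.mark.parametrize("r, q, expected", [
        (0.5, 0.01, "positive"),
        (-0.5, 0.03, "negative"),
        (0.9, 0.06, "non_significant"),
    ])
    def test_sign_category(self, r, q, expected):
        assert cn.classify_sign_category(self.make_assoc(r, q)) == expected

    @pytest.mark.parametrize("sign, category, call", [
        (1, "positive", "coherent"),
        (-1, "negative", "coherent"),
        (-1, "positive", "incoherent"),
        (1, "negative", "incoherent"),
        (1, "non_significant", "non_significant"),
        (-1, "non_significant", "non_significant"),
    ])
    def test_edge_coherency(self, sign, category, call):
        assert cn.classify_edge_coherency(sign, category).call == call

    def test_sign_flip_antisymmetry(self):
        """Flipping the edge sign swaps coherent <-> incoherent; the
        non-significant verdict is sign-invariant."""
        swap = {"coherent": "incoherent", "incoherent": "coherent",
                "non_significant": "non_significant"}
        for category in cn.association.CATEGORIES:
            plus = cn.classify_edge_coherency(1, category).call
            minus = cn.classify_edge_coherency(-1, category).call
            assert minus == swap[plus]


class TestDegCoherency:
    @pytest.mark.parametrize("d1, d2, sign, expected", [
        ("up", "up", 1, "coherent"),
        ("up", "up", -1, "incoherent"),
        ("up", "down", -1, "coherent"),
        ("down", "down", 1, "coherent"),
        ("down", "up", 1, "incoherent"),
    ])
    def test_rule(self, d1, d2, sign, expected):
        assert cn.classify_deg_coherency(d1, d2, sign) == expected

    def test_truth_table_exhaustion(self):
        """Exactly 4 of the 8 (direction, direction, sign) combinations
        are coherent."""
        calls = [cn.classify_deg_coherency(a, b, s)
                 for a, b, s in itertools.product(("up", "down"),
                                                  ("up", "down"), (1, -1))]
        assert calls.count("coherent") == 4
        assert calls.count("incoherent") == 4

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            cn.classify_deg_coherency("up", "flat", 1)
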