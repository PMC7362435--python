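"""Differential acetylation: RPKM, size factors, the NB Wald test, BH
adjustment and the clustering normalization chain."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from acetylome.consensus import ConsensusRegion, CountsMatrix
from acetylome.differential import (
    bh_adjust,
    classify_dars,
    nb_test,
    normalize_for_clustering,
    quantile_normalize,
    results_to_frame,
    rpkm,
    size_factors,
)
from acetylome.regions import GenomicRegion


class TestRpkm:
    def test_direct_formula(self):
        out = rpkm(np.array([[10]]), np.array([2000]), np.array([1e6]))
        assert out[0, 0] == pytest.approx(5.0)

    def test_zero_count(self):
        assert rpkm(np.array([[0]]), np.array([2000]), np.array([1e6]))[0, 0] == 0

    def test_library_doubling_halves(self, rng):
        counts = rng.integers(0, 100, size=(20, 2))
        lens = rng.integers(500, 5000, size=20)
        a = rpkm(counts, lens, np.array([1e6, 1e6]))
        b = rpkm(counts, lens, np.array([2e6, 1e6]))
        np.testing.assert_allclose(b[:, 0] * 2, a[:, 0])
        np.testing.assert_allclose(b[:, 1], a[:, 1])


class TestSizeFactors:
    def test_doubled_sample(self):
        counts = np.array([[10, 20], [30, 60], [7, 14]])
        np.testing.assert_allclose(
            size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_identical_samples(self):
        counts = np.tile(np.array([[5], [9], [20]]), (1, 4))
        np.testing.assert_allclose(size_factors(counts), np.ones(4))

    def test_matches_bruteforce(self, rng):
        import math

        counts = rng.negative_binomial(10, 0.1, size=(300, 6)) + 1
        # independent slow implementation: explicit loops
        gm = [
            math.exp(sum(math.log(float(c)) for c in row) / len(row))
            for row in counts
        ]
        expected = []
        for j in range(6):
            ratios = sorted(counts[i, j] / gm[i] for i in range(300))
            expected.append(np.median(ratios))
        np.testing.assert_allclose(size_factors(counts), expected, rtol=1e-9)

    def test_no_allpositive_region_raises(self):
        with pytest.raises(ValueError):
            size_factors(np.array([[0, 5], [3, 0]]))


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_single_and_degenerate(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))

    def test_nan_passthrough_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.02])
        out = bh_adjust(p)
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    def test_matches_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


def _make_counts(rng, mu, lfc, n1, n2, dispersion):
    group = np.array([1] * n1 + [0] * n2)
    mean = mu[:, None] * 2.0 ** (lfc[:, None] * group[None, :])
    r = 1 / dispersion
    return rng.negative_binomial(r, r / (r + mean)), group


class TestNbTest:
    def test_no_signal_region(self, rng):
        counts, group = _make_counts(rng, np.full(300, 100.0), np.zeros(300), 5, 5, 0.05)
        counts[0] = 80  # constant, equal in both groups
        res = nb_test(counts, group)
        assert res[0].p_value > 0.5
        assert abs(res[0].log2fc) < 0.05

    def test_all_zero_region_excluded(self, rng):
        counts, group = _make_counts(rng, np.full(50, 50.0), np.zeros(50), 3, 3, 0.1)
        counts[7] = 0
        res = nb_test(counts, group)
        assert np.isnan(res[7].p_value)
        assert res[7].direction == "none"

    def test_planted_lfc_recovered(self, rng):
        # balanced hyper/hypo planting, as in the synthetic generator —
        # one-sided planting would bias the size factors themselves
        mu = np.full(800, 200.0)
        lfc = np.zeros(800)
        signs = rng.choice([-1.0, 1.0], size=200)
        lfc[:200] = 2.0 * signs
        counts, group = _make_counts(rng, mu, lfc, 10, 5, 0.1)
        res = nb_test(counts, group)
        est = np.array([r.log2fc for r in res[:200]])
        assert abs((est * signs).mean() - 2.0) < 0.2

    def test_requires_two_samples_per_group(self, rng):
        counts = rng.poisson(50, size=(10, 3))
        with pytest.raises(ValueError):
            nb_test(counts, np.array([1, 1, 0]))

    def test_agrees_with_pydeseq2_on_strong_effects(self, rng):
        """Independent cross-check: on a fixture with clear planted effects,
        direction calls and fold-change estimates should agree with an
        established NB Wald implementation (not numerically identical —
        the dispersion machinery differs)."""
        import pandas as pd
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        mu = 2.0 ** rng.normal(7, 0.7, 300)
        lfc = np.zeros(300)
        lfc[:60] = rng.choice([-1.5, 1.5], size=60)
        counts, group = _make_counts(rng, mu, lfc, 8, 5, 0.1)
        res = nb_test(counts, group)
        ours = results_to_frame(res)

        meta = pd.DataFrame({"condition": np.where(group == 1, "B", "A")})
        dds = DeseqDataSet(
            counts=pd.DataFrame(counts.T), metadata=meta,
            design="~condition", quiet=True,
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        theirs = ds.results_df.reset_index(drop=True)

        planted = np.abs(lfc) > 0
        corr = np.corrcoef(
            ours["log2fc"], theirs["log2FoldChange"].to_numpy()
        )[0, 1]
        assert corr > 0.95
        sign_agree = np.mean(
            np.sign(ours["log2fc"].to_numpy()[planted])
            == np.sign(theirs["log2FoldChange"].to_numpy()[planted])
        )
        assert sign_agree == 1.0


class TestClassifyDars:
    def test_boundaries(self, rng):
        counts, group = _make_counts(
            rng, np.full(200, 100.0), np.r_[np.full(50, 2.0), np.zeros(150)], 8, 5, 0.1
        )
        res = nb_test(counts, group)
        hyper, hypo = classify_dars(res)
        for r in hyper:
            assert r.p_adj < 0.05 and r.log2fc > 0
        for r in hypo:
            assert r.p_adj < 0.05 and r.log2fc < 0

    def test_order_invariance(self, rng):
        counts, group = _make_counts(
            rng, np.full(100, 80.0), rng.choice([0, 1.5], 100), 6, 4, 0.1
        )
        res = nb_test(counts, group)
        hyper, hypo = classify_dars(res)
        h2, l2 = classify_dars(list(reversed(res)))
        assert {r.region_id for r in hyper} == {r.region_id for r in h2}
        assert {r.region_id for r in hypo} == {r.region_id for r in l2}


class TestNormalization:
    def test_quantile_normalize_example(self):
        mat = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out[:, 0], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.0, 4.5])

    def test_columns_identical_after_qn(self, rng):
        mat = rng.uniform(size=(50, 4))
        out = quantile_normalize(mat)
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_chain_row_medians_zero(self, rng):
        regions = []
        pos = 1000
        for i in range(40):
            regions.append(
                ConsensusRegion(
                    GenomicRegion("chr1", pos, pos + int(rng.integers(2000, 4000)), f"r{i}"),
                    frozenset({"a", "b", "c"}),
                )
            )
            pos = regions[-1].region.end + 10_000
        counts = rng.poisson(40, size=(40, 3))
        cm = CountsMatrix(
            regions, ["a", "b", "c"], {"a": "patient", "b": "patient", "c": "control"},
            counts, {"a": 100_000, "b": 120_000, "c": 90_000},
        )
        norm = normalize_for_clustering(cm)
        np.testing.assert_allclose(norm.values.median(axis=1), 0, atol=1e-12)
        assert norm.chain == [
            "rpkm", "quantile_normalize", "add_1_rpkm", "log2", "median_center",
        ]
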