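"""Expression filtering, correlations, the GSEA running score, the
expression DE test, marker panels and concordant-TF calling."""

import numpy as np
import pandas as pd
import pytest

from acetylome.annotation import GeneModel
from acetylome.integration import (
    RankedGeneList,
    concordant_tfs,
    de_test,
    expressed_filter,
    gsea_es,
    gsea_nes_fdr,
    marker_panel,
    per_sample_correlation,
)


def brute_force_es(metrics, hit_flags, weight=1.0):
    """Explicit running-sum oracle (plain Python loop)."""
    n = len(metrics)
    n_hits = sum(hit_flags)
    hit_total = sum(abs(m) ** weight for m, h in zip(metrics, hit_flags) if h)
    running = []
    acc = 0.0
    for m, h in zip(metrics, hit_flags):
        if h:
            acc += abs(m) ** weight / hit_total
        else:
            acc -= 1.0 / (n - n_hits)
        running.append(acc)
    best = max(running, key=abs)
    return best


class TestExpressedFilter:
    def test_threshold_strict(self):
        table = pd.DataFrame({"s1": [0.4, 0.6, 0.5]}, index=["a", "b", "c"])
        out = expressed_filter(table)
        assert list(out.index) == ["b"]

    def test_matches_bruteforce(self, rng):
        table = pd.DataFrame(rng.exponential(0.7, size=(100, 4)))
        out = expressed_filter(table)
        brute = [i for i in table.index if table.loc[i].mean() > 0.5]
        assert list(out.index) == brute


class TestPerSampleCorrelation:
    def test_identical_vectors(self, rng):
        sig = pd.DataFrame(rng.uniform(1, 10, size=(50, 3)),
                           index=[f"g{i}" for i in range(50)],
                           columns=["a", "b", "c"])
        corr = per_sample_correlation(sig, sig.copy())
        np.testing.assert_allclose(corr["spearman"], 1.0)
        np.testing.assert_allclose(corr["pearson"], 1.0)

    def test_independent_near_zero(self, rng):
        idx = [f"g{i}" for i in range(800)]
        a = pd.DataFrame(rng.uniform(0, 10, size=(800, 2)), index=idx, columns=["s1", "s2"])
        b = pd.DataFrame(rng.uniform(0, 10, size=(800, 2)), index=idx, columns=["s1", "s2"])
        corr = per_sample_correlation(a, b)
        assert (corr["spearman"].abs() < 0.1).all()

    def test_too_few_genes(self):
        a = pd.DataFrame({"s": [1, 2]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            per_sample_correlation(a, a)


class TestGseaEs:
    def test_top_gene_fixture(self):
        ranked = RankedGeneList(["a", "b", "c", "d"], np.array([2.0, 1.0, -1.0, -2.0]))
        es, running, hits = gsea_es(ranked, {"a"})
        assert es == pytest.approx(1.0)
        assert hits == [0]

    def test_all_genes_degenerate(self):
        ranked = RankedGeneList(["a", "b"], np.array([2.0, 1.0]))
        es, running, _ = gsea_es(ranked, {"a", "b"})
        assert es == pytest.approx(1.0)  # hit-only running sum peaks at 1

    def test_reversal_negates_symmetric_set(self):
        metrics = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ranked = RankedGeneList(list("abcdef"), metrics)
        es_top, _, _ = gsea_es(ranked, {"a"})
        ranked_rev = RankedGeneList(list("fedcba"), metrics)
        es_bottom, _, _ = gsea_es(ranked_rev, {"a"})
        assert es_top == pytest.approx(-es_bottom)

    def test_empty_intersection_raises(self):
        ranked = RankedGeneList(["a"], np.array([1.0]))
        with pytest.raises(ValueError):
            gsea_es(ranked, {"z"})

    def test_matches_bruteforce_on_random_fixtures(self, rng):
        for _ in range(50):
            n = 15
            metrics = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            ranked = RankedGeneList(genes, metrics)
            members = set(rng.choice(genes, size=4, replace=False))
            es, _, _ = gsea_es(ranked, members)
            brute = brute_force_es(ranked.metric, [g in members for g in ranked.gene_ids])
            assert es == pytest.approx(brute)


class TestGseaNesFdr:
    def test_deterministic_under_seed(self, rng):
        metrics = np.sort(rng.normal(size=100))[::-1]
        ranked = RankedGeneList([f"g{i}" for i in range(100)], metrics)
        sets = {"s": set(ranked.gene_ids[:8])}
        a = gsea_nes_fdr(ranked, sets, n_permutations=100, seed=9)
        b = gsea_nes_fdr(ranked, sets, n_permutations=100, seed=9)
        assert a[0].nes == b[0].nes and a[0].fdr == b[0].fdr

    def test_nes_sign_matches_es(self, rng):
        metrics = np.sort(rng.normal(size=100))[::-1]
        ranked = RankedGeneList([f"g{i}" for i in range(100)], metrics)
        sets = {"top": set(ranked.gene_ids[:8]), "bottom": set(ranked.gene_ids[-8:])}
        for r in gsea_nes_fdr(ranked, sets, n_permutations=100, seed=2):
            assert np.sign(r.nes) == np.sign(r.es)

    def test_random_sets_fdr_not_concentrated_low(self, rng):
        """Random gene sets on a random ranking should not pile up at small
        FDR values (null calibration of the permutation FDR)."""
        metrics = np.sort(rng.normal(size=200))[::-1]
        genes = [f"g{i}" for i in range(200)]
        ranked = RankedGeneList(genes, metrics)
        fdrs = []
        for k in range(20):
            sets = {"rand": set(rng.choice(genes, size=15, replace=False))}
            res = gsea_nes_fdr(ranked, sets, n_permutations=100, seed=k)
            fdrs.append(res[0].fdr)
        assert np.median(fdrs) > 0.25


class TestDeTest:
    def test_planted_gene_up(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 10)),
            index=[f"g{i}" for i in range(50)],
        )
        counts.iloc[0, :5] = rng.poisson(400, size=5)
        groups = np.array(["patient"] * 5 + ["control"] * 5)
        out = de_test(counts, groups)
        assert out.loc["g0", "de_direction"] == "up"

    def test_all_zero_gene_excluded(self, rng):
        counts = pd.DataFrame(
            rng.poisson(60, size=(20, 8)), index=[f"g{i}" for i in range(20)]
        )
        counts.iloc[3] = 0
        out = de_test(counts, np.array(["patient"] * 4 + ["control"] * 4))
        assert "g3" not in out.index


def _marker_setup(rng):
    genes = [
        GeneModel(f"g{i}", f"G{i}", "chr1", "+", 10_000 + i * 50_000,
                  10_000 + i * 50_000, 15_000 + i * 50_000)
        for i in range(6)
    ]
    samples = ["p1", "p2", "c1", "c2"]
    groups = dict(zip(samples, ["patient", "patient", "control", "control"]))
    promoter = pd.DataFrame(
        rng.uniform(1, 5, size=(6, 4)), index=[g.gene_id for g in genes], columns=samples
    )
    expression = pd.DataFrame(
        rng.uniform(1, 5, size=(6, 4)), index=[g.gene_id for g in genes], columns=samples
    )
    markers = pd.DataFrame(
        {"cell_type": ["ct1"] * 3 + ["ct2"] * 3, "gene_id": [g.gene_id for g in genes]}
    )
    dars = pd.DataFrame(
        {"chrom": ["chr1"], "start": [8_000], "end": [9_500], "direction": ["hyper"]}
    )
    de = pd.DataFrame(
        {
            "log2fc": rng.normal(size=6),
            "p_value": rng.uniform(size=6),
            "de": [True, False] * 3,
            "de_direction": ["up", "none"] * 3,
        },
        index=[g.gene_id for g in genes],
    )
    return genes, samples, groups, promoter, expression, markers, dars, de


class TestMarkerPanel:
    def test_group_means_reconcile(self, rng):
        genes, samples, groups, promoter, expression, markers, dars, de = _marker_setup(rng)
        panels = marker_panel(markers, genes, promoter, expression, groups, dars, de)
        for panel in panels:
            for m in panel.markers:
                weighted = (2 * m.promoter_acetylation["patient"]
                            + 2 * m.promoter_acetylation["control"]) / 4
                assert m.promoter_acetylation["all"] == pytest.approx(weighted, abs=1e-12)

    def test_upstream_dar_flag(self, rng):
        genes, samples, groups, promoter, expression, markers, dars, de = _marker_setup(rng)
        panels = marker_panel(markers, genes, promoter, expression, groups, dars, de)
        records = {m.gene_id: m for p in panels for m in p.markers}
        # g0 TSS 10,000 (+): upstream window [7500, 10000) overlaps DAR [8000,9500)
        assert records["g0"].dar_flag and records["g0"].dar_direction == "hyper"
        assert not records["g1"].dar_flag

    def test_missing_marker_skipped(self, rng):
        genes, samples, groups, promoter, expression, markers, dars, de = _marker_setup(rng)
        markers = pd.concat(
            [markers, pd.DataFrame({"cell_type": ["ct3"], "gene_id": ["absent"]})]
        )
        panels = marker_panel(markers, genes, promoter, expression, groups, dars, de)
        ct3 = [p for p in panels if p.cell_type == "ct3"][0]
        assert ct3.markers == []


class TestConcordantTfs:
    def make_de(self, up, down):
        genes = sorted(up | down | {"x1", "x2"})
        return pd.DataFrame(
            {
                "de_direction": [
                    "up" if g in up else "down" if g in down else "none" for g in genes
                ]
            },
            index=genes,
        )

    def test_intersection(self):
        de = self.make_de({"B", "C"}, {"E"})
        out = concordant_tfs(
            {"exclusive_hyper": {"A", "B"}, "exclusive_hypo": {"E", "F"}, "shared": set()},
            de,
        )
        assert out["concordant_hyper"] == {"B"}
        assert out["concordant_hypo"] == {"E"}

    def test_shared_counts_on_both_sides(self):
        de = self.make_de({"S"}, {"S2"})
        out = concordant_tfs(
            {"exclusive_hyper": set(), "exclusive_hypo": set(), "shared": {"S", "S2"}},
            de,
        )
        assert out["concordant_hyper"] == {"S"}
        assert out["concordant_hypo"] == {"S2"}

    def test_external_gene_set_restriction(self):
        de = self.make_de({"A", "B"}, set())
        out = concordant_tfs(
            {"exclusive_hyper": {"A", "B"}, "exclusive_hypo": set(), "shared": set()},
            de,
            external_gene_set={"B"},
        )
        assert out["concordant_hyper_external"] == {"B"}
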