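"""The synthetic-data generator: determinism, planted structure and the
statistical properties the downstream analyses rely on."""

import numpy as np
import pytest

from acetylome.differential import rpkm
from acetylome.synthetic import (
    SimulationConfig,
    calibrate_noise_sd,
    child_rng,
    simulate_counts,
    simulate_genes_and_expression,
    simulate_regions,
    simulate_sequences_and_motifs,
)


def small_config(**kw):
    defaults = dict(
        n_chromosomes=2,
        chrom_length=120_000_000,
        n_regions=200,
        n_samples_case=6,
        n_samples_control=4,
        n_genes=50,
        seed=11,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_regions=0)

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            small_config(dar_fraction=1.5)

    def test_overdense_rejected(self):
        with pytest.raises(ValueError):
            small_config(chrom_length=1_000_000, n_regions=500)

    def test_motif_longer_than_sequence(self):
        with pytest.raises(ValueError):
            small_config(motif_length=600, sequence_length=500)


class TestSimulateRegions:
    def test_deterministic(self):
        cfg = small_config()
        r1, t1 = simulate_regions(cfg)
        r2, t2 = simulate_regions(cfg)
        assert r1 == r2
        assert t1.region_direction == t2.region_direction

    def test_sorted_nonoverlapping_min_gap(self):
        regions, _ = simulate_regions(small_config())
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for regs in by_chrom.values():
            for a, b in zip(regs, regs[1:]):
                assert b.start - a.end >= 5_000

    def test_absorbing_chain_single_direction_per_chromosome(self):
        cfg = small_config(dar_fraction=1.0, direction_persistence=1.0)
        regions, truth = simulate_regions(cfg)
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, set()).add(truth.region_direction[r.id])
        for dirs in by_chrom.values():
            assert len(dirs) == 1

    def test_both_distance_classes_occur(self):
        regions, _ = simulate_regions(small_config(n_regions=400))
        gaps = []
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for regs in by_chrom.values():
            gaps += [b.midpoint - a.midpoint for a, b in zip(regs, regs[1:])]
        gaps = np.array(gaps)
        assert ((gaps >= 5_000) & (gaps <= 100_000)).any()
        assert ((gaps > 100_000) & (gaps <= 1_000_000)).any()

    def test_persistence_pair_statistic(self):
        """With rho = 0.5, consecutive planted DARs share direction half the
        time; the chain statistic is recoverable to +/-0.03 at 10,000 DARs."""
        for rho, tol in ((0.5, 0.02), (0.8, 0.03)):
            cfg = SimulationConfig(
                n_chromosomes=10, chrom_length=600_000_000, n_regions=10_500,
                dar_fraction=1.0, direction_persistence=rho, n_genes=10, seed=3,
            )
            regions, truth = simulate_regions(cfg)
            same = total = 0
            by_chrom = {}
            for r in regions:
                by_chrom.setdefault(r.chrom, []).append(r)
            for regs in by_chrom.values():
                dirs = [truth.region_direction[r.id] for r in regs]
                dirs = [d for d in dirs if d != "null"]
                same += sum(a == b for a, b in zip(dirs, dirs[1:]))
                total += len(dirs) - 1
            assert same / total == pytest.approx(rho, abs=tol)


class TestSimulateCounts:
    def test_poisson_degenerate_at_zero_dispersion(self):
        cfg = small_config(dispersion=0.0, dar_fraction=0.0, n_regions=300,
                           baseline_log_sd=0.0, baseline_log_mean=6.0)
        regions, truth = simulate_regions(cfg)
        cm = simulate_counts(regions, truth, cfg)
        # per sample, counts ~ Poisson(64 * s_j): variance/mean ratio ~ 1
        for j in range(cm.counts.shape[1]):
            col = cm.counts[:, j]
            ratio = col.var() / col.mean()
            assert ratio == pytest.approx(1.0, abs=4 * np.sqrt(2 / len(col)))

    def test_nb_moments(self):
        cfg = SimulationConfig(
            n_chromosomes=4, chrom_length=400_000_000, n_regions=10_000,
            n_samples_case=2, n_samples_control=2, dar_fraction=0.0,
            baseline_log_mean=6.0, baseline_log_sd=0.0, dispersion=0.2, seed=5,
            n_genes=10,
        )
        regions, truth = simulate_regions(cfg)
        cm = simulate_counts(regions, truth, cfg)
        sf = cm.counts.mean(axis=0) / 64.0  # recovers the drawn size factors
        q = cm.counts / sf[None, :]
        mu = 64.0
        for j in range(4):
            var = q[:, j].var()
            expected_var = mu / sf[j] + 0.2 * mu**2
            se = expected_var * np.sqrt(2 / len(q))  # rough SE of a variance
            assert abs(var - expected_var) < 4 * se

    def test_planted_fourfold_effect(self):
        cfg = SimulationConfig(
            n_chromosomes=2, chrom_length=200_000_000, n_regions=1_000,
            n_samples_case=10, n_samples_control=10, dar_fraction=0.5,
            direction_persistence=0.5, planted_lfc=2.0, baseline_log_sd=0.0,
            baseline_log_mean=7.0, dispersion=0.05, seed=8, n_genes=10,
        )
        regions, truth = simulate_regions(cfg)
        cm = simulate_counts(regions, truth, cfg)
        hyper = np.array([truth.region_direction[r.id] == "hyper" for r in regions])
        null = np.array([truth.region_direction[r.id] == "null" for r in regions])
        # null regions recover each sample's size factor; normalize with them
        sf = cm.counts[null].mean(axis=0) / 128.0
        q = cm.counts / sf[None, :]
        ratio = q[hyper, :10].mean() / q[hyper, 10:].mean()
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_all_zero_mu_row(self):
        cfg = small_config(dispersion=0.0)
        regions, truth = simulate_regions(cfg)
        cm = simulate_counts(regions, truth, cfg)
        assert (cm.counts >= 0).all()


class TestGenesAndExpression:
    def _setup(self, **kw):
        cfg = small_config(**kw)
        regions, truth = simulate_regions(cfg)
        cm = simulate_counts(regions, truth, cfg)
        genes, expr_rpkm, expr_counts = simulate_genes_and_expression(
            regions, truth, cfg, cm
        )
        return cfg, regions, truth, cm, genes, expr_rpkm

    def test_tss_inside_driving_region(self):
        cfg, regions, truth, cm, genes, _ = self._setup()
        by_id = {r.id: r for r in regions}
        for g in genes:
            driver = by_id[truth.gene_to_region[g.gene_id]]
            assert driver.start <= g.tss < driver.end
            assert g.chrom == driver.chrom

    def test_noiseless_linkage_perfect_spearman(self):
        from scipy import stats

        cfg, regions, truth, cm, genes, expr = self._setup(
            promoter_link_noise_sd=0.0, n_genes=40
        )
        lib = np.array([cm.library_size[s] for s in cm.samples], float)
        by_id = {r.id: i for i, r in enumerate(regions)}
        acet = rpkm(cm.counts, cm.region_lengths, lib)
        j = 0  # first sample
        x = np.array([acet[by_id[truth.gene_to_region[g.gene_id]], j] for g in genes])
        y = expr.iloc[:, j].to_numpy()
        assert stats.spearmanr(x, y).statistic == pytest.approx(1.0)

    def test_zero_slope_no_correlation(self):
        from scipy import stats

        cfg, regions, truth, cm, genes, expr = self._setup(
            promoter_link_slope=0.0, promoter_link_noise_sd=1.0, n_genes=50
        )
        lib = np.array([cm.library_size[s] for s in cm.samples], float)
        by_id = {r.id: i for i, r in enumerate(regions)}
        acet = rpkm(cm.counts, cm.region_lengths, lib)
        x = np.array([acet[by_id[truth.gene_to_region[g.gene_id]], 0] for g in genes])
        y = expr.iloc[:, 0].to_numpy()
        assert abs(stats.spearmanr(x, y).statistic) < 0.35  # ~N(0, 1/sqrt(50))

    def test_calibrate_noise_sd(self, rng):
        x = rng.normal(0, 2.0, 5000)
        sd = calibrate_noise_sd(x, 0.6)
        y = x + rng.normal(0, sd, 5000)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.6, abs=0.03)


class TestSequencesAndMotifs:
    def test_plant_rate_zero(self):
        cfg = small_config(motif_plant_rate=0.0)
        regions, truth = simulate_regions(cfg)
        simulate_sequences_and_motifs(regions, truth, cfg)
        assert not any(truth.motif_planted.values())

    def test_plant_rate_one_consensus_present(self):
        cfg = small_config(motif_plant_rate=1.0, dar_fraction=0.5)
        regions, truth = simulate_regions(cfg)
        sequences, pwms, _ = simulate_sequences_and_motifs(regions, truth, cfg)
        consensus = pwms[0].consensus
        for r in regions:
            if truth.region_direction[r.id] == "hyper":
                assert consensus in sequences[r.id]
                assert truth.motif_planted[r.id]

    def test_plant_count_binomial_range(self):
        cfg = SimulationConfig(
            n_chromosomes=2, chrom_length=200_000_000, n_regions=400,
            dar_fraction=1.0, direction_persistence=0.0, motif_plant_rate=0.6,
            seed=2, n_genes=10,
        )
        regions, truth = simulate_regions(cfg)
        simulate_sequences_and_motifs(regions, truth, cfg)
        n_hyper = sum(d == "hyper" for d in truth.region_direction.values())
        planted = sum(truth.motif_planted.values())
        # 99% binomial band at p = 0.6
        lo, hi = 0.6 * n_hyper - 2.6 * np.sqrt(n_hyper * 0.24), 0.6 * n_hyper + 2.6 * np.sqrt(n_hyper * 0.24)
        assert lo <= planted <= hi

    def test_sequences_uppercase_keyed_by_region(self):
        cfg = small_config()
        regions, truth = simulate_regions(cfg)
        sequences, _, _ = simulate_sequences_and_motifs(regions, truth, cfg)
        assert set(sequences) == {r.id for r in regions}
        assert all(s == s.upper() for s in sequences.values())


class TestChildRng:
    def test_streams_independent_and_stable(self):
        a1 = child_rng(7, "counts").integers(0, 1_000_000, 5)
        a2 = child_rng(7, "counts").integers(0, 1_000_000, 5)
        b = child_rng(7, "regions").integers(0, 1_000_000, 5)
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, b)
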