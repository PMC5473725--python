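"""Synthetic-data generator: genotype model, traits, summary statistics and
the benchmark fixture."""

import filecmp
import math

import numpy as np
import pytest
from scipy import stats

from methylsmr import (SimScenario, make_benchmark, read_gwas,
                       simulate_genotypes, simulate_locus_study,
                       simulate_traits, summary_stats, write_benchmark,
                       write_gwas)
from methylsmr.simulate import (BenchmarkConfig, GenotypeSample,
                                dosage_corr_from_latent)


class TestGenotypes:
    def test_maf_bounds_enforced(self, rng):
        sc = SimScenario(n_snps=4, maf=np.array([0.01, 0.3, 0.3, 0.3]))
        with pytest.raises(ValueError, match="maf"):
            simulate_genotypes(sc, 100, rng)

    def test_column_means_track_maf(self, rng):
        maf = np.array([0.1, 0.25, 0.4, 0.5])
        sc = SimScenario(n_snps=4, maf=maf, ld_rho=0.5)
        g = simulate_genotypes(sc, 5000, rng, maf=maf)
        for j in range(4):
            se = math.sqrt(2 * maf[j] * (1 - maf[j]) / 5000)
            assert abs(g.dosages[:, j].mean() - 2 * maf[j]) < 3 * se

    def test_zero_rho_gives_independent_snps(self, rng):
        sc = SimScenario(kind="null", n_snps=8, ld_rho=0.0,
                         maf=np.full(8, 0.3))
        g = simulate_genotypes(sc, 5000, rng, maf=np.full(8, 0.3))
        r = np.corrcoef(g.dosages, rowvar=False)
        adj = np.abs(np.diag(r, 1))
        assert adj.mean() < 0.05

    def test_realized_ld_matches_tetrachoric_prediction(self, rng):
        """At latent rho = 0.9 the realized dosage correlations follow the
        thresholded-Gaussian forward map (large-sample check)."""
        maf = np.array([0.3, 0.2, 0.45, 0.1, 0.35, 0.25, 0.5, 0.15, 0.4, 0.3])
        sc = SimScenario(kind="null", n_snps=10, ld_rho=0.9, maf=maf)
        g = simulate_genotypes(sc, 50_000, rng, maf=maf)
        realized = np.corrcoef(g.dosages, rowvar=False)
        for i in range(10):
            for j in range(i + 1, 10):
                pred = dosage_corr_from_latent(0.9 ** (j - i), maf[i], maf[j])
                assert abs(realized[i, j] - pred) < 0.1

    def test_linkage_realizes_target_causal_ld(self, rng):
        for target in (0.3, 0.6, 0.9):
            sc = SimScenario(kind="linkage", causal_r=target, n_snps=8,
                             maf=np.full(8, 0.3))
            g = simulate_genotypes(sc, 20_000, rng, maf=np.full(8, 0.3))
            c = sc.causal_index
            r = np.corrcoef(g.dosages[:, c], g.dosages[:, c + 1])[0, 1]
            assert abs(r - target) < 0.05

    def test_perfect_ld_duplicates_causal_column(self, rng):
        sc = SimScenario(kind="linkage", causal_r=1.0, n_snps=6,
                         maf=np.full(6, 0.3))
        g = simulate_genotypes(sc, 500, rng, maf=np.full(6, 0.3))
        c = sc.causal_index
        np.testing.assert_array_equal(g.dosages[:, c], g.dosages[:, c + 1])


class TestTraits:
    def _samples(self, sc, rng, n1=2000, n2=2000):
        maf = np.full(sc.n_snps, 0.3)
        a = simulate_genotypes(sc, n1, rng, maf=maf, id_prefix="q")
        b = simulate_genotypes(sc, n2, rng, maf=maf, id_prefix="g")
        return a, b

    def test_disjoint_samples_required(self, rng):
        sc = SimScenario(n_snps=4, maf=np.full(4, 0.3))
        a, _ = self._samples(sc, rng)
        with pytest.raises(ValueError, match="sample_overlap"):
            simulate_traits(a, a, sc, rng)

    def test_zero_qtl_effect_gives_flat_regression(self, rng):
        sc = SimScenario(kind="null", b_zx=0.0, n_snps=4,
                         maf=np.full(4, 0.3))
        a, b = self._samples(sc, rng)
        m, _ = simulate_traits(a, b, sc, rng)
        slope = np.polyfit(a.dosages[:, sc.causal_index], m, 1)[0]
        se = 1.0 / math.sqrt(2000 * a.dosages[:, sc.causal_index].var())
        assert abs(slope) < 3 * se

    def test_noiseless_pleiotropy_has_constant_wald_ratio(self, rng):
        """With no residual noise and shared genotypes, b_gwas/b_qtl is
        exactly the mediated effect at every SNP correlated with the causal
        variant: the single-causal-variant signature HEIDI looks for."""
        sc = SimScenario(kind="pleiotropy", sd_m=0.0, sd_y=0.0,
                         n_snps=6, maf=np.full(6, 0.3), b_zx=0.5, b_xy=0.4)
        a, _ = self._samples(sc, rng)
        twin = GenotypeSample([f"t{i}" for i in range(a.n)], a.dosages,
                              a.snp_ids, a.chrom, a.positions,
                              a.effect_alleles, a.other_alleles)
        m, y = simulate_traits(a, twin, sc, rng)
        mq = summary_stats(a, m)
        gy = summary_stats(twin, y)
        for q, g in zip(mq, gy):
            if abs(q.beta) > 1e-8:
                assert g.beta / q.beta == pytest.approx(0.4, rel=1e-9)

    def test_ols_recovers_causal_effect(self, rng):
        sc = SimScenario(kind="pleiotropy", b_zx=0.5, b_xy=0.3, n_snps=6,
                         maf=np.full(6, 0.3), n_qtl=10_000)
        a, b = self._samples(sc, rng, n1=10_000)
        m, _ = simulate_traits(a, b, sc, rng)
        recs = summary_stats(a, m)
        causal = recs[sc.causal_index]
        assert abs(causal.beta - 0.5) < 3 * causal.se


class TestSummaryStats:
    def test_exact_linear_trait_hits_p_floor(self, rng):
        sc = SimScenario(kind="null", n_snps=4, maf=np.full(4, 0.3),
                         ld_rho=0.3)
        g = simulate_genotypes(sc, 200, rng, maf=np.full(4, 0.3))
        y = 2.0 * g.dosages[:, 2]
        recs = summary_stats(g, y)
        rec = [r for r in recs if r.snp_id == g.snp_ids[2]][0]
        assert rec.beta == pytest.approx(2.0, rel=1e-9)
        assert rec.p == 5e-324  # underflow-guarded minimum

    def test_monomorphic_snp_omitted(self, rng):
        sc = SimScenario(kind="null", n_snps=3, maf=np.full(3, 0.3))
        g = simulate_genotypes(sc, 100, rng, maf=np.full(3, 0.3))
        g.dosages[:, 0] = 1.0
        recs = summary_stats(g, rng.standard_normal(100))
        assert len(recs) == 2

    def test_permuted_trait_p_values_uniform(self, rng):
        """Null p-values across independent SNPs pass a KS uniformity
        check (no genomic inflation)."""
        sc = SimScenario(kind="null", n_snps=300, ld_rho=0.0,
                         maf=np.full(300, 0.3))
        g = simulate_genotypes(sc, 2000, rng, maf=np.full(300, 0.3))
        y = rng.permutation(g.dosages[:, 0] + rng.standard_normal(2000))
        ps = np.array([r.p for r in summary_stats(g, y)])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_output_round_trips_through_reader(self, tmp_path, rng):
        sc = SimScenario(kind="null", n_snps=6, maf=np.full(6, 0.3))
        g = simulate_genotypes(sc, 500, rng, maf=np.full(6, 0.3))
        recs = summary_stats(g, rng.standard_normal(500))
        path = tmp_path / "sim.ma"
        write_gwas(recs, path)
        back = read_gwas(path)
        assert back.n_skipped == 0 and len(back) == len(recs)


class TestBenchmark:
    def test_truth_table_covers_all_probe_trait_pairs(self, bench):
        probes = {p.probe_id for p in bench.qtl}
        traits = set(bench.gwas)
        assert len(bench.truth) == len(probes) * len(traits)
        assert set(bench.truth["probe_id"]) == probes

    def test_fixture_set_is_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = BenchmarkConfig(n_probes=6, n_traits=2, n_gwas=1000,
                              n_qtl=400, n_qtl2=400, seed=5)
        p1 = write_benchmark(make_benchmark(cfg), tmp_path / "a")
        p2 = write_benchmark(make_benchmark(cfg), tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_cross_tissue_qtl_sign_concordance(self, bench):
        """At probes where the two tissues share the causal variant, the
        top tissue-1 mQTL effect has the same sign in tissue 2."""
        shared = set(bench.truth.loc[bench.truth["shared_causal"],
                                     "probe_id"])
        t2 = {p.probe_id: p for p in bench.qtl2}
        n = same = 0
        for probe in bench.qtl:
            if probe.probe_id not in shared:
                continue
            top = min(probe.records, key=lambda r: r.p)
            other = t2[probe.probe_id].get(top.snp_id)
            if other is None:
                continue
            n += 1
            same += (top.beta > 0) == (other.beta > 0)
        assert n > 20 and same / n > 0.95

    def test_locus_study_is_reproducible(self):
        a = simulate_locus_study(SimScenario(seed=42, n_gwas=1000))
        b = simulate_locus_study(SimScenario(seed=42, n_gwas=1000))
        assert [r.beta for r in a.qtl.records] == \
               [r.beta for r in b.qtl.records]
        assert [r.p for r in a.gwas] == [r.p for r in b.gwas]
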