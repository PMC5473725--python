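"""I/O, validation, allele harmonization and LD reference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylsmr import (LDReference, VariantAssoc, harmonize, ld_correlation,
                       read_gwas, read_qtl, write_gwas, write_qtl)
from methylsmr.sumstats import ProbeCisSet, SummaryStatsError, wald_p


def _ma(tmp_path, rows, header="SNP A1 A2 freq b se p n"):
    path = tmp_path / "test.ma"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def _var(**kw):
    base = dict(snp_id="rs1", effect_allele="A", other_allele="G",
                eaf=0.3, beta=0.1, se=0.05, p=wald_p(0.1, 0.05), n=100.0)
    base.update(kw)
    return VariantAssoc(**base)


class TestReadGwas:
    def test_well_formed_file_read_verbatim(self, tmp_path):
        path = _ma(tmp_path, ["rs1 A G 0.3 0.1 0.05 0.0455 100",
                              "rs2 T C 0.5 -0.2 0.1 0.0455 100",
                              "rs3 C A 0.1 0.0 0.1 1.0 100"])
        recs = read_gwas(path)
        assert len(recs) == 3 and recs.n_skipped == 0
        assert recs[0].snp_id == "rs1" and recs[0].effect_allele == "A"
        assert recs[1].beta == -0.2 and recs[2].p == 1.0

    def test_invalid_rows_skipped_and_counted(self, tmp_path):
        path = _ma(tmp_path, ["rs1 A G 0.3 0.1 0.0 0.5 100",   # se = 0
                              "rs2 T C 0.5 -0.2 0.1 0.0455 100"])
        recs = read_gwas(path)
        assert len(recs) == 1 and recs.n_skipped == 1

    def test_inconsistent_p_flagged_not_dropped(self, tmp_path):
        # beta/se = 3 implies Wald p ~ 2.7e-3; stored p = 2e-300 is kept
        # but flagged
        path = _ma(tmp_path, ["rs1 A G 0.3 0.3 0.1 2e-300 100"])
        recs = read_gwas(path)
        assert len(recs) == 1 and recs.n_flagged == 1
        assert recs[0].p_inconsistent
        p_wald = wald_p(0.3, 0.1)
        assert not (p_wald / 10 <= 2e-300 <= p_wald * 10)

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        path = _ma(tmp_path, ["rs1 A 0.3 0.1 0.05 0.05 100"],
                   header="SNP A1 freq b se p n")
        with pytest.raises(SummaryStatsError, match="mandatory"):
            read_gwas(path)


QTL_HEADER = ("probe\tprobe_chr\tprobe_bp\tgene\tSNP\tchr\tbp\t"
              "A1\tA2\tfreq\tb\tse\tp")


def _qtl_file(tmp_path, rows):
    path = tmp_path / "qtl.tsv"
    path.write_text("\n".join([QTL_HEADER] + rows) + "\n")
    return path


def _qtl_row(probe="cg1", probe_bp=1_000_000, snp="rs1", bp=1_000_500,
             b=0.5, se=0.05):
    p = wald_p(b, se)
    return (f"{probe}\t1\t{probe_bp}\tGENE1\t{snp}\t1\t{bp}\t"
            f"A\tG\t0.3\t{b}\t{se}\t{p:.6g}")


class TestReadQtl:
    def test_long_format_grouped_by_probe(self, tmp_path):
        rows = [_qtl_row(probe=p, snp=f"rs{i}", bp=1_000_000 + i * 100)
                for p in ("cg1", "cg2") for i in range(5)]
        probes = read_qtl(_qtl_file(tmp_path, rows))
        assert [p.probe_id for p in probes] == ["cg1", "cg2"]
        assert all(len(p) == 5 for p in probes)
        assert probes[0].gene_annotation == "GENE1"

    def test_duplicate_probe_snp_pair_is_hard_error(self, tmp_path):
        rows = [_qtl_row(), _qtl_row()]
        with pytest.raises(SummaryStatsError, match="cg1.*rs1"):
            read_qtl(_qtl_file(tmp_path, rows))

    def test_snp_outside_cis_window_excluded(self, tmp_path):
        rows = [_qtl_row(snp="rs_near", bp=1_000_000 + 400_000),
                _qtl_row(snp="rs_far", bp=1_000_000 + 600_000),
                _qtl_row(snp="rs_edge", bp=1_000_000 + 500_000)]
        probes = read_qtl(_qtl_file(tmp_path, rows), cis_window=500_000)
        ids = [r.snp_id for r in probes[0].records]
        # 600 kb > 500 kb excluded; the window is inclusive at the boundary
        assert ids == ["rs_near", "rs_edge"]


class TestRoundTrip:
    def test_gwas_write_read_identity(self, tmp_path, bench):
        recs = list(bench.gwas["trait1"])[:50]
        path = tmp_path / "rt.ma"
        write_gwas(recs, path)
        back = read_gwas(path)
        assert back.n_skipped == 0 and len(back) == len(recs)
        for a, b in zip(recs, back):
            assert (a.snp_id, a.effect_allele, a.other_allele) == \
                   (b.snp_id, b.effect_allele, b.other_allele)
            assert math.isclose(a.beta, b.beta, abs_tol=1e-12)
            assert math.isclose(a.se, b.se, abs_tol=1e-12)
            assert math.isclose(a.p, b.p, rel_tol=1e-12)

    def test_qtl_write_read_identity(self, tmp_path, bench):
        probes = bench.qtl[:2]
        path = tmp_path / "rt_qtl.tsv"
        write_qtl(probes, path)
        back = read_qtl(path)
        assert len(back) == 2
        for orig, rb in zip(sorted(probes, key=lambda p: p.probe_id), back):
            assert rb.probe_id == orig.probe_id
            assert len(rb) == len(orig)
            for a, b in zip(orig.records, rb.records):
                assert a.snp_id == b.snp_id
                assert math.isclose(a.beta, b.beta, abs_tol=1e-12)


class TestHarmonize:
    def test_swapped_alleles_negate_beta_and_complement_eaf(self):
        a = _var(effect_allele="A", other_allele="G", beta=0.1)
        b = _var(effect_allele="G", other_allele="A", beta=0.2, eaf=0.3)
        h = harmonize(a, b)
        assert h.ok and h.flipped
        assert h.b.effect_allele == "A" and h.b.other_allele == "G"
        assert h.b.beta == -0.2 and h.b.eaf == 0.7

    def test_strand_complement_resolved(self):
        a = _var(effect_allele="A", other_allele="G")
        b = _var(effect_allele="T", other_allele="C", beta=0.2)
        h = harmonize(a, b)
        assert h.ok and not h.flipped and h.b.beta == 0.2
        # complement + swap
        b2 = _var(effect_allele="C", other_allele="T", beta=0.2, eaf=0.3)
        h2 = harmonize(a, b2)
        assert h2.ok and h2.flipped and h2.b.beta == -0.2

    def test_irreconcilable_alleles_excluded(self):
        a = _var(effect_allele="A", other_allele="G")
        b = _var(effect_allele="A", other_allele="C")
        h = harmonize(a, b)
        assert not h.ok and h.reason == "allele_mismatch"

    def test_palindrome_at_half_frequency_ambiguous(self):
        a = _var(effect_allele="A", other_allele="T", eaf=0.50)
        b = _var(effect_allele="A", other_allele="T", eaf=0.50)
        h = harmonize(a, b)
        assert not h.ok and h.reason == "ambiguous_palindrome"

    def test_palindrome_resolved_by_clear_frequency(self):
        a = _var(effect_allele="A", other_allele="T", eaf=0.1)
        b = _var(effect_allele="A", other_allele="T", eaf=0.12, beta=0.2)
        h = harmonize(a, b)
        assert h.ok and h.b.beta == 0.2
        # opposite frequency side implies the other strand orientation
        b2 = _var(effect_allele="A", other_allele="T", eaf=0.88, beta=0.2)
        h2 = harmonize(a, b2)
        assert h2.ok and h2.b.beta == -0.2 and math.isclose(h2.b.eaf, 0.12)

    def test_palindrome_missing_eaf_dropped(self):
        a = _var(effect_allele="C", other_allele="G", eaf=0.1)
        b = _var(effect_allele="C", other_allele="G", eaf=None)
        assert harmonize(a, b).reason == "ambiguous_palindrome"

    @given(beta=st.floats(-2, 2, allow_nan=False),
           eaf=st.floats(0.01, 0.99),
           swap=st.booleans())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_involution(self, beta, eaf, swap):
        """Harmonizing an already-harmonized record changes nothing."""
        a = _var(effect_allele="A", other_allele="G", beta=0.1, eaf=0.3)
        alleles = ("G", "A") if swap else ("A", "G")
        b = _var(effect_allele=alleles[0], other_allele=alleles[1],
                 beta=beta, eaf=eaf)
        h1 = harmonize(a, b)
        assert h1.ok
        h2 = harmonize(a, h1.b)
        assert h2.ok
        assert h2.b.beta == h1.b.beta and h2.b.eaf == h1.b.eaf
        assert h2.b.effect_allele == h1.b.effect_allele


class TestLDReference:
    def _ref(self, cols, ids=None, eas=None, oas=None):
        cols = np.asarray(cols, dtype=float)
        ids = ids or [f"s{i}" for i in range(cols.shape[1])]
        return LDReference(ids, cols, eas, oas)

    def test_identical_columns_r_one(self):
        x = [0, 1, 2, 1, 0, 2]
        ref = self._ref(np.column_stack([x, x]))
        assert ld_correlation(ref, "s0", "s1") == pytest.approx(1.0)

    def test_allele_recode_negates_r(self):
        x = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        y = np.array([0, 1, 2, 2, 1, 2], dtype=float)
        r = ld_correlation(self._ref(np.column_stack([x, y])), "s0", "s1")
        r_flip = ld_correlation(self._ref(np.column_stack([x, 2 - y])),
                                "s0", "s1")
        assert r_flip == pytest.approx(-r, abs=1e-12)

    def test_hand_computed_pearson(self):
        x = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        y = np.array([1, 1, 2, 0, 0, 2], dtype=float)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        ref = self._ref(np.column_stack([x, y]))
        assert ld_correlation(ref, "s0", "s1") == pytest.approx(expected,
                                                                rel=1e-12)

    def test_symmetry_and_row_order_invariance(self, rng):
        d = rng.integers(0, 3, size=(30, 2)).astype(float)
        ref = self._ref(d)
        r_ij = ld_correlation(ref, "s0", "s1")
        assert ld_correlation(ref, "s1", "s0") == r_ij
        perm = rng.permutation(30)
        ref_p = self._ref(d[perm])
        assert ld_correlation(ref_p, "s0", "s1") == pytest.approx(r_ij,
                                                                  abs=1e-12)

    def test_monomorphic_snp_errors(self):
        ref = self._ref(np.column_stack([[1, 1, 1, 1], [0, 1, 2, 1]]))
        with pytest.raises(ValueError, match="monomorphic"):
            ld_correlation(ref, "s0", "s1")

    def test_missing_dosages_use_complete_pairs(self):
        x = np.array([0, 1, 2, 1, np.nan, 2])
        y = np.array([0, 1, 2, 2, 1, np.nan])
        ref = self._ref(np.column_stack([x, y]))
        mask = ~(np.isnan(x) | np.isnan(y))
        expected = np.corrcoef(x[mask], y[mask])[0, 1]
        assert ld_correlation(ref, "s0", "s1") == pytest.approx(expected)

    def test_dosage_file_round_trip(self, tmp_path):
        d = np.array([[0, 1], [2, 1], [1, 0]], dtype=float)
        ref = LDReference(["rs1", "rs2"], d, ["A", "T"], ["G", "C"])
        path = tmp_path / "ld.tsv"
        ref.write_dosage_file(path)
        back = LDReference.from_dosage_file(path)
        assert back.snp_ids == ["rs1", "rs2"]
        assert back.effect_alleles == ["A", "T"]
        np.testing.assert_allclose(back.dosages, d)

    def test_orientation_tracks_counted_allele(self):
        d = np.array([[0, 1], [2, 1], [1, 0]], dtype=float)
        ref = LDReference(["rs1", "rs2"], d, ["A", "T"], ["G", "C"])
        assert ref.orientation("rs1", "A") == 1
        assert ref.orientation("rs1", "G") == -1
        assert ref.orientation("rs1", "T") == 1  # strand complement of A


class TestVcfReference:
    VCF = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\t./.
"""

    def test_gt_counts_alt_allele(self, tmp_path):
        path = tmp_path / "panel.vcf"
        path.write_text(self.VCF)
        ref = LDReference.from_vcf(path)
        assert ref.snp_ids == ["rs1", "rs2"]
        assert ref.effect_alleles == ["A", "T"]  # ALT is counted
        np.testing.assert_allclose(ref.dosages[:, 0], [0, 1, 2, 1])
        assert np.isnan(ref.dosages[3, 1])


class TestConfig:
    def test_yaml_round_trip(self, tmp_path, config):
        from methylsmr import AnalysisConfig
        path = tmp_path / "cfg.yaml"
        config.to_yaml(path)
        back = AnalysisConfig.from_yaml(path)
        assert back == config

    def test_threshold_bounds_validated(self):
        from methylsmr import AnalysisConfig
        with pytest.raises(ValueError):
            AnalysisConfig(heidi_threshold=1.5)


class TestProbeCisSet:
    def test_duplicate_snp_ids_rejected(self):
        with pytest.raises(SummaryStatsError, match="duplicate"):
            ProbeCisSet("cg1", "1", 100, records=[_var(), _var()])
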