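# methylsmr

Summary-data Mendelian randomization (SMR) with the HEIDI heterogeneity
test, for integrating methylation/expression QTL and GWAS summary
statistics.

## What it does

GWAS hits are mostly regulatory, and the causal gene is often not the
nearest one. When a variant's association overlaps a cis-mQTL or eQTL
signal, two explanations compete: one causal variant affecting both the
molecular trait and the phenotype (pleiotropy), or two distinct causal
variants in LD (linkage). `methylsmr`:

- reads GWAS (`.ma` dialect) and long-format cis-QTL summary tables,
  harmonizes alleles (strand flips, palindromic SNPs resolved by
  frequency), and computes LD from a dosage-matrix or VCF reference;
- tests each probe with the SMR statistic: with z1 = b_gwas/se_gwas and
  z2 = b_qtl/se_qtl at the top cis-QTL SNP,
  `T_SMR = z1²z2²/(z1²+z2²)` on 1 df, `b_SMR = b_gwas/b_qtl`,
  `se_SMR = |b_SMR|/√T_SMR`;
- separates pleiotropy from linkage with the HEIDI test: deviations of the
  Wald ratio across alternative cis instruments, delta-method covariance
  under LD, tail of the matching weighted sum of chi-squares;
- orchestrates discovery across traits with per-dataset Bonferroni
  correction, replication, sign-concordance (exact binomial in log space),
  mQTL/eQTL gene-level overlap, novel-locus flagging, multi-trait sites,
  and the clustered trait-by-probe t-statistic matrix;
- ships a generative simulator (latent-Gaussian AR(1) haplotypes,
  pleiotropy/linkage/null scenarios, two tissues) so the whole pipeline is
  testable end to end without cohort data.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```python
from methylsmr import (AnalysisConfig, SimScenario, simulate_locus_study)
from methylsmr.pipeline import analyze_probe

# one cis locus where a single causal variant drives methylation and,
# through it, the phenotype in an independent GWAS sample
study = simulate_locus_study(SimScenario(kind="pleiotropy", seed=3,
                                         n_gwas=5000))
gwas = {r.snp_id: r for r in study.gwas}
rec = analyze_probe(study.qtl, gwas, study.ld, AnalysisConfig(), "trait1")
print(f"instrument {rec.instrument_snp}  b_SMR={rec.b_smr:.3f}  "
      f"p_SMR={rec.p_smr:.2e}  HEIDI p={rec.heidi_p:.3f}")
```

prints

```
instrument snp011  b_SMR=0.297  p_SMR=5.81e-07  HEIDI p=0.296
```

The instrument is the strongest cis-mQTL SNP shared with the GWAS. The
Wald ratio b_SMR estimates the methylation-to-phenotype effect (generative
value 0.3 here), p_SMR says the shared signal is far beyond the
family-wise threshold, and the non-significant HEIDI p (> 0.05) means the
alternative instruments tell a consistent story — a pleiotropic
association, not linkage. Under a linkage scenario (`kind="linkage"`,
two causal variants at LD r = 0.5) the same call returns HEIDI p < 0.01
and the association is classified `linkage`.

A full multi-trait run on a synthetic study:

```bash
smr simulate --seed 7 --out-dir sim
smr run --gwas sim/gwas_trait1.ma --gwas sim/gwas_trait2.ma \
        --gwas sim/gwas_trait3.ma --qtl sim/mqtl_tissue1.tsv \
        --ld sim/ld_reference.tsv --out-dir out
# tested 72 probes; SMR threshold 0.000694
```

`out/smr_results.tsv` has one row per trait-probe pair with the SMR and
HEIDI statistics and the pleiotropic/linkage/not_significant/untested
classification; `out/smr_pleiotropic.bed` holds the pleiotropic probe
positions (0-based half-open). The `examples/` directory has one short
script per capability.

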