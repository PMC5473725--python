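"""Cross-tissue concordance and replication.

The benchmark carries a second tissue (n=665) that shares the causal
variant for 90% of probes. Running SMR in both tissues, the direction of
b_SMR agrees for almost every association, and associations discovered in
tissue 1 can be checked against tissue 2's own Bonferroni threshold.
"""

from methylsmr import (AnalysisConfig, make_benchmark, replicate,
                       run_discovery, sign_concordance)

bench = make_benchmark(seed=7)
cfg = AnalysisConfig()
run1 = run_discovery(bench.gwas, bench.qtl, bench.ld, cfg)
run2 = run_discovery(bench.gwas, bench.qtl2, bench.ld, cfg)

rep = sign_concordance(run1.records, run2.records)
print(f"sign concordance: {rep.n_same_sign}/{rep.n_tested} "
      f"({100 * rep.proportion:.1f}%), exact sign test "
      f"log10 p = {rep.log10_sign_test_p:.1f}")

statuses = replicate(run1, run2, cfg)
n_rep = sum(s.status == "replicated" for s in statuses)
print(f"replication: {n_rep}/{len(statuses)} discovery pleiotropic "
      "associations meet tissue-2's SMR and HEIDI criteria")
print("\nHigh concordance with a vanishing sign-test p mirrors the "
      "shared genetic control of methylation across tissues; the "
      "replication criteria are tissue-2's own Bonferroni threshold "
      "plus HEIDI p > 0.05.")
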