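"""Multi-trait sites and the clustered t-statistic matrix.

Finds probes pleiotropically associated with two or more traits and
builds the trait-by-probe matrix of t_SMR = b_SMR/se_SMR, ordered by
average-linkage hierarchical clustering — the data behind a
multi-phenotype heatmap.
"""

from methylsmr import (AnalysisConfig, make_benchmark, multi_trait_sites,
                       run_discovery, trait_probe_matrix)

bench = make_benchmark(seed=7)
result = run_discovery(bench.gwas, bench.qtl, bench.ld, AnalysisConfig())

multi = multi_trait_sites(result.records)
print(f"probes pleiotropic for >= 2 traits: {len(multi)}")
if len(multi):
    print(multi.to_string(index=False))

seed_probes = sorted({r.probe_id for r in result.records
                      if r.classification == "pleiotropic"})
tpm = trait_probe_matrix(result, seed_probes, min_tested_sites=10)
print(f"\nmatrix: {tpm.values.shape[0]} probes x "
      f"{tpm.values.shape[1]} traits (cells are t_SMR; NaN = untested)")
print("clustered trait order:", tpm.col_order)
print("first probes in clustered order:", tpm.row_order[:5])
print("\nTraits that share pleiotropic architecture cluster together; "
      "each cell is the signed strength of the probe-trait SMR signal.")
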